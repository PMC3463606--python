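import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retnetdyn import (
    ExpressionMatrix,
    SimConfig,
    TypedNetwork,
    cluster_entities,
    correlation_matrix,
    pearson_cc,
    simulate_expression,
    simulate_irn,
    target_correlation_z,
)
from retnetdyn.exceptions import ConstantProfileError, EmptyInputError, ParameterError
from retnetdyn.expression import cluster_timepoints
from retnetdyn.network import GENE, MIRNA, TF


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3, 4, 5, 6), (2, 4, 6, 8, 10, 12), 1.0),
            ((1, 2, 3, 4, 5, 6), (6, 5, 4, 3, 2, 1), -1.0),
            ((1, 2, 3), (1, 3, 2), 0.5),  # hand computation of the closed form
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert pearson_cc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_is_an_error(self):
        with pytest.raises(ConstantProfileError):
            pearson_cc((1, 1, 1), (1, 2, 3))

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(-50, 50), min_size=4, max_size=8),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    def test_symmetry_and_affine_invariance(self, xs, scale, shift):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        x = np.array(xs, dtype=float)
        y = rng.normal(size=len(x))
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        cc = pearson_cc(x, y)
        assert -1.0 <= cc <= 1.0
        assert pearson_cc(y, x) == pytest.approx(cc, abs=1e-12)
        assert pearson_cc(scale * x + shift, y) == pytest.approx(cc, abs=1e-9)


class TestCorrelationMatrix:
    def test_matches_pairwise_calls(self, make_expression):
        rng = np.random.default_rng(11)
        vals = {f"g{i}": rng.normal(size=5) for i in range(3)}
        vals.update({f"m{i}": rng.normal(size=5) for i in range(2)})
        types = {k: (GENE if k.startswith("g") else MIRNA) for k in vals}
        expr = make_expression(vals, types)
        mat = correlation_matrix(expr, ["g0", "g1", "g2"], ["m0", "m1"])
        for g in ["g0", "g1", "g2"]:
            for m in ["m0", "m1"]:
                assert mat.loc[g, m] == pytest.approx(
                    pearson_cc(vals[g], vals[m]), abs=1e-12
                )

    def test_identical_and_negated_profiles(self, make_expression):
        x = np.array([1.0, 4.0, 2.0, 5.0])
        expr = make_expression({"g": x, "m": x, "n": -x}, {"g": GENE, "m": MIRNA, "n": MIRNA})
        mat = correlation_matrix(expr, ["g"], ["m", "n"])
        assert mat.loc["g", "m"] == pytest.approx(1.0)
        assert mat.loc["g", "n"] == pytest.approx(-1.0)

    def test_constant_profile_marked_nan(self, make_expression):
        expr = make_expression(
            {"g": [1, 1, 1, 1], "m": [1, 2, 3, 4]}, {"g": GENE, "m": MIRNA}
        )
        assert np.isnan(correlation_matrix(expr, ["g"], ["m"]).loc["g", "m"])


class TestClusterEntities:
    def test_planted_groups_recovered_with_peaks(self, make_expression):
        early = np.array([9.0, 6.0, 5.0, 4.0, 3.0, 2.0])
        late = early[::-1]
        vals = {f"e{i}": early for i in range(3)}
        vals.update({f"l{i}": late for i in range(3)})
        expr = make_expression(vals, {k: GENE for k in vals})
        clusters = cluster_entities(expr, GENE, min_size=2)
        assert len(clusters) == 2
        peaks = {frozenset(c.members): c.peak_timepoint for c in clusters}
        assert peaks[frozenset({"e0", "e1", "e2"})] == "t0"
        assert peaks[frozenset({"l0", "l1", "l2"})] == "t5"

    def test_identical_profiles_one_cluster(self, make_expression):
        prof = np.array([1.0, 5.0, 2.0, 4.0])
        expr = make_expression({f"g{i}": prof for i in range(4)}, {f"g{i}": GENE for i in range(4)})
        clusters = cluster_entities(expr, GENE, min_size=1)
        assert len(clusters) == 1 and clusters[0].size == 4

    def test_min_size_filters_everything(self, make_expression):
        prof = np.array([1.0, 5.0, 2.0, 4.0])
        expr = make_expression({"a": prof, "b": -prof}, {"a": GENE, "b": GENE})
        assert cluster_entities(expr, GENE, min_size=5) == []

    def test_min_size_validation(self, make_expression):
        prof = np.array([1.0, 5.0, 2.0])
        expr = make_expression({"a": prof, "b": prof}, {"a": GENE, "b": GENE})
        with pytest.raises(ParameterError):
            cluster_entities(expr, GENE, min_size=0)

    def test_clusters_are_disjoint(self):
        cfg = SimConfig(seed=5, n_tf=3, n_mirna=5, n_gene=60, planted_motifs={})
        net, _ = simulate_irn(cfg)
        expr, _ = simulate_expression(cfg, net)
        clusters = cluster_entities(expr, GENE, min_size=1)
        all_members = [m for c in clusters for m in c.members]
        assert len(all_members) == len(set(all_members))


class TestTargetCorrelationZ:
    @staticmethod
    def _planted_case(seed=0, anticorr=0.3, noise=0.2):
        cfg = SimConfig(seed=seed, n_tf=4, n_mirna=12, n_gene=250,
                        planted_motifs={}, anticorr_fraction=anticorr,
                        poscorr_fraction=0.0, anticorr_noise_sd=noise)
        net, _ = simulate_irn(cfg)
        expr, _ = simulate_expression(cfg, net)
        return expr, net

    def test_anticorrelated_targets_enrich_low_bins(self):
        expr, net = self._planted_case(seed=1)
        rep = target_correlation_z(expr, net, n_rand=200, seed=7)
        low = rep.bin_edges[1:] <= -0.5
        assert np.nanmax(rep.z[low]) > 2.0

    def test_observed_total_invariant_across_seeds(self):
        expr, net = self._planted_case(seed=2)
        r1 = target_correlation_z(expr, net, n_rand=20, seed=1)
        r2 = target_correlation_z(expr, net, n_rand=20, seed=99)
        assert r1.observed.sum() == r2.observed.sum() == r1.n_pairs

    def test_null_preserves_per_mirna_target_count(self):
        # with bin_width covering everything, every null replicate must place
        # exactly n_pairs correlations
        expr, net = self._planted_case(seed=3)
        rep = target_correlation_z(expr, net, bin_width=2.0, n_rand=5, seed=0)
        assert rep.null_mean[0] == rep.n_pairs and rep.null_sd[0] == 0.0
        assert np.isnan(rep.z[0])  # degenerate null -> undefined marker

    def test_degenerate_null_sd_zero(self, make_expression):
        # a single measured gene: every null draw equals the observed pair set
        t = np.array([1.0, 2.0, 3.0, 1.0])
        net = TypedNetwork({"m": MIRNA, "g": GENE}, [("m", "g")])
        expr = make_expression({"m": t, "g": -t}, {"m": MIRNA, "g": GENE})
        rep = target_correlation_z(expr, net, bin_width=0.5, n_rand=3, seed=0)
        assert np.all(rep.null_sd == 0.0)
        assert np.all(np.isnan(rep.z))

    def test_no_measurable_pairs_raises(self, make_expression):
        net = TypedNetwork({"m": MIRNA, "g": GENE}, [("m", "g")])
        expr = make_expression({"m": [1.0, 2.0, 3.0]}, {"m": MIRNA})
        with pytest.raises(EmptyInputError):
            target_correlation_z(expr, net, n_rand=5, seed=0)

    def test_bad_bin_width(self, make_expression):
        expr, net = self._planted_case(seed=4)
        with pytest.raises(ParameterError):
            target_correlation_z(expr, net, bin_width=0.3, n_rand=5, seed=0)


class TestClusterTimepoints:
    def test_duplicated_columns_split(self, make_expression):
        rng = np.random.default_rng(0)
        a = rng.normal(size=6)
        b = a + 10.0
        vals = {f"g{i}": np.array([a[i], a[i], b[i], b[i]]) for i in range(6)}
        expr = make_expression(vals, {k: GENE for k in vals}, ["A1", "A2", "B1", "B2"])
        cut = set(map(frozenset, cluster_timepoints(expr).two_cut))
        assert cut == {frozenset({"A1", "A2"}), frozenset({"B1", "B2"})}

    def test_deterministic_for_fixed_input(self, make_expression):
        rng = np.random.default_rng(5)
        vals = {f"g{i}": rng.normal(size=5) for i in range(8)}
        expr = make_expression(vals, {k: GENE for k in vals})
        t1 = cluster_timepoints(expr)
        t2 = cluster_timepoints(expr)
        assert np.array_equal(t1.linkage_matrix, t2.linkage_matrix)
        assert t1.newick() == t2.newick()

    def test_smooth_drift_merges_adjacent_first(self):
        cfg = SimConfig(seed=9, n_tf=3, n_mirna=5, n_gene=120, planted_motifs={},
                        anticorr_fraction=0.0, poscorr_fraction=0.0)
        net, _ = simulate_irn(cfg)
        expr, _ = simulate_expression(cfg, net)
        tree = cluster_timepoints(expr)
        # oracle: first merge = closest column pair, which must be adjacent
        from retnetdyn.expression import _standardized_rows
        std = _standardized_rows(expr.values.to_numpy())
        std = std[~np.isnan(std[:, 0])]
        d = np.linalg.norm(std[:, :, None] - std[:, None, :], axis=0)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        first = {int(tree.linkage_matrix[0, 0]), int(tree.linkage_matrix[0, 1])}
        assert first == {i, j}
        assert abs(i - j) == 1

    def test_too_few_timepoints(self, make_expression):
        expr = make_expression({"g": [1.0, 2.0]}, {"g": GENE}, ["t0", "t1"])
        with pytest.raises(ParameterError):
            cluster_timepoints(expr)


def test_expression_tsv_round_trip(tmp_path):
    cfg = SimConfig(seed=13, n_tf=3, n_mirna=4, n_gene=20, planted_motifs={})
    net, _ = simulate_irn(cfg)
    expr, _ = simulate_expression(cfg, net)
    expr.to_tsv(tmp_path / "e.tsv")
    back = ExpressionMatrix.from_tsv(tmp_path / "e.tsv")
    assert back.timepoints == expr.timepoints
    assert back.types.equals(expr.types)
    assert np.allclose(back.values.to_numpy(), expr.values.to_numpy())
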