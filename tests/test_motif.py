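from collections import Counter
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from oracles import bf_connected_triples
from retnetdyn import (
    SimConfig,
    TypedNetwork,
    canonical_typed_label,
    count_2node_mutual,
    count_motifs,
    enumerate_size3,
    motif_dynamics,
    motif_zscores,
    simulate_irn,
    simulate_regimes,
    typed_edge_swap,
)
from retnetdyn.exceptions import ParameterError
from retnetdyn.motif import cluster_timepoints, label_triple
from retnetdyn.network import GENE, MIRNA, TF


class TestEnumerateSize3:
    def test_star_has_three_triples(self, star_net):
        assert len(list(enumerate_size3(star_net))) == 3

    def test_triangle_single_triple(self):
        net = TypedNetwork(
            {"T1": TF, "T2": TF, "g": GENE},
            [("T1", "T2"), ("T1", "g"), ("T2", "g")],
        )
        assert len(list(enumerate_size3(net))) == 1

    def test_matches_exhaustive_scan(self, make_random_net):
        rng = np.random.default_rng(31)
        for _ in range(30):
            net = make_random_net(rng, n_nodes=12, p=0.2)
            esu = Counter(frozenset(t) for t in enumerate_size3(net))
            assert max(esu.values(), default=1) == 1  # each triple exactly once
            assert esu == Counter(bf_connected_triples(net))


class TestCanonicalTypedLabel:
    def test_isomorphic_pair_same_label(self):
        a = canonical_typed_label([TF, MIRNA, GENE], [(0, 1), (1, 0), (0, 2)])
        b = canonical_typed_label([GENE, TF, MIRNA], [(1, 2), (2, 1), (1, 0)])
        assert a == b
        assert a.family == "RML"

    @pytest.mark.parametrize(
        "types, arcs, family",
        [
            ([TF, GENE, GENE], [(0, 1), (0, 2)], "SIM"),
            ([TF, MIRNA, GENE], [(0, 2), (1, 2)], "CRM"),
            ([TF, MIRNA, GENE], [(0, 1), (0, 2), (1, 2)], "FFL"),
            ([TF, MIRNA, GENE], [(0, 1), (1, 0), (0, 2)], "RML"),
            ([TF, TF, GENE], [(0, 1), (1, 2)], "other"),  # cascade
        ],
    )
    def test_family_assignment(self, types, arcs, family):
        assert canonical_typed_label(types, arcs).family == family

    def test_wrong_node_count(self):
        with pytest.raises(ParameterError):
            canonical_typed_label([TF, GENE], [(0, 1)])

    def test_invariant_under_all_relabelings_exhaustive(self):
        """Every typed connected 3-node digraph maps to one label under all 6
        node permutations (the full 27 x 64 sweep)."""
        types = [TF, MIRNA, GENE]
        pairs = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
        n_checked = 0
        for t0 in types:
            for t1 in types:
                for t2 in types:
                    for bits in range(64):
                        arcs = [p for k, p in enumerate(pairs) if bits >> k & 1]
                        und = {frozenset(p) for p in arcs}
                        if len(und) < 2:
                            continue  # disconnected
                        ts = (t0, t1, t2)
                        ref = canonical_typed_label(ts, arcs)
                        for perm in permutations(range(3)):
                            p_types = [None] * 3
                            for k in range(3):
                                p_types[perm[k]] = ts[k]
                            p_arcs = [(perm[i], perm[j]) for i, j in arcs]
                            assert canonical_typed_label(p_types, p_arcs) == ref
                        n_checked += 1
        assert n_checked > 1000


class TestCountMotifs:
    def test_star_is_three_sims(self, star_net):
        counts = count_motifs(star_net)
        assert sum(counts.values()) == 3
        label = label_triple(star_net, ("T", "g1", "g2")).canonical_label
        assert counts[label] == 3

    def test_tf_mirna_filter(self, star_net):
        assert count_motifs(star_net, require_tf_and_mirna=True) == Counter()

    def test_partition_property(self, make_random_net):
        rng = np.random.default_rng(37)
        for _ in range(10):
            net = make_random_net(rng, n_nodes=12, p=0.2)
            counts = count_motifs(net)
            assert sum(counts.values()) == len(list(enumerate_size3(net)))

    def test_counts_match_per_triple_labels(self, make_random_net):
        rng = np.random.default_rng(41)
        net = make_random_net(rng, n_nodes=10, p=0.3)
        expected = Counter(
            label_triple(net, t).canonical_label for t in enumerate_size3(net)
        )
        assert count_motifs(net) == expected


def neighbor_type_histograms(net):
    out = {}
    for v in sorted(net.nodes):
        succ = Counter(net.node_type(u) for u in net.successors(v))
        pred = Counter(net.node_type(u) for u in net.predecessors(v))
        out[v] = (succ, pred)
    return out


class TestTypedEdgeSwap:
    def test_single_arc_unchanged(self):
        net = TypedNetwork({"T": TF, "g": GENE}, [("T", "g")])
        swapped = typed_edge_swap(net, seed=0)
        assert swapped.arc_set() == net.arc_set()
        assert swapped.swaps_achieved == 0

    def test_conservation_laws(self, make_random_net):
        rng = np.random.default_rng(43)
        for _ in range(20):
            net = make_random_net(rng, n_nodes=15, p=0.2)
            swapped = typed_edge_swap(net, seed=int(rng.integers(2**31)))
            assert swapped.n_arcs == net.n_arcs
            assert neighbor_type_histograms(swapped) == neighbor_type_histograms(net)
            for v in net.nodes:
                assert swapped.out_degree(v) == net.out_degree(v)
                assert swapped.in_degree(v) == net.in_degree(v)
            for s, t in swapped.arcs():
                assert s != t

    def test_actually_randomizes(self):
        cfg = SimConfig(seed=3, n_tf=5, n_mirna=10, n_gene=100, planted_motifs={})
        net, _ = simulate_irn(cfg)
        swapped = typed_edge_swap(net, seed=1)
        assert swapped.swaps_achieved > 0
        assert swapped.arc_set() != net.arc_set()

    def test_deterministic(self):
        cfg = SimConfig(seed=3, n_tf=5, n_mirna=10, n_gene=100, planted_motifs={})
        net, _ = simulate_irn(cfg)
        a = typed_edge_swap(net, seed=9)
        b = typed_edge_swap(net, seed=9)
        assert a.arc_set() == b.arc_set()


class TestMotifZScores:
    def test_unswappable_network_degenerate(self):
        net = TypedNetwork({"T": TF, "g": GENE, "h": GENE}, [("T", "g"), ("T", "h")])
        prof = motif_zscores(net, n_rand=5, seed=0)
        for st in prof.per_label.values():
            assert np.isnan(st.z) or st.z == 0.0

    def test_planted_ffls_recovered(self):
        cfg = SimConfig(seed=11)  # default scale, 50 planted FFLs
        net, _ = simulate_irn(cfg)
        prof = motif_zscores(net, n_rand=50, seed=2, require_tf_and_mirna=True)
        assert prof.per_family["FFL"].z > 2.0

    def test_bit_identical_rerun(self):
        cfg = SimConfig(seed=5, n_tf=4, n_mirna=6, n_gene=60, planted_motifs={"FFL": 5})
        net, _ = simulate_irn(cfg)
        a = motif_zscores(net, n_rand=10, seed=3)
        b = motif_zscores(net, n_rand=10, seed=3)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())


class TestCount2NodeMutual:
    def test_mutual_pair_counted_once(self):
        net = TypedNetwork({"T1": TF, "M1": MIRNA}, [("T1", "M1"), ("M1", "T1")])
        res = count_2node_mutual(net, n_rand=3, seed=0)
        assert res.observed == 1

    def test_dag_has_none(self, chain_net):
        assert count_2node_mutual(chain_net, n_rand=3, seed=0).observed == 0

    def test_matches_pair_scan(self, make_random_net):
        rng = np.random.default_rng(47)
        for _ in range(15):
            net = make_random_net(rng, n_nodes=12, p=0.3)
            expected = sum(
                1
                for s, t in net.arcs()
                if s < t and net.has_arc(t, s)
            )
            assert count_2node_mutual(net, n_rand=2, seed=0).observed == expected


class TestMotifDynamics:
    def test_identical_networks_identical_columns(self):
        from retnetdyn.active import ActiveSubnetwork

        cfg = SimConfig(seed=7, n_tf=4, n_mirna=6, n_gene=50, planted_motifs={"FFL": 5})
        net, _ = simulate_irn(cfg)
        subnets = [
            ActiveSubnetwork("t0", set(net.nodes), set(net.nodes), net),
            ActiveSubnetwork("t1", set(net.nodes), set(net.nodes), net),
        ]
        zmat, _ = motif_dynamics(subnets, n_rand=30, seed=13)
        pd.testing.assert_series_equal(
            zmat["t0"], zmat["t1"], check_names=False
        )

    def test_row_alignment_covers_all_labels(self):
        cfg = SimConfig(seed=19)
        subnets, _ = simulate_regimes(cfg)
        zmat, profiles = motif_dynamics(subnets[:3], n_rand=5, seed=1)
        union = set().union(*(p.per_label for p in profiles))
        assert set(zmat.index) == union

    def test_regime_family_directions(self):
        """Mutual-loop motifs dominate the interconnected regime; one-way
        FFL/SIM patterns dominate the modular regime."""
        cfg = SimConfig(seed=23)
        subnets, man = simulate_regimes(cfg)
        zmat, profiles = motif_dynamics(subnets, n_rand=40, seed=29)
        fam_z = {
            p.network_label: {f: st.z for f, st in p.per_family.items()}
            for p in profiles
        }
        early = [tp for tp, r in man["regimes"].items() if r == "early"]
        late = [tp for tp, r in man["regimes"].items() if r == "late"]
        mean = lambda fam, tps: np.nanmean([fam_z[tp].get(fam, np.nan) for tp in tps])
        assert mean("RML", early) > mean("RML", late)
        assert mean("FFL", late) > mean("FFL", early)
        assert mean("SIM", late) > mean("SIM", early)


class TestClusterTimepoints:
    def test_duplicated_columns_split(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        b = a + 5
        z = pd.DataFrame({"A1": a, "A2": a, "B1": b, "B2": b})
        cut = set(map(frozenset, cluster_timepoints(z).two_cut))
        assert cut == {frozenset({"A1", "A2"}), frozenset({"B1", "B2"})}

    def test_outlier_column_merges_last(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=8)
        z = pd.DataFrame(
            {"a": base, "b": base + rng.normal(0, 0.01, 8),
             "c": base + rng.normal(0, 0.01, 8), "x": base + 50}
        )
        tree = cluster_timepoints(z)
        # the outlier joins at the final (highest) merge
        last = tree.linkage_matrix[-1]
        n = len(tree.labels)
        members = {int(last[0]), int(last[1])}
        assert (tree.labels.index("x") in members) or (last[3] == n)
        cut = set(map(frozenset, tree.two_cut))
        assert frozenset({"x"}) in cut

    def test_missing_z_imputed_as_zero(self):
        z = pd.DataFrame(
            {"a": [1.0, np.nan], "b": [1.0, 0.0], "c": [-5.0, 3.0]},
            index=["m1", "m2"],
        )
        cut = set(map(frozenset, cluster_timepoints(z).two_cut))
        assert cut == {frozenset({"a", "b"}), frozenset({"c"})}
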