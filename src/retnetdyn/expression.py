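"""Expression matrices, Pearson correlation, clustering, and the
miRNA–target correlation-bin randomization test.

Profiles are log2 expression values of typed entities (TF / miRNA / gene)
over an ordered axis of developmental time points.  The randomization test
compares the histogram of miRNA–predicted-target correlations against nulls
in which every miRNA keeps its target-set *size* but draws targets uniformly
from the measured genes; per-bin Z-values flag enriched or depleted
correlation ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._cluster import TimepointClustering, cluster_columns
from .exceptions import (
    ConstantProfileError,
    EmptyInputError,
    ParameterError,
    UnknownEntityError,
)
from .network import GENE, MIRNA, TF, NODE_TYPES, TypedNetwork

logger = logging.getLogger(__name__)


class ExpressionMatrix:
    """Log2 expression of typed entities over ordered time points.

    Backed by a pandas DataFrame (rows = entities, columns = time points)
    plus a parallel type Series.  Rows with missing values are dropped (and
    counted) at load time; time-point order is preserved exactly as given.
    """

    def __init__(self, values: pd.DataFrame, types: pd.Series):
        if not values.index.equals(types.index):
            raise ParameterError("values and types must share the same entity index")
        bad = set(types.unique()) - set(NODE_TYPES)
        if bad:
            raise ParameterError(f"unknown entity types: {sorted(bad)}")
        if values.isna().any().any():
            raise ParameterError("ExpressionMatrix may not contain missing values")
        if values.index.has_duplicates:
            raise ParameterError("duplicate entity ids")
        self.values = values.astype(float)
        self.types = types

    # -- views -------------------------------------------------------------
    @property
    def entity_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_entities(self) -> int:
        return len(self.values)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.values.index

    def profile(self, entity_id: str) -> np.ndarray:
        try:
            return self.values.loc[entity_id].to_numpy()
        except KeyError:
            raise UnknownEntityError(f"unknown entity {entity_id!r}") from None

    def entity_type(self, entity_id: str) -> str:
        try:
            return self.types.loc[entity_id]
        except KeyError:
            raise UnknownEntityError(f"unknown entity {entity_id!r}") from None

    def ids_of_type(self, ntype: str) -> List[str]:
        return list(self.types.index[self.types == ntype])

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if df.shape[1] < 4:
            raise ParameterError(f"{path}: need id, type and >=2 time-point columns")
        df = df.set_index(df.columns[0])
        types = df.iloc[:, 0]
        values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
        n_bad = int(values.isna().any(axis=1).sum())
        if n_bad:
            logger.warning("%s: dropping %d rows with missing values", path, n_bad)
            keep = ~values.isna().any(axis=1)
            values, types = values[keep], types[keep]
        return cls(values, types)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "type", self.types)
        out.index.name = "id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length profiles.

    Raises :class:`ConstantProfileError` for a constant vector (correlation
    undefined); callers typically skip and log such pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("profiles must be 1-D and of equal length")
    if len(x) < 3:
        raise ParameterError("profiles must have length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        raise ConstantProfileError("correlation undefined for a constant profile")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _standardized_rows(mat: np.ndarray) -> np.ndarray:
    """Center and L2-normalize rows; constant rows become NaN rows."""
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = centered / norms
    out[norms[:, 0] == 0.0] = np.nan
    return out


def correlation_matrix(
    expr: ExpressionMatrix, genes: Sequence[str], mirnas: Sequence[str]
) -> pd.DataFrame:
    """Gene × miRNA Pearson correlation matrix; undefined entries are NaN."""
    for eid in list(genes) + list(mirnas):
        if eid not in expr:
            raise UnknownEntityError(f"unknown entity {eid!r}")
    g = _standardized_rows(expr.values.loc[list(genes)].to_numpy())
    m = _standardized_rows(expr.values.loc[list(mirnas)].to_numpy())
    cc = np.clip(g @ m.T, -1.0, 1.0)
    return pd.DataFrame(cc, index=list(genes), columns=list(mirnas))


# ---------------------------------------------------------------------------
# Entity clustering
# ---------------------------------------------------------------------------

@dataclass
class EntityCluster:
    members: List[str]
    mean_profile: np.ndarray
    peak_timepoint: str

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_entities(
    expr: ExpressionMatrix,
    which: str,
    min_size: int,
    cut: float = 0.5,
) -> List[EntityCluster]:
    """Group same-type entities by expression-correlation similarity.

    Average-linkage hierarchical clustering with distance 1 − cc, cut at
    ``cut``; only clusters with at least ``min_size`` members are returned,
    each with its mean profile and peak time point.  Constant-profile
    entities (undefined correlation) are excluded and logged.
    """
    if min_size < 1:
        raise ParameterError("min_size must be >= 1")
    ids = expr.ids_of_type(which)
    if len(ids) < 2:
        raise ParameterError(f"need >= 2 entities of type {which!r}")
    mat = expr.values.loc[ids].to_numpy()
    std = _standardized_rows(mat)
    keep = ~np.isnan(std[:, 0])
    if keep.sum() < len(ids):
        logger.warning("cluster_entities: excluding %d constant profiles", int((~keep).sum()))
    ids = [i for i, k in zip(ids, keep) if k]
    if len(ids) < 2:
        return []
    std = std[keep]
    corr = np.clip(std @ std.T, -1.0, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    lk = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(lk, t=cut, criterion="distance")
    clusters: List[EntityCluster] = []
    for label in np.unique(assign):
        members = [i for i, a in zip(ids, assign) if a == label]
        if len(members) < min_size:
            continue
        mean_profile = expr.values.loc[members].to_numpy().mean(axis=0)
        peak = expr.timepoints[int(np.argmax(mean_profile))]
        clusters.append(EntityCluster(members=members, mean_profile=mean_profile, peak_timepoint=peak))
    clusters.sort(key=lambda c: (-c.size, c.members[0]))
    return clusters


# ---------------------------------------------------------------------------
# miRNA–target correlation randomization test
# ---------------------------------------------------------------------------

@dataclass
class CorrelationBinReport:
    """Observed vs null histogram of miRNA–target correlations, with Z per bin.

    Bins partition [−1, 1], right-closed (the first bin also includes −1).
    ``z`` is NaN where the null SD is zero (undefined marker).
    """

    bin_edges: np.ndarray
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    n_rand: int
    seed: int
    n_pairs: int = 0
    n_excluded_pairs: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "observed": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": self.z,
            }
        )

    def write(self, path, metadata_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if metadata_path is not None:
            import json

            with open(metadata_path, "w") as fh:
                json.dump(
                    {
                        "seed": self.seed,
                        "n_rand": self.n_rand,
                        "n_pairs": self.n_pairs,
                        "n_excluded_pairs": self.n_excluded_pairs,
                    },
                    fh,
                    indent=2,
                )
                fh.write("\n")


def _bin_index(cc: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # right-closed bins (lo, hi]; cc == -1 folded into the first bin
    idx = np.searchsorted(edges, cc, side="left") - 1
    return np.clip(idx, 0, len(edges) - 2)


def target_correlation_z(
    expr: ExpressionMatrix,
    net: TypedNetwork,
    bin_width: float = 0.05,
    n_rand: int = 1000,
    seed: int = 0,
) -> CorrelationBinReport:
    """Fig.-2-style test: miRNA–target correlation histogram vs random targets.

    Observed counts come from every miRNA→target arc whose endpoints are both
    measured and non-constant.  Each randomization replaces every miRNA's
    target set by an equal-sized uniform sample (without replacement) of
    measured genes.  Z per bin = (observed − null mean) / null SD (sample SD,
    ddof = 1); bins with zero null SD get NaN.
    """
    nbins = 2.0 / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ParameterError("bin_width must divide 2 into an integer number of bins")
    nbins = int(round(nbins))
    if n_rand < 2:
        raise ParameterError("n_rand must be >= 2")
    edges = np.linspace(-1.0, 1.0, nbins + 1)

    mirna_ids = [m for m in expr.ids_of_type(MIRNA) if m in net]
    gene_pool = expr.ids_of_type(GENE)
    if not gene_pool:
        raise EmptyInputError("no measurable miRNA-target pairs")
    gene_std = _standardized_rows(expr.values.loc[gene_pool].to_numpy())
    measurable = [g for g, row in zip(gene_pool, gene_std) if not np.isnan(row[0])]
    gene_idx = {g: i for i, g in enumerate(gene_pool)}

    n_excluded = 0
    mirna_rows: List[Tuple[np.ndarray, int]] = []  # (cc row over gene pool, n targets)
    observed = np.zeros(nbins, dtype=float)
    n_pairs = 0
    for m in mirna_ids:
        prof = expr.profile(m)
        mstd = _standardized_rows(prof[None, :])[0]
        targets = [t for t in net.successors(m) if t in gene_idx]
        if np.isnan(mstd[0]):
            n_excluded += len(targets)
            continue
        cc_row = np.clip(gene_std @ mstd, -1.0, 1.0)
        t_idx = []
        for t in targets:
            i = gene_idx[t]
            if np.isnan(cc_row[i]):
                n_excluded += 1
            else:
                t_idx.append(i)
        if not t_idx:
            continue
        ccs = cc_row[np.array(t_idx)]
        np.add.at(observed, _bin_index(ccs, edges), 1)
        n_pairs += len(t_idx)
        mirna_rows.append((cc_row, len(t_idx)))

    if n_pairs == 0:
        raise EmptyInputError("no measurable miRNA-target pairs")

    measurable_idx = np.array([gene_idx[g] for g in measurable])
    rng = np.random.default_rng(seed)
    null_counts = np.zeros((n_rand, nbins), dtype=float)
    for r in range(n_rand):
        counts = np.zeros(nbins, dtype=float)
        for cc_row, k in mirna_rows:
            pick = rng.choice(measurable_idx, size=k, replace=False)
            np.add.at(counts, _bin_index(cc_row[pick], edges), 1)
        null_counts[r] = counts
    null_mean = null_counts.mean(axis=0)
    null_sd = null_counts.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed - null_mean) / null_sd
    z[null_sd == 0.0] = np.nan

    if n_excluded:
        logger.info("target_correlation_z: excluded %d pairs with unmeasured/constant endpoint", n_excluded)
    return CorrelationBinReport(
        bin_edges=edges,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        n_rand=n_rand,
        seed=seed,
        n_pairs=n_pairs,
        n_excluded_pairs=n_excluded,
    )


# ---------------------------------------------------------------------------
# Time-point clustering
# ---------------------------------------------------------------------------

def cluster_timepoints(expr: ExpressionMatrix) -> TimepointClustering:
    """Cluster time-point columns on per-entity standardized expression.

    Euclidean distance, average linkage; constant rows are excluded from the
    standardization.  Returns the merge tree and the 2-group cut.
    """
    if len(expr.timepoints) < 3:
        raise ParameterError("need >= 3 time points")
    std = _standardized_rows(expr.values.to_numpy())
    std = std[~np.isnan(std[:, 0])]
    if std.shape[0] == 0:
        raise EmptyInputError("all profiles are constant")
    return cluster_columns(std, expr.timepoints)
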