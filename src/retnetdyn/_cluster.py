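"""Shared hierarchical-clustering helpers (average linkage throughout)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .exceptions import ParameterError


@dataclass
class TimepointClustering:
    """Average-linkage merge tree over a set of columns plus its 2-group cut."""

    labels: List[str]
    linkage_matrix: np.ndarray
    two_cut: Tuple[frozenset, frozenset]

    def newick(self) -> str:
        """Merge tree as a Newick string with merge heights as branch lengths."""
        n = len(self.labels)
        nodes = {i: (self.labels[i], 0.0) for i in range(n)}
        for k, (a, b, height, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            (sa, ha), (sb, hb) = nodes.pop(a), nodes.pop(b)
            la, lb = max(height - ha, 0.0), max(height - hb, 0.0)
            nodes[n + k] = (f"({sa}:{la:.6g},{sb}:{lb:.6g})", height)
        (tree, _), = nodes.values()
        return tree + ";"


def cluster_columns(matrix: np.ndarray, labels: List[str]) -> TimepointClustering:
    """Cluster the columns of ``matrix`` (Euclidean distance, average linkage).

    Requires at least 3 columns; returns the merge tree and the 2-group cut.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != len(labels):
        raise ParameterError("matrix/label shape mismatch")
    if matrix.shape[1] < 3:
        raise ParameterError("need at least 3 columns to cluster")
    dist = pdist(matrix.T, metric="euclidean")
    lk = linkage(dist, method="average")
    assign = fcluster(lk, t=2, criterion="maxclust")
    g1 = frozenset(l for l, a in zip(labels, assign) if a == assign[0])
    g2 = frozenset(l for l, a in zip(labels, assign) if a != assign[0])
    return TimepointClustering(labels=list(labels), linkage_matrix=lk, two_cut=(g1, g2))
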