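"""Topology metrics for typed directed networks.

Six per-network measures: mean out-degree over regulators (targets per
TF/miRNA), mean in-degree over regulated targets, clustering coefficient,
average directed shortest-path length over reachable pairs, betweenness
(unnormalized sum of geodesic fractions), and reachability (fraction of
other nodes reachable by directed paths).  A size-matched random-subnetwork
null re-samples nodes per type from the IRN and re-applies backtrack +
wiring; the perturbation curve removes the highest-degree node step by step
and counts newly isolated singletons.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, List, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .active import backtrack_closure
from .exceptions import ParameterError, UnknownEntityError
from .network import GENE, MIRNA, TF, REGULATOR_TYPES, TypedNetwork

METRIC_NAMES = ("out_degree_mean", "in_degree_mean", "cc_mean", "apl", "bw_mean", "reach_mean")


def clustering_coefficient(net: TypedNetwork, v: str) -> float:
    """Directed clustering coefficient of ``v``.

    Fraction of ordered pairs (i, j), i != j, of the union neighborhood N(v)
    connected by an arc i->j; 0 when |N(v)| < 2.
    """
    nbrs = net.neighbors(v)
    k = len(nbrs)
    if k < 2:
        return 0.0
    arcs = 0
    for i in nbrs:
        arcs += len(net.successors(i) & nbrs)
    return arcs / (k * (k - 1))


def betweenness(net: TypedNetwork, v: str) -> float:
    """Unnormalized directed betweenness: sum over ordered pairs (s, t),
    s != t != v, of the fraction of s->t geodesics through v."""
    if v not in net:
        raise UnknownEntityError(f"unknown node {v!r}")
    return betweenness_all(net)[v]


def betweenness_all(net: TypedNetwork) -> Dict[str, float]:
    g = net.to_networkx()
    return dict(nx.betweenness_centrality(g, normalized=False))


def _bfs_dists(net: TypedNetwork, source: str) -> Dict[str, int]:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in net.successors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def reachability(net: TypedNetwork, v: str) -> float:
    """Fraction of the other |V|−1 nodes reachable from ``v`` by directed paths."""
    if net.n_nodes < 2:
        raise ParameterError("reachability needs >= 2 nodes")
    if v not in net:
        raise UnknownEntityError(f"unknown node {v!r}")
    return (len(_bfs_dists(net, v)) - 1) / (net.n_nodes - 1)


@dataclass
class TopologyReport:
    """Per-network topology summary plus the per-node table behind each mean."""

    out_degree_mean: float
    in_degree_mean: float
    cc_mean: float
    apl: float
    bw_mean: float
    reach_mean: float
    n_reachable_pairs: int
    per_node: pd.DataFrame

    def metrics(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def network_metrics(net: TypedNetwork) -> TopologyReport:
    """All six metrics of a network.

    Denominators follow the regulatory reading: out-degree averages over
    regulators only; in-degree over nodes with at least one regulator; CC,
    betweenness and reachability over all nodes; APL over reachable ordered
    pairs only (count reported).  Means with an empty denominator are NaN.
    """
    if net.n_nodes == 0:
        raise ParameterError("empty network")
    nodes = sorted(net.nodes)
    bw = betweenness_all(net)
    n = net.n_nodes

    rows = []
    total_path = 0
    n_pairs = 0
    for v in nodes:
        dists = _bfs_dists(net, v)
        n_reach = len(dists) - 1
        total_path += sum(dists.values())
        n_pairs += n_reach
        rows.append(
            {
                "node": v,
                "type": net.node_type(v),
                "out_degree": net.out_degree(v),
                "in_degree": net.in_degree(v),
                "cc": clustering_coefficient(net, v),
                "bw": bw[v],
                "reach": n_reach / (n - 1) if n > 1 else np.nan,
            }
        )
    per_node = pd.DataFrame(rows).set_index("node")

    is_reg = per_node["type"].isin(REGULATOR_TYPES)
    regulated = per_node["in_degree"] >= 1
    return TopologyReport(
        out_degree_mean=float(per_node.loc[is_reg, "out_degree"].mean()) if is_reg.any() else float("nan"),
        in_degree_mean=float(per_node.loc[regulated, "in_degree"].mean()) if regulated.any() else float("nan"),
        cc_mean=float(per_node["cc"].mean()),
        apl=(total_path / n_pairs) if n_pairs else float("nan"),
        bw_mean=float(per_node["bw"].mean()),
        reach_mean=float(per_node["reach"].mean()),
        n_reachable_pairs=n_pairs,
        per_node=per_node,
    )


@dataclass
class NullTopology:
    """Mean/SD of each metric over size-matched random sub-networks."""

    mean: Dict[str, float]
    sd: Dict[str, float]
    n_rand: int
    seed: int


def random_subnetwork_null(
    irn: TypedNetwork,
    n_tf: int,
    n_mirna: int,
    n_gene: int,
    n_rand: int,
    seed: int,
) -> NullTopology:
    """Size-matched null: sample the requested node counts per type from the
    IRN, apply backtrack closure and induced wiring, and measure topology.

    NaN metrics (e.g., APL of an arcless replicate) are excluded per-metric
    via nanmean/nanstd (sample SD).
    """
    if n_rand < 2:
        raise ParameterError("n_rand must be >= 2")
    pools = {TF: sorted(irn.nodes_of_type(TF)), MIRNA: sorted(irn.nodes_of_type(MIRNA)), GENE: sorted(irn.nodes_of_type(GENE))}
    wanted = {TF: n_tf, MIRNA: n_mirna, GENE: n_gene}
    for ntype, k in wanted.items():
        if k > len(pools[ntype]):
            raise ParameterError(f"requested {k} {ntype} nodes but IRN has {len(pools[ntype])}")
    rng = np.random.default_rng(seed)
    values = {name: [] for name in METRIC_NAMES}
    for _ in range(n_rand):
        sample: List[str] = []
        for ntype, k in wanted.items():
            if k:
                sample.extend(rng.choice(pools[ntype], size=k, replace=False))
        closed = backtrack_closure(sample, irn)
        report = network_metrics(irn.induced_subgraph(closed))
        for name, val in report.metrics().items():
            values[name].append(val)
    mean = {k: float(np.nanmean(v)) for k, v in values.items()}
    sd = {k: float(np.nanstd(v, ddof=1)) for k, v in values.items()}
    return NullTopology(mean=mean, sd=sd, n_rand=n_rand, seed=seed)


@dataclass
class PerturbationCurve:
    """Singleton counts along sequential highest-degree (hub) removal."""

    steps: List[Tuple[str, int]]

    def singletons(self) -> List[int]:
        return [s for _, s in self.steps]


def perturb_hubs(net: TypedNetwork, k_max: int) -> PerturbationCurve:
    """Remove the current highest-total-degree node ``k_max`` times (ties by
    lexicographic id, degree recomputed each step) and count singletons:
    remaining nodes of degree 0 that had degree > 0 in the input network."""
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    if k_max > net.n_nodes:
        raise ParameterError("k_max exceeds node count")
    succ = {v: set(net.successors(v)) for v in net.nodes}
    pred = {v: set(net.predecessors(v)) for v in net.nodes}
    originally_connected = {v for v in net.nodes if succ[v] or pred[v]}
    steps: List[Tuple[str, int]] = []
    for _ in range(k_max):
        hub = min(succ, key=lambda v: (-(len(succ[v]) + len(pred[v])), v))
        for t in succ[hub]:
            pred[t].discard(hub)
        for s in pred[hub]:
            succ[s].discard(hub)
        del succ[hub], pred[hub]
        singles = sum(
            1 for v in succ if not succ[v] and not pred[v] and v in originally_connected
        )
        steps.append((hub, singles))
    return PerturbationCurve(steps=steps)
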