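"""Synthetic regulatory networks, expression time courses, and annotations.

The generators emulate the statistical structure the analysis assumes in the
developing-retina setting: a hub-dominated static network of TFs, miRNAs and
target genes; log2 expression profiles over ~6 ordered time points organized
in clusters peaking at distinct times; miRNA–target anti-correlation with a
small positively correlated tail; and per-time-point active networks in two
regimes — densely interconnected "early" networks and modular, hub-centered
"late" networks.  Every generator is a pure function of its config (seed
mandatory): reruns are bit-identical, and each emits a manifest sufficient
to verify the planted structure.

Seed splitting: generator k draws from
``numpy.random.SeedSequence(cfg.seed, spawn_key=(k,))`` with k = 0 (network),
1 (expression), 2 (regimes), 3 (annotations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .active import ActiveSubnetwork
from .enrichment import AnnotationCollection
from .exceptions import ParameterError
from .expression import EntityCluster, ExpressionMatrix
from .network import GENE, MIRNA, TF, TypedNetwork

logger = logging.getLogger(__name__)

EARLY, LATE = "early", "late"
_STREAM = {"irn": 0, "expression": 1, "regimes": 2, "annotations": 3}


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults are a desk-scale rendition of the study system: 10 TFs, 30
    miRNAs, 800 genes over 6 time points; regulator out-degrees follow a
    capped discrete power law (exponent 2.5, hub-dominated); expression
    clusters peak at distinct time points with log2 amplitude 4 and noise SD
    0.5; 30% of miRNA→gene pairs are anti-correlated (noise SD 0.2) with a 5%
    positively correlated tail; 50 feed-forward loops are planted in the
    static network; the time course splits into 3 early- and 3 late-regime
    active networks.
    """

    seed: Optional[int] = None

    # static network
    n_tf: int = 10
    n_mirna: int = 30
    n_gene: int = 800
    out_degree_exponent: float = 2.5
    out_degree_min: int = 2
    out_degree_cap: int = 80
    p_target_gene: float = 0.9
    planted_motifs: Dict[str, int] = field(default_factory=lambda: {"FFL": 50})

    # expression
    n_timepoints: int = 6
    n_clusters: int = 6
    baseline: float = 6.0
    cluster_amplitude: float = 4.0
    cluster_width: float = 1.0
    cluster_noise_sd: float = 0.5
    anticorr_fraction: float = 0.3
    poscorr_fraction: float = 0.05
    anticorr_noise_sd: float = 0.2

    # per-time-point regime networks
    regimes: Tuple[str, ...] = (EARLY, EARLY, EARLY, LATE, LATE, LATE)
    regime_n_tf: int = 6
    regime_n_mirna: int = 10
    regime_n_gene: int = 120
    early_regs_per_gene: int = 3
    n_planted_rml: int = 25
    n_planted_ffl: int = 25
    n_planted_crm: int = 15
    n_late_bridges: int = 6

    # annotations
    annotation_fraction: float = 0.8
    annotation_background: int = 10

    def validate(self) -> None:
        if self.seed is None:
            raise ParameterError("SimConfig.seed is mandatory")
        for name in ("n_tf", "n_mirna", "n_gene", "n_timepoints", "n_clusters",
                     "regime_n_tf", "regime_n_mirna", "regime_n_gene"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        for name in ("p_target_gene", "anticorr_fraction", "poscorr_fraction",
                     "annotation_fraction"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.anticorr_fraction + self.poscorr_fraction > 1.0:
            raise ParameterError("anticorr_fraction + poscorr_fraction must be <= 1")
        if any(r not in (EARLY, LATE) for r in self.regimes):
            raise ParameterError("regimes must be 'early' or 'late'")
        if self.n_timepoints != len(self.timepoint_labels):
            raise ParameterError("n_timepoints inconsistent with labels")

    @property
    def timepoint_labels(self) -> List[str]:
        if self.n_timepoints == 6:
            return ["E15", "E18", "P1", "P5", "P12", "Adult"]
        return [f"t{i}" for i in range(self.n_timepoints)]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAM[stream],))
        )


def _node_ids(n_tf: int, n_mirna: int, n_gene: int) -> Tuple[List[str], List[str], List[str]]:
    tfs = [f"TF{i:03d}" for i in range(n_tf)]
    mirnas = [f"miR{i:03d}" for i in range(n_mirna)]
    genes = [f"g{i:05d}" for i in range(n_gene)]
    return tfs, mirnas, genes


def _power_law_degrees(rng: np.random.Generator, n: int, exponent: float,
                       dmin: int, dmax: int) -> np.ndarray:
    raw = rng.zipf(exponent, size=n)
    return np.clip(raw + dmin - 1, dmin, dmax)


def simulate_irn(cfg: SimConfig) -> Tuple[TypedNetwork, dict]:
    """Static typed network with heavy-tailed regulator out-degrees and the
    requested planted motif instances.  Returns (network, manifest); the
    manifest lists every planted node triple."""
    cfg.validate()
    rng = cfg.rng("irn")
    tfs, mirnas, genes = _node_ids(cfg.n_tf, cfg.n_mirna, cfg.n_gene)
    regulators = tfs + mirnas
    node_types = {v: TF for v in tfs}
    node_types.update({v: MIRNA for v in mirnas})
    node_types.update({v: GENE for v in genes})

    arcs: set = set()
    degrees = _power_law_degrees(rng, len(regulators), cfg.out_degree_exponent,
                                 cfg.out_degree_min, cfg.out_degree_cap)
    gene_arr = np.array(genes)
    for reg, d in zip(regulators, degrees):
        others = [r for r in regulators if r != reg]
        n_gene_tgt = int(rng.binomial(d, cfg.p_target_gene))
        n_gene_tgt = min(n_gene_tgt, len(genes))
        n_reg_tgt = min(int(d) - n_gene_tgt, len(others))
        for tgt in rng.choice(gene_arr, size=n_gene_tgt, replace=False):
            arcs.add((reg, str(tgt)))
        if n_reg_tgt > 0:
            for tgt in rng.choice(others, size=n_reg_tgt, replace=False):
                arcs.add((reg, str(tgt)))

    planted: Dict[str, List[Tuple[str, str, str]]] = {}
    used_genes: set = set()
    for family, count in cfg.planted_motifs.items():
        if count < 0:
            raise ParameterError("planted motif count must be >= 0")
        free_genes = [g for g in genes if g not in used_genes]
        if count > len(free_genes) or (family != "SIM" and (not tfs or not mirnas)):
            raise ParameterError(f"infeasible planting of {count} {family} motifs")
        triples: List[Tuple[str, str, str]] = []
        for i in range(count):
            c = free_genes[i]
            used_genes.add(c)
            for _ in range(100):
                a = tfs[int(rng.integers(len(tfs)))]
                b = mirnas[int(rng.integers(len(mirnas)))]
                if family == "FFL" and (b, a) in arcs:
                    continue  # a 2-cycle would reclassify the triple
                if family == "CRM" and ((a, b) in arcs or (b, a) in arcs):
                    continue
                break
            if family == "FFL":
                arcs.update([(a, b), (a, c), (b, c)])
            elif family == "RML":
                arcs.update([(a, b), (b, a), (a, c)])
            elif family == "CRM":
                arcs.update([(a, c), (b, c)])
            else:
                raise ParameterError(f"unknown planted motif family {family!r}")
            triples.append((a, b, c))
        planted[family] = triples

    net = TypedNetwork(node_types, arcs)
    manifest = {
        "planted": {fam: [list(t) for t in trips] for fam, trips in planted.items()},
        "n_arcs": net.n_arcs,
        "seed": cfg.seed,
    }
    return net, manifest


def _reflect(profile: np.ndarray) -> np.ndarray:
    """Mirror a profile around its mean (perfect anti-correlation)."""
    return 2.0 * profile.mean() - profile


def simulate_expression(cfg: SimConfig, net: TypedNetwork) -> Tuple[ExpressionMatrix, dict]:
    """Clustered log2 time courses for every network node, with a configured
    fraction of miRNA→gene target pairs rewritten to anti-correlated (and a
    small tail to positively correlated) profiles.

    The manifest records cluster assignments and the realized correlation of
    every rewritten pair.
    """
    cfg.validate()
    rng = cfg.rng("expression")
    ids = sorted(net.nodes)
    types = {v: net.node_type(v) for v in ids}
    T = cfg.n_timepoints
    t_axis = np.arange(T, dtype=float)
    peaks = np.linspace(0, T - 1, cfg.n_clusters)

    assign = rng.integers(0, cfg.n_clusters, size=len(ids))
    values = np.empty((len(ids), T))
    for row, (eid, k) in enumerate(zip(ids, assign)):
        bump = cfg.cluster_amplitude * np.exp(-0.5 * ((t_axis - peaks[k]) / cfg.cluster_width) ** 2)
        values[row] = cfg.baseline + bump + rng.normal(0.0, cfg.cluster_noise_sd, size=T)

    index = {eid: i for i, eid in enumerate(ids)}
    mt_arcs = [
        (m, g)
        for m in sorted(net.nodes_of_type(MIRNA))
        for g in sorted(net.successors(m))
        if types[g] == GENE
    ]
    order = rng.permutation(len(mt_arcs))
    n_anti = int(round(cfg.anticorr_fraction * len(mt_arcs)))
    n_pos = int(round(cfg.poscorr_fraction * len(mt_arcs)))
    rewritten: Dict[str, str] = {}
    pair_cc: List[Tuple[str, str, str, float]] = []
    for rank, arc_i in enumerate(order[: n_anti + n_pos]):
        m, g = mt_arcs[arc_i]
        if g in rewritten:
            continue
        mode = "anti" if rank < n_anti else "pos"
        mprof = values[index[m]]
        base = _reflect(mprof) if mode == "anti" else mprof.copy()
        values[index[g]] = base + rng.normal(0.0, cfg.anticorr_noise_sd, size=T)
        rewritten[g] = mode
        gprof = values[index[g]]
        mc, gc = mprof - mprof.mean(), gprof - gprof.mean()
        denom = np.linalg.norm(mc) * np.linalg.norm(gc)
        cc = float(mc @ gc / denom) if denom > 0 else float("nan")
        pair_cc.append((m, g, mode, cc))

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=ids, columns=cfg.timepoint_labels),
        pd.Series({v: types[v] for v in ids}),
    )
    manifest = {
        "clusters": {eid: int(k) for eid, k in zip(ids, assign)},
        "rewritten_pairs": [
            {"mirna": m, "gene": g, "mode": mode, "cc": cc} for m, g, mode, cc in pair_cc
        ],
        "seed": cfg.seed,
    }
    return expr, manifest


def _regime_types(tfs, mirnas, genes) -> Dict[str, str]:
    types = {v: TF for v in tfs}
    types.update({v: MIRNA for v in mirnas})
    types.update({v: GENE for v in genes})
    return types


def _early_network(cfg: SimConfig, rng: np.random.Generator,
                   tfs: List[str], mirnas: List[str], genes: List[str]) -> Tuple[TypedNetwork, dict]:
    """Densely interconnected regime: every gene redundantly regulated by
    several regulators, plus planted mutual (2-cycle) regulator pairs, each
    with an attached third gene.  Reg–reg arcs exist *only* inside the mutual
    pairs, so the swap null cannot reproduce the reciprocity."""
    regulators = tfs + mirnas
    arcs: set = set()
    k = min(cfg.early_regs_per_gene, len(regulators))
    for g in genes:
        for reg in rng.choice(regulators, size=k, replace=False):
            arcs.add((str(reg), g))
    pairs = [(regulators[i], regulators[j])
             for i in range(len(regulators)) for j in range(i + 1, len(regulators))]
    if cfg.n_planted_rml > len(pairs):
        raise ParameterError("infeasible RML planting")
    pick = rng.permutation(len(pairs))[: cfg.n_planted_rml]
    planted = []
    for pi in pick:
        a, b = pairs[pi]
        c = genes[int(rng.integers(len(genes)))]
        arcs.update([(a, b), (b, a), (a, c)])
        planted.append((a, b, c))
    return TypedNetwork(_regime_types(tfs, mirnas, genes), arcs), {
        "RML": [list(t) for t in planted]
    }


def _late_network(cfg: SimConfig, rng: np.random.Generator,
                  tfs: List[str], mirnas: List[str], genes: List[str]) -> Tuple[TypedNetwork, dict]:
    """Modular hub-centered regime: each regulator owns an exclusive block of
    module genes (star wiring), a handful of one-way hub→hub bridges, and
    planted FFLs / CRMs whose shared targets come from a reserved gene pool
    regulated by exactly the two planted regulators."""
    regulators = tfs + mirnas
    n_reserved = cfg.n_planted_ffl + cfg.n_planted_crm
    if n_reserved >= len(genes):
        raise ParameterError("infeasible FFL/CRM planting: too few genes")
    module_genes, reserved = genes[: len(genes) - n_reserved], genes[len(genes) - n_reserved:]
    arcs: set = set()
    blocks = np.array_split(np.arange(len(module_genes)), len(regulators))
    for hub_i, block in enumerate(blocks):
        for gi in block:
            arcs.add((regulators[hub_i], module_genes[gi]))
    # sparse one-way bridges between modules
    n_bridges = 0
    while n_bridges < cfg.n_late_bridges:
        i, j = rng.integers(len(regulators), size=2)
        a, b = regulators[i], regulators[j]
        if a != b and (a, b) not in arcs and (b, a) not in arcs:
            arcs.add((a, b))
            n_bridges += 1

    def pick_pair(allow_forward: bool):
        for _ in range(500):
            i, j = rng.integers(len(regulators), size=2)
            a, b = regulators[i], regulators[j]
            if a == b or (b, a) in arcs:
                continue
            if not allow_forward and (a, b) in arcs:
                continue
            return a, b
        raise ParameterError("could not find a plantable regulator pair")

    planted_ffl, planted_crm = [], []
    res_iter = iter(reserved)
    for _ in range(cfg.n_planted_ffl):
        a, b = pick_pair(allow_forward=True)
        c = next(res_iter)
        arcs.update([(a, b), (a, c), (b, c)])
        planted_ffl.append((a, b, c))
    for _ in range(cfg.n_planted_crm):
        a, b = pick_pair(allow_forward=False)
        c = next(res_iter)
        arcs.update([(a, c), (b, c)])
        planted_crm.append((a, b, c))
    return TypedNetwork(_regime_types(tfs, mirnas, genes), arcs), {
        "FFL": [list(t) for t in planted_ffl],
        "CRM": [list(t) for t in planted_crm],
    }


def simulate_regimes(cfg: SimConfig) -> Tuple[List[ActiveSubnetwork], dict]:
    """One active-subnetwork-shaped network per time point.

    Early-regime networks are densely cross-wired (high clustering, short
    paths, redundant gene regulation, planted TF⇄miRNA mutual loops); late
    ones are hub-and-spoke modules sparsely bridged (low clustering, central
    hubs, planted FFLs and CRMs).  The manifest records the regime and the
    planted triples per time point.
    """
    cfg.validate()
    if len(cfg.regimes) != cfg.n_timepoints:
        raise ParameterError("regimes length must equal n_timepoints")
    children = np.random.SeedSequence(cfg.seed, spawn_key=(_STREAM["regimes"],)).spawn(
        cfg.n_timepoints
    )
    tfs, mirnas, genes = _node_ids(cfg.regime_n_tf, cfg.regime_n_mirna, cfg.regime_n_gene)
    subnets: List[ActiveSubnetwork] = []
    manifest: dict = {"regimes": {}, "planted": {}, "seed": cfg.seed}
    for label, regime, child in zip(cfg.timepoint_labels, cfg.regimes, children):
        rng = np.random.default_rng(child)
        build = _early_network if regime == EARLY else _late_network
        net, planted = build(cfg, rng, tfs, mirnas, genes)
        subnets.append(
            ActiveSubnetwork(timepoint=label, initial_set=set(net.nodes),
                             closed_set=set(net.nodes), subnet=net)
        )
        manifest["regimes"][label] = regime
        manifest["planted"][label] = planted
    return subnets, manifest


def simulate_annotations(
    cfg: SimConfig,
    clusters: Sequence[EntityCluster],
    universe: Optional[Iterable[str]] = None,
) -> Tuple[AnnotationCollection, dict]:
    """One annotation term per expression cluster: a configured fraction of
    the cluster's members plus background genes drawn from the rest of the
    universe.  The manifest maps each term to its source cluster."""
    cfg.validate()
    if not clusters:
        raise ParameterError("no clusters supplied")
    rng = cfg.rng("annotations")
    if universe is None:
        universe = set().union(*(set(c.members) for c in clusters))
    universe = sorted(set(universe))
    uni_set = set(universe)
    terms: Dict[str, Tuple[str, List[str]]] = {}
    truth: Dict[str, dict] = {}
    for i, cluster in enumerate(clusters):
        members = [m for m in cluster.members if m in uni_set]
        n_keep = int(round(cfg.annotation_fraction * len(members)))
        keep = [str(x) for x in rng.choice(members, size=n_keep, replace=False)] if n_keep else []
        outside = sorted(uni_set - set(cluster.members))
        n_bg = min(cfg.annotation_background, len(outside))
        background = [str(x) for x in rng.choice(outside, size=n_bg, replace=False)] if n_bg else []
        term_id = f"TERM{i:03d}"
        terms[term_id] = (f"synthetic process peaking at {cluster.peak_timepoint}", keep + background)
        truth[term_id] = {"cluster_index": i, "peak": cluster.peak_timepoint,
                          "n_from_cluster": len(keep), "n_background": len(background)}
    collection = AnnotationCollection.build(terms, universe)
    return collection, {"terms": truth, "seed": cfg.seed}
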