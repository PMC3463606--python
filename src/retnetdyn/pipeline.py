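"""End-to-end orchestration.

``run_all`` executes the full analysis in dependency order — simulate (or
load) the inputs, miRNA–target correlation test, per-time-point active
sub-networks, topology + size-matched null, motif Z-profiles + dynamics +
time-point clustering, and functional enrichment — writing every artifact
with provenance (stage, seed, config hash) and skipping completed stages on
rerun unless forced.  Per-stage seeds are split from the master seed via
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import active, enrichment, expression, motif, network, syndata, topology
from .exceptions import ParameterError

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "correlate", "active", "topology", "motifs", "enrich")


@dataclass
class RunConfig:
    """Configuration for a full run.

    Either ``synthetic`` is true (inputs generated from ``sim`` with the run
    seed) or the three input paths must exist.  Null-model sizes default to
    the analysis conventions: 300 random sub-networks for the topology null
    and 1000 randomizations for the motif and correlation nulls.
    """

    out_dir: str
    seed: int = 0
    synthetic: bool = True
    sim: syndata.SimConfig = field(default_factory=syndata.SimConfig)
    tf_edges: Optional[str] = None
    mirna_edges: Optional[str] = None
    expression_tsv: Optional[str] = None
    gmt: Optional[str] = None
    activity_rule: str = "percentile:50"
    bin_width: float = 0.05
    corr_n_rand: int = 1000
    topo_null_n_rand: int = 300
    motif_n_rand: int = 1000
    swap_attempts: Optional[int] = None
    require_tf_and_mirna: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        cfg.sim = syndata.SimConfig(**sim_raw)
        return cfg

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("tf_edges", "mirna_edges", "expression_tsv"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ParameterError(f"input path for {name!r} missing or does not exist: {path}")
        if self.synthetic and self.sim.seed is None:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(_STAGES.index(stage),))


def _stage_seed_int(seed: int, stage: str) -> int:
    return int(_stage_seed(seed, stage).generate_state(1)[0] % (2**31))


class _Manifest:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.config_hash = config_hash
        self.data: Dict[str, dict] = {}
        if path.exists():
            stored = json.loads(path.read_text())
            if stored.get("config_hash") == config_hash:
                self.data = stored.get("stages", {})

    def done(self, stage: str) -> bool:
        entry = self.data.get(stage)
        return bool(entry) and all(Path(p).exists() for p in entry.get("outputs", []))

    def record(self, stage: str, outputs: List[str], seed: int) -> None:
        self.data[stage] = {"outputs": outputs, "seed": seed}
        self.path.write_text(
            json.dumps({"config_hash": self.config_hash, "stages": self.data}, indent=2) + "\n"
        )


def run_all(cfg: RunConfig, force: bool = False) -> dict:
    """Run every stage; returns the run manifest as a dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest = _Manifest(out / "manifest.json", chash)

    # -- stage: inputs -----------------------------------------------------
    net_dir = out / "irn"
    expr_path = out / "expression.tsv"
    gmt_path = out / "annotations.gmt"
    if cfg.synthetic:
        if force or not manifest.done("simulate"):
            seed = cfg.sim.seed
            net, irn_manifest = syndata.simulate_irn(cfg.sim)
            expr, expr_manifest = syndata.simulate_expression(cfg.sim, net)
            network.write_network(net, net_dir)
            expr.to_tsv(expr_path)
            clusters = expression.cluster_entities(expr, network.GENE, min_size=2)
            ann, ann_manifest = syndata.simulate_annotations(
                cfg.sim, clusters, universe=expr.ids_of_type(network.GENE)
            )
            ann.to_gmt(gmt_path)
            (out / "sim_manifest.json").write_text(
                json.dumps({"irn": irn_manifest, "expression": expr_manifest,
                            "annotations": ann_manifest}, indent=2) + "\n"
            )
            manifest.record("simulate", [str(net_dir / "arcs.tsv"), str(expr_path), str(gmt_path)], seed)
        net = network.read_network(net_dir)
        expr = expression.ExpressionMatrix.from_tsv(expr_path)
        ann = enrichment.AnnotationCollection.from_gmt(
            gmt_path, universe=expr.ids_of_type(network.GENE)
        )
    else:
        net = network.load_edge_lists(cfg.tf_edges, cfg.mirna_edges)
        network.write_network(net, net_dir)
        expr = expression.ExpressionMatrix.from_tsv(cfg.expression_tsv)
        ann = (
            enrichment.AnnotationCollection.from_gmt(cfg.gmt, universe=expr.ids_of_type(network.GENE))
            if cfg.gmt
            else None
        )

    rule = active.ThresholdRule.parse(cfg.activity_rule)

    # -- stage: miRNA-target correlation test ------------------------------
    if force or not manifest.done("correlate"):
        seed = _stage_seed_int(cfg.seed, "correlate")
        report = expression.target_correlation_z(
            expr, net, bin_width=cfg.bin_width, n_rand=cfg.corr_n_rand, seed=seed
        )
        report.write(out / "correlation_bins.tsv", out / "correlation_bins.json")
        manifest.record("correlate", [str(out / "correlation_bins.tsv")], seed)

    # -- stage: active sub-networks ----------------------------------------
    subnets = [active.extract_active(expr, net, tp, rule) for tp in expr.timepoints]
    if force or not manifest.done("active"):
        outputs = []
        for sn in subnets:
            d = out / "active" / sn.timepoint
            network.write_network(sn.subnet, d)
            outputs.append(str(d / "arcs.tsv"))
        sets = active.specific_sets(expr, rule)
        d = out / "specific_sets"
        d.mkdir(parents=True, exist_ok=True)
        for tp, ids in sets.specific.items():
            (d / f"{tp}.txt").write_text("\n".join(sorted(ids)) + "\n")
        (d / "housekeeping.txt").write_text("\n".join(sorted(sets.housekeeping)) + "\n")
        manifest.record("active", outputs, cfg.seed)

    # -- stage: topology + size-matched null -------------------------------
    if force or not manifest.done("topology"):
        seed = _stage_seed_int(cfg.seed, "topology")
        topo: Dict[str, dict] = {}
        for i, sn in enumerate(subnets):
            report = topology.network_metrics(sn.subnet)
            summary = network.summarize(sn.subnet)
            null = topology.random_subnetwork_null(
                net,
                n_tf=summary.n_tf,
                n_mirna=summary.n_mirna,
                n_gene=summary.n_gene,
                n_rand=cfg.topo_null_n_rand,
                seed=seed + i,
            )
            report.per_node.to_csv(out / "active" / sn.timepoint / "node_metrics.tsv", sep="\t")
            topo[sn.timepoint] = {
                "metrics": report.metrics(),
                "n_reachable_pairs": report.n_reachable_pairs,
                "null_mean": null.mean,
                "null_sd": null.sd,
                "n_rand": null.n_rand,
            }
        (out / "topology.json").write_text(json.dumps(topo, indent=2) + "\n")
        manifest.record("topology", [str(out / "topology.json")], seed)

    # -- stage: motifs ------------------------------------------------------
    if force or not manifest.done("motifs"):
        seed = _stage_seed_int(cfg.seed, "motifs")
        zmat, profiles = motif.motif_dynamics(
            subnets,
            n_rand=cfg.motif_n_rand,
            seed=seed,
            n_swap_attempts=cfg.swap_attempts,
            require_tf_and_mirna=cfg.require_tf_and_mirna,
        )
        for prof in profiles:
            prof.to_frame().to_csv(out / "active" / prof.network_label / "motifs.tsv",
                                   sep="\t", index=False)
        zmat.to_csv(out / "motif_z_matrix.tsv", sep="\t")
        tree = motif.cluster_timepoints(zmat)
        (out / "motif_timepoint_tree.nwk").write_text(tree.newick() + "\n")
        expr_tree = expression.cluster_timepoints(expr)
        (out / "expression_timepoint_tree.nwk").write_text(expr_tree.newick() + "\n")
        (out / "timepoint_cuts.json").write_text(
            json.dumps(
                {
                    "motif_two_cut": [sorted(g) for g in tree.two_cut],
                    "expression_two_cut": [sorted(g) for g in expr_tree.two_cut],
                },
                indent=2,
            )
            + "\n"
        )
        manifest.record("motifs", [str(out / "motif_z_matrix.tsv")], seed)

    # -- stage: enrichment ---------------------------------------------------
    if ann is not None and (force or not manifest.done("enrich")):
        sets = active.specific_sets(expr, rule)
        d = out / "enrichment"
        d.mkdir(parents=True, exist_ok=True)
        outputs = []
        for tp, ids in sets.specific.items():
            genes = {g for g in ids if g in ann.universe}
            if not genes:
                continue
            results = enrichment.enrich(genes, ann)
            path = d / f"{tp}.tsv"
            enrichment.write_enrichment(results, path)
            outputs.append(str(path))
        manifest.record("enrich", outputs, cfg.seed)

    return {"config_hash": chash, "stages": manifest.data}
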