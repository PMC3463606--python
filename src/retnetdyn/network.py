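"""Typed regulatory networks.

The static integrated regulatory network (IRN) combines TF→target and
miRNA→target relationships into a single directed graph whose nodes carry a
type tag: ``TF``, ``miRNA`` or ``gene``.  Only TFs and miRNAs may be arc
sources — a non-regulator gene never regulates.  The same container also
represents every per-time-point active sub-network.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Set, Tuple

from .exceptions import ParameterError, ParseError, TypeConflictError, UnknownEntityError

logger = logging.getLogger(__name__)

TF = "TF"
MIRNA = "miRNA"
GENE = "gene"
NODE_TYPES = (TF, MIRNA, GENE)
REGULATOR_TYPES = frozenset({TF, MIRNA})

Arc = Tuple[str, str]


@dataclass
class LoadReport:
    """Bookkeeping from an edge-list load."""

    n_rows: int = 0
    n_duplicates: int = 0
    n_self_loops: int = 0


class TypedNetwork:
    """A simple directed graph with typed nodes.

    Parameters
    ----------
    node_types
        Mapping from node id to one of ``TF``, ``miRNA``, ``gene``.
    arcs
        Iterable of ``(source, target)`` pairs.  Sources must be typed TF or
        miRNA; self-loops and duplicates are rejected here (loaders drop them
        *before* construction and report counts).
    """

    def __init__(self, node_types: Mapping[str, str], arcs: Iterable[Arc] = ()):
        self._types: Dict[str, str] = {}
        for node, ntype in node_types.items():
            if ntype not in NODE_TYPES:
                raise ParameterError(f"unknown node type {ntype!r} for node {node!r}")
            self._types[str(node)] = ntype
        self._succ: Dict[str, Set[str]] = {v: set() for v in self._types}
        self._pred: Dict[str, Set[str]] = {v: set() for v in self._types}
        for src, tgt in arcs:
            self.add_arc(src, tgt)
        self.load_report: LoadReport | None = None

    # -- construction -----------------------------------------------------
    def add_arc(self, src: str, tgt: str) -> None:
        if src not in self._types or tgt not in self._types:
            raise UnknownEntityError(f"arc ({src!r}, {tgt!r}) references unknown node")
        if src == tgt:
            raise ParameterError(f"self-loop on {src!r} not allowed")
        if self._types[src] not in REGULATOR_TYPES:
            raise ParameterError(f"arc source {src!r} has non-regulator type {self._types[src]!r}")
        self._succ[src].add(tgt)
        self._pred[tgt].add(src)

    # -- basic views ------------------------------------------------------
    @property
    def nodes(self) -> Set[str]:
        return set(self._types)

    @property
    def n_nodes(self) -> int:
        return len(self._types)

    @property
    def n_arcs(self) -> int:
        return sum(len(s) for s in self._succ.values())

    def node_type(self, v: str) -> str:
        try:
            return self._types[v]
        except KeyError:
            raise UnknownEntityError(f"unknown node {v!r}") from None

    def node_types(self) -> Dict[str, str]:
        return dict(self._types)

    def __contains__(self, v: str) -> bool:
        return v in self._types

    def arcs(self) -> Iterator[Arc]:
        for src in self._succ:
            for tgt in self._succ[src]:
                yield (src, tgt)

    def arc_set(self) -> Set[Arc]:
        return set(self.arcs())

    def has_arc(self, src: str, tgt: str) -> bool:
        return src in self._succ and tgt in self._succ[src]

    def successors(self, v: str) -> Set[str]:
        if v not in self._types:
            raise UnknownEntityError(f"unknown node {v!r}")
        return set(self._succ[v])

    def predecessors(self, v: str) -> Set[str]:
        if v not in self._types:
            raise UnknownEntityError(f"unknown node {v!r}")
        return set(self._pred[v])

    def neighbors(self, v: str) -> Set[str]:
        """N(v): union of in- and out-neighbors."""
        if v not in self._types:
            raise UnknownEntityError(f"unknown node {v!r}")
        return self._succ[v] | self._pred[v]

    def out_degree(self, v: str) -> int:
        return len(self._succ[v])

    def in_degree(self, v: str) -> int:
        return len(self._pred[v])

    def degree(self, v: str) -> int:
        return len(self._succ[v]) + len(self._pred[v])

    def nodes_of_type(self, ntype: str) -> Set[str]:
        return {v for v, t in self._types.items() if t == ntype}

    def regulators(self) -> Set[str]:
        return {v for v, t in self._types.items() if t in REGULATOR_TYPES}

    # -- derived networks -------------------------------------------------
    def induced_subgraph(self, nodes: Iterable[str]) -> "TypedNetwork":
        keep = set(nodes)
        unknown = keep - set(self._types)
        if unknown:
            raise UnknownEntityError(f"unknown nodes in induced_subgraph: {sorted(unknown)[:5]}")
        sub_types = {v: self._types[v] for v in keep}
        sub_arcs = [(s, t) for s in keep for t in self._succ[s] if t in keep]
        return TypedNetwork(sub_types, sub_arcs)

    def copy(self) -> "TypedNetwork":
        return TypedNetwork(self._types, self.arcs())

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for v, t in self._types.items():
            g.add_node(v, ntype=t)
        g.add_edges_from(self.arcs())
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, TypedNetwork):
            return NotImplemented
        return self._types == other._types and self.arc_set() == other.arc_set()

    def __repr__(self) -> str:
        return f"TypedNetwork(n_nodes={self.n_nodes}, n_arcs={self.n_arcs})"


@dataclass
class NetworkSummary:
    """Composition of a typed network: node counts and arc counts by regulator type."""

    n_tf: int
    n_mirna: int
    n_gene: int
    n_tf_arcs: int
    n_mirna_arcs: int
    n_arcs_total: int = field(default=0)

    def __post_init__(self):
        expected = self.n_tf_arcs + self.n_mirna_arcs
        if self.n_arcs_total == 0:
            self.n_arcs_total = expected
        elif self.n_arcs_total != expected:
            raise ParameterError("n_arcs_total inconsistent with per-type arc counts")

    def to_dict(self) -> Dict[str, int]:
        return {
            "n_tf": self.n_tf,
            "n_mirna": self.n_mirna,
            "n_gene": self.n_gene,
            "n_tf_arcs": self.n_tf_arcs,
            "n_mirna_arcs": self.n_mirna_arcs,
            "n_arcs_total": self.n_arcs_total,
        }


def _parse_edge_file(path) -> Iterator[Tuple[int, str, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}")
            reg, tgt = (f.strip() for f in fields)
            if not reg or not tgt:
                raise ParseError(f"{path}:{lineno}: empty identifier")
            yield lineno, reg, tgt


def load_edge_lists(tf_edges, mirna_edges) -> TypedNetwork:
    """Build the IRN from a TF→target and a miRNA→target edge list.

    The file of origin fixes the regulator type; an id regulating in both
    files is a type conflict.  Ids appearing only as targets are typed
    ``gene``; a regulator listed as someone's target keeps its regulator
    type.  Duplicate rows collapse; self-loops are dropped and counted in
    the attached :class:`LoadReport`.
    """
    report = LoadReport()
    rows: list[Tuple[str, str, str]] = []  # (regulator, target, regulator_type)
    tf_regs: Set[str] = set()
    mirna_regs: Set[str] = set()
    for path, rtype, regs in ((tf_edges, TF, tf_regs), (mirna_edges, MIRNA, mirna_regs)):
        if path is None:
            continue
        for _, reg, tgt in _parse_edge_file(path):
            report.n_rows += 1
            regs.add(reg)
            rows.append((reg, tgt, rtype))
    conflict = tf_regs & mirna_regs
    if conflict:
        raise TypeConflictError(
            f"ids appear as regulators in both files: {sorted(conflict)[:5]}"
        )

    node_types: Dict[str, str] = {}
    for reg in tf_regs:
        node_types[reg] = TF
    for reg in mirna_regs:
        node_types[reg] = MIRNA
    for reg, tgt, _ in rows:
        node_types.setdefault(tgt, GENE)

    arcs: Set[Arc] = set()
    for reg, tgt, _ in rows:
        if reg == tgt:
            report.n_self_loops += 1
            continue
        if (reg, tgt) in arcs:
            report.n_duplicates += 1
            continue
        arcs.add((reg, tgt))

    net = TypedNetwork(node_types, arcs)
    net.load_report = report
    logger.info(
        "loaded %d rows -> %d arcs (%d duplicates collapsed, %d self-loops dropped)",
        report.n_rows, len(arcs), report.n_duplicates, report.n_self_loops,
    )
    return net


def summarize(net: TypedNetwork) -> NetworkSummary:
    """Node counts by type and arc counts by regulator type."""
    n_tf_arcs = 0
    n_mirna_arcs = 0
    for src, _ in net.arcs():
        if net.node_type(src) == TF:
            n_tf_arcs += 1
        else:
            n_mirna_arcs += 1
    return NetworkSummary(
        n_tf=len(net.nodes_of_type(TF)),
        n_mirna=len(net.nodes_of_type(MIRNA)),
        n_gene=len(net.nodes_of_type(GENE)),
        n_tf_arcs=n_tf_arcs,
        n_mirna_arcs=n_mirna_arcs,
    )


def write_network(net: TypedNetwork, out_dir) -> None:
    """Canonical network dump: arcs.tsv, nodes.tsv, summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "arcs.tsv", "w") as fh:
        fh.write("source\ttarget\tsource_type\n")
        for src, tgt in sorted(net.arcs()):
            fh.write(f"{src}\t{tgt}\t{net.node_type(src)}\n")
    with open(out / "nodes.tsv", "w") as fh:
        fh.write("node\ttype\n")
        for v in sorted(net.nodes):
            fh.write(f"{v}\t{net.node_type(v)}\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summarize(net).to_dict(), fh, indent=2)
        fh.write("\n")


def read_network(in_dir) -> TypedNetwork:
    """Load a network written by :func:`write_network`."""
    path = Path(in_dir)
    node_types: Dict[str, str] = {}
    with open(path / "nodes.tsv") as fh:
        header = fh.readline()
        if not header.startswith("node"):
            raise ParseError(f"{path/'nodes.tsv'}: missing header")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path/'nodes.tsv'}:{lineno}: expected 2 columns")
            node_types[fields[0]] = fields[1]
    arcs = []
    with open(path / "arcs.tsv") as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path/'arcs.tsv'}:{lineno}: expected 3 columns")
            arcs.append((fields[0], fields[1]))
    return TypedNetwork(node_types, arcs)
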