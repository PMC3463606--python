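"""Typed size-3 network motifs.

Connected 3-node induced sub-graphs are enumerated with Wernicke's ESU
algorithm and classified up to *typed* isomorphism: two sub-graphs share a
canonical label iff some node bijection preserves both arc structure and
node types (TF / miRNA / gene).  Families follow the standard regulatory
vocabulary: RML (two regulators locked in a mutual 2-cycle plus an attached
third node), FFL (A→B, A→C, B→C), SIM (one regulator, two targets, nothing
else), CRM (two regulators, one shared target, nothing else).

Significance is measured against degree-preserving randomizations: double
arc swaps restricted to arcs with the same (source type, target type) pair,
which conserve every node's in/out degree *and* the type composition of its
in- and out-neighborhoods.  Z = (observed − null mean) / null SD.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._cluster import TimepointClustering, cluster_columns
from .active import ActiveSubnetwork
from .exceptions import ParameterError
from .network import GENE, MIRNA, TF, REGULATOR_TYPES, TypedNetwork

logger = logging.getLogger(__name__)

_TYPE_CODE = {TF: 0, MIRNA: 1, GENE: 2}
_TYPE_CHAR = "TMG"
# fixed ordered-pair order used in every serialization
_PAIRS = ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1))

RML, FFL, SIM, CRM, OTHER = "RML", "FFL", "SIM", "CRM", "other"


@dataclass(frozen=True)
class TypedMotif:
    """A typed-isomorphism class of a connected 3-node sub-graph."""

    canonical_label: str
    family: str


def _serialize(types: Sequence[int], arcs: frozenset) -> str:
    bits = "".join("1" if p in arcs else "0" for p in _PAIRS)
    return f"{_TYPE_CHAR[types[0]]}{_TYPE_CHAR[types[1]]}{_TYPE_CHAR[types[2]]}:{bits}"


def _family(types: Sequence[int], arcs: frozenset) -> str:
    mutual_pairs = [(i, j) for i in range(3) for j in range(i + 1, 3)
                    if (i, j) in arcs and (j, i) in arcs]
    for i, j in mutual_pairs:
        if types[i] != _TYPE_CODE[GENE] and types[j] != _TYPE_CODE[GENE]:
            return RML
    n = len(arcs)
    outd = [sum(1 for (i, j) in arcs if i == k) for k in range(3)]
    ind = [sum(1 for (i, j) in arcs if j == k) for k in range(3)]
    if not mutual_pairs and n == 3 and sorted(outd) == [0, 1, 2] and sorted(ind) == [0, 1, 2]:
        return FFL
    if n == 2:
        if 2 in outd:
            return SIM
        if 2 in ind:
            return CRM
    return OTHER


def _connected(arcs: frozenset) -> bool:
    adj = {0: set(), 1: set(), 2: set()}
    for i, j in arcs:
        adj[i].add(j)
        adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == 3


def canonical_typed_label(types: Sequence[str], arcs: Iterable[Tuple[int, int]]) -> TypedMotif:
    """Canonical label + family of a typed 3-node sub-graph.

    ``types`` are three node-type strings for nodes 0, 1, 2; ``arcs`` are
    ordered index pairs.  The label is the lexicographic minimum over all 6
    node permutations of a fixed serialization, so isomorphic sub-graphs —
    and only those — collide.
    """
    if len(types) != 3:
        raise ParameterError("exactly 3 nodes required")
    tcodes = tuple(_TYPE_CODE[t] for t in types)
    arcset = frozenset((int(i), int(j)) for i, j in arcs)
    for i, j in arcset:
        if i == j or not (0 <= i <= 2 and 0 <= j <= 2):
            raise ParameterError(f"invalid arc ({i}, {j})")
    best = None
    for perm in permutations(range(3)):
        # node k of the original becomes node perm[k]
        ptypes = [0, 0, 0]
        for k in range(3):
            ptypes[perm[k]] = tcodes[k]
        parcs = frozenset((perm[i], perm[j]) for i, j in arcset)
        s = _serialize(ptypes, parcs)
        if best is None or s < best:
            best = s
    return TypedMotif(canonical_label=best, family=_family(tcodes, arcset))


# precomputed (t0, t1, t2, bits) -> (label, family) over all typed 3-node digraphs
_LABEL_TABLE: Dict[Tuple[int, int, int, int], Tuple[str, str]] = {}


def _label_table() -> Dict[Tuple[int, int, int, int], Tuple[str, str]]:
    if _LABEL_TABLE:
        return _LABEL_TABLE
    type_names = {v: k for k, v in _TYPE_CODE.items()}
    for t0 in range(3):
        for t1 in range(3):
            for t2 in range(3):
                for bits in range(64):
                    arcs = frozenset(p for k, p in enumerate(_PAIRS) if bits >> k & 1)
                    motif = canonical_typed_label(
                        [type_names[t0], type_names[t1], type_names[t2]], arcs
                    )
                    _LABEL_TABLE[(t0, t1, t2, bits)] = (motif.canonical_label, motif.family)
    return _LABEL_TABLE


def family_of(label: str) -> str:
    """Family tag of a canonical label."""
    tcodes = tuple(_TYPE_CODE[{"T": TF, "M": MIRNA, "G": GENE}[c]] for c in label[:3])
    arcs = frozenset(p for k, p in enumerate(_PAIRS) if label[4 + k] == "1")
    return _family(tcodes, arcs)


class _IndexedNet:
    """Integer-indexed adjacency view of a TypedNetwork for tight loops."""

    def __init__(self, net: TypedNetwork):
        self.ids = sorted(net.nodes)
        index = {v: i for i, v in enumerate(self.ids)}
        self.tcode = [_TYPE_CODE[net.node_type(v)] for v in self.ids]
        n = len(self.ids)
        self.out: List[set] = [set() for _ in range(n)]
        und: List[set] = [set() for _ in range(n)]
        for s, t in net.arcs():
            si, ti = index[s], index[t]
            self.out[si].add(ti)
            und[si].add(ti)
            und[ti].add(si)
        self.und_sets = und
        self.und = [sorted(s) for s in und]


def _iter_triples(ix: _IndexedNet) -> Iterator[Tuple[int, int, int]]:
    """ESU for k = 3: each connected triple exactly once."""
    und, und_sets = ix.und, ix.und_sets
    for v in range(len(ix.ids)):
        nv = und_sets[v]
        ext = [u for u in und[v] if u > v]
        for i, u in enumerate(ext):
            for w in ext[i + 1:]:
                yield v, u, w
            for w in und[u]:
                if w > v and w not in nv:
                    yield v, u, w


def enumerate_size3(net: TypedNetwork) -> Iterator[Tuple[str, str, str]]:
    """Yield each connected 3-node induced sub-graph once, as a node-id triple."""
    ix = _IndexedNet(net)
    for a, b, c in _iter_triples(ix):
        yield (ix.ids[a], ix.ids[b], ix.ids[c])


def label_triple(net: TypedNetwork, triple: Sequence[str]) -> TypedMotif:
    """Canonical motif of the sub-graph induced on three named nodes."""
    a, b, c = triple
    types = [net.node_type(v) for v in triple]
    arcs = []
    for i, s in enumerate(triple):
        for j, t in enumerate(triple):
            if i != j and net.has_arc(s, t):
                arcs.append((i, j))
    return canonical_typed_label(types, arcs)


def count_motifs(net: TypedNetwork, require_tf_and_mirna: bool = False) -> Counter:
    """Counts of connected 3-node induced sub-graphs by canonical label.

    With ``require_tf_and_mirna`` only triples containing at least one TF
    *and* one miRNA are counted.
    """
    table = _label_table()
    ix = _IndexedNet(net)
    tc, out = ix.tcode, ix.out
    counts: Counter = Counter()
    for v, u, w in _iter_triples(ix):
        tv, tu, tw = tc[v], tc[u], tc[w]
        if require_tf_and_mirna:
            ts = (tv, tu, tw)
            if 0 not in ts or 1 not in ts:
                continue
        bits = 0
        ov, ou, ow = out[v], out[u], out[w]
        if u in ov:
            bits |= 1
        if w in ov:
            bits |= 2
        if v in ou:
            bits |= 4
        if w in ou:
            bits |= 8
        if v in ow:
            bits |= 16
        if u in ow:
            bits |= 32
        counts[table[(tv, tu, tw, bits)][0]] += 1
    return counts


# ---------------------------------------------------------------------------
# Degree- and type-preserving randomization
# ---------------------------------------------------------------------------

def typed_edge_swap(
    net: TypedNetwork,
    n_swap_attempts: Optional[int] = None,
    seed=None,
) -> TypedNetwork:
    """Randomize arcs by double swaps within (source type, target type) classes.

    A partner arc with the same type pair is drawn for a uniformly chosen
    arc; the targets are exchanged unless that would create a self-loop or a
    duplicate arc.  Every node's in/out degree and the type composition of
    its in- and out-neighborhoods are conserved exactly.  Default budget is
    10·|E| attempts.  The returned network carries ``swaps_achieved``.
    """
    arcs = sorted(net.arcs())
    types = net.node_types()
    if len(arcs) < 2:
        out = net.copy()
        out.swaps_achieved = 0
        logger.info("typed_edge_swap: fewer than 2 arcs, returning a copy")
        return out
    if n_swap_attempts is None:
        n_swap_attempts = 10 * len(arcs)

    groups: Dict[Tuple[str, str], List[Tuple[str, str]]] = {}
    flat: List[Tuple[Tuple[str, str], int]] = []
    for s, t in arcs:
        key = (types[s], types[t])
        lst = groups.setdefault(key, [])
        flat.append((key, len(lst)))
        lst.append((s, t))
    arc_set = set(arcs)

    rng = np.random.default_rng(seed)
    pick1 = rng.integers(0, len(arcs), size=n_swap_attempts)
    pick2 = rng.random(n_swap_attempts)
    swaps = 0
    for a in range(n_swap_attempts):
        key, i1 = flat[pick1[a]]
        glist = groups[key]
        i2 = int(pick2[a] * len(glist))
        if i1 == i2:
            continue
        s1, t1 = glist[i1]
        s2, t2 = glist[i2]
        if s1 == s2 or t1 == t2 or s1 == t2 or s2 == t1:
            continue
        new1, new2 = (s1, t2), (s2, t1)
        if new1 in arc_set or new2 in arc_set:
            continue
        arc_set.discard((s1, t1))
        arc_set.discard((s2, t2))
        arc_set.add(new1)
        arc_set.add(new2)
        glist[i1] = new1
        glist[i2] = new2
        swaps += 1
    out = TypedNetwork(types, arc_set)
    out.swaps_achieved = swaps
    if swaps == 0:
        logger.info("typed_edge_swap: no swap was possible, returning an arc-identical copy")
    return out


# ---------------------------------------------------------------------------
# Z-scores
# ---------------------------------------------------------------------------

@dataclass
class MotifStat:
    observed: float
    null_mean: float
    null_sd: float
    z: float  # NaN when null_sd == 0
    family: str


@dataclass
class MotifZProfile:
    """Observed motif counts vs the swap-null ensemble, per canonical label
    and aggregated per family."""

    per_label: Dict[str, MotifStat]
    per_family: Dict[str, MotifStat]
    n_rand: int
    seed: int
    network_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "canonical_label": label,
                "family": st.family,
                "observed": st.observed,
                "null_mean": st.null_mean,
                "null_sd": st.null_sd,
                "z": st.z,
            }
            for label, st in sorted(self.per_label.items())
        ]
        return pd.DataFrame(rows)


def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _stats_from_counts(observed: Counter, null_counts: List[Counter], keys, fam) -> Dict[str, MotifStat]:
    out: Dict[str, MotifStat] = {}
    n_rand = len(null_counts)
    for key in sorted(keys):
        obs = float(observed.get(key, 0))
        null = np.array([c.get(key, 0) for c in null_counts], dtype=float)
        mean = float(null.mean())
        sd = float(null.std(ddof=1)) if n_rand > 1 else 0.0
        z = (obs - mean) / sd if sd > 0 else float("nan")
        out[key] = MotifStat(observed=obs, null_mean=mean, null_sd=sd, z=z, family=fam(key))
    return out


def _to_family_counter(counts: Counter) -> Counter:
    fam: Counter = Counter()
    for label, c in counts.items():
        fam[family_of(label)] += c
    return fam


def motif_zscores(
    net: TypedNetwork,
    n_rand: int = 1000,
    n_swap_attempts: Optional[int] = None,
    seed: int = 0,
    require_tf_and_mirna: bool = False,
    network_label: str = "",
) -> MotifZProfile:
    """Motif Z-profile of a network against ``n_rand`` independently swapped
    copies.  Labels seen only in the real network or only in the null are
    included with count 0 on the missing side."""
    if n_rand < 2:
        raise ParameterError("n_rand must be >= 2")
    observed = count_motifs(net, require_tf_and_mirna)
    children = _seed_seq(seed).spawn(n_rand)
    null_counts = [
        count_motifs(typed_edge_swap(net, n_swap_attempts, child), require_tf_and_mirna)
        for child in children
    ]
    keys = set(observed)
    for c in null_counts:
        keys.update(c)
    per_label = _stats_from_counts(observed, null_counts, keys, family_of)
    fam_obs = _to_family_counter(observed)
    fam_null = [_to_family_counter(c) for c in null_counts]
    fam_keys = set(fam_obs)
    for c in fam_null:
        fam_keys.update(c)
    per_family = _stats_from_counts(fam_obs, fam_null, fam_keys, lambda k: k)
    return MotifZProfile(
        per_label=per_label,
        per_family=per_family,
        n_rand=n_rand,
        seed=seed,
        network_label=network_label,
    )


@dataclass
class MutualPairResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float
    n_rand: int
    seed: int


def _count_mutual(net: TypedNetwork) -> int:
    arc_set = net.arc_set()
    return sum(1 for s, t in arc_set if s < t and (t, s) in arc_set)


def count_2node_mutual(
    net: TypedNetwork,
    n_rand: int = 1000,
    seed: int = 0,
    n_swap_attempts: Optional[int] = None,
) -> MutualPairResult:
    """Mutually-regulating regulator pairs (a⇄b) vs the same swap null."""
    if n_rand < 2:
        raise ParameterError("n_rand must be >= 2")
    observed = _count_mutual(net)
    children = _seed_seq(seed).spawn(n_rand)
    null = np.array(
        [_count_mutual(typed_edge_swap(net, n_swap_attempts, child)) for child in children],
        dtype=float,
    )
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    return MutualPairResult(observed=observed, null_mean=mean, null_sd=sd, z=z, n_rand=n_rand, seed=seed)


# ---------------------------------------------------------------------------
# Motif dynamics across time-point networks
# ---------------------------------------------------------------------------

def motif_dynamics(
    subnets: Sequence[ActiveSubnetwork],
    n_rand: int = 1000,
    seed: int = 0,
    n_swap_attempts: Optional[int] = None,
    require_tf_and_mirna: bool = False,
) -> Tuple[pd.DataFrame, List[MotifZProfile]]:
    """Motif × time-point Z matrix over a series of active sub-networks.

    Rows are the union of canonical labels across all networks and nulls;
    undefined Z (zero null SD) is NaN.  All networks share the same null seed
    (common random numbers), so identical networks get identical Z columns.
    """
    if len(subnets) < 2:
        raise ParameterError("need >= 2 sub-networks")
    shared = int(_seed_seq(seed).generate_state(1)[0] % (2**31))
    profiles = [
        motif_zscores(
            sn.subnet,
            n_rand=n_rand,
            n_swap_attempts=n_swap_attempts,
            seed=shared,
            require_tf_and_mirna=require_tf_and_mirna,
            network_label=sn.timepoint,
        )
        for sn in subnets
    ]
    labels = sorted(set().union(*(p.per_label for p in profiles)))
    data = {
        p.network_label: [p.per_label[l].z if l in p.per_label else np.nan for l in labels]
        for p in profiles
    }
    zmat = pd.DataFrame(data, index=labels)
    return zmat, profiles


def cluster_timepoints(z_matrix: pd.DataFrame) -> TimepointClustering:
    """Cluster the time-point columns of a motif Z matrix (missing Z imputed
    as 0; Euclidean distance, average linkage)."""
    filled = z_matrix.fillna(0.0)
    return cluster_columns(filled.to_numpy(), list(z_matrix.columns))
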