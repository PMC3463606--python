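"""Active sub-network extraction.

At each time point the initially active set is every entity expressed above
a threshold (absolute log2 value or per-time-point percentile).  The
backtrack closure then adds every TF/miRNA with an arc into the current set,
regardless of its own expression, until a fixpoint — regulators such as
low-expressed master TFs stay in the analysis.  The active sub-network is the
IRN induced on the closed set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Union

import numpy as np

from .exceptions import ParameterError, UnknownEntityError
from .expression import ExpressionMatrix
from .network import TypedNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdRule:
    """Activity rule: ``kind`` is ``absolute`` (log2 cutoff) or ``percentile``
    (per-time-point percentile cutoff); activity is *strictly greater than*
    the resulting threshold."""

    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in ("absolute", "percentile"):
            raise ParameterError(f"unknown threshold kind {self.kind!r}")
        if self.kind == "percentile" and not (0.0 <= self.value <= 100.0):
            raise ParameterError("percentile must be in [0, 100]")

    @classmethod
    def parse(cls, spec: Union[str, "ThresholdRule"]) -> "ThresholdRule":
        """Parse ``'percentile:50'`` / ``'absolute:4.0'``."""
        if isinstance(spec, ThresholdRule):
            return spec
        try:
            kind, value = spec.split(":")
            return cls(kind=kind.strip(), value=float(value))
        except (ValueError, AttributeError):
            raise ParameterError(f"cannot parse threshold rule {spec!r}") from None

    def cutoff(self, values: np.ndarray) -> float:
        if self.kind == "absolute":
            return self.value
        return float(np.percentile(values, self.value))


DEFAULT_RULE = ThresholdRule("percentile", 50.0)


def initial_active_set(
    expr: ExpressionMatrix, timepoint: str, rule: Union[str, ThresholdRule] = DEFAULT_RULE
) -> Set[str]:
    """Entities expressed strictly above the rule's threshold at ``timepoint``."""
    rule = ThresholdRule.parse(rule)
    if timepoint not in expr.timepoints:
        raise UnknownEntityError(f"unknown timepoint {timepoint!r}")
    col = expr.values[timepoint].to_numpy()
    thr = rule.cutoff(col)
    mask = col > thr
    return set(np.array(expr.entity_ids)[mask])


def backtrack_closure(seed_set: Iterable[str], net: TypedNetwork) -> Set[str]:
    """Smallest superset of ``seed_set`` closed under adding upstream regulators.

    Every TF/miRNA with an arc into a member is added, repeatedly, until no
    regulator is new.  Since only regulators have out-arcs this is reverse
    reachability from the seed set.
    """
    closed = set(seed_set)
    unknown = closed - net.nodes
    if unknown:
        raise UnknownEntityError(f"seed nodes not in network: {sorted(unknown)[:5]}")
    frontier = list(closed)
    while frontier:
        nxt = []
        for v in frontier:
            for reg in net.predecessors(v):
                if reg not in closed:
                    closed.add(reg)
                    nxt.append(reg)
        frontier = nxt
    return closed


@dataclass
class ActiveSubnetwork:
    """A time point's active sub-network: initial set, backtrack closure, and
    the IRN induced on the closure."""

    timepoint: str
    initial_set: Set[str]
    closed_set: Set[str]
    subnet: TypedNetwork


def extract_active(
    expr: ExpressionMatrix,
    net: TypedNetwork,
    timepoint: str,
    rule: Union[str, ThresholdRule] = DEFAULT_RULE,
) -> ActiveSubnetwork:
    """Threshold, backtrack, and wire the active sub-network at a time point.

    Entities above threshold that are absent from the network cannot be wired
    and are excluded from the initial set (count logged).
    """
    active = initial_active_set(expr, timepoint, rule)
    in_net = active & net.nodes
    dropped = len(active) - len(in_net)
    if dropped:
        logger.info("extract_active[%s]: %d active entities not in network", timepoint, dropped)
    closed = backtrack_closure(in_net, net)
    return ActiveSubnetwork(
        timepoint=timepoint,
        initial_set=in_net,
        closed_set=closed,
        subnet=net.induced_subgraph(closed),
    )


@dataclass
class SpecificSets:
    """Per-time-point specifically-active entities and the housekeeping set
    (entities active at every time point)."""

    specific: Dict[str, Set[str]]
    housekeeping: Set[str]


def specific_sets(
    expr: ExpressionMatrix, rule: Union[str, ThresholdRule] = DEFAULT_RULE
) -> SpecificSets:
    """Housekeeping = active at all time points; specific(t) = active(t) minus
    housekeeping.  An entity active at several (but not all) time points is
    specific to each of them."""
    if len(expr.timepoints) < 2:
        raise ParameterError("need >= 2 time points")
    active: Dict[str, Set[str]] = {
        t: initial_active_set(expr, t, rule) for t in expr.timepoints
    }
    housekeeping = set.intersection(*active.values()) if active else set()
    specific = {t: s - housekeeping for t, s in active.items()}
    return SpecificSets(specific=specific, housekeeping=housekeeping)
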