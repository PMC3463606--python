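"""Hypergeometric functional enrichment over GMT annotation sets.

For a query set of size c drawn from a universe of G genes, of which n carry
a term, the p-value is the upper-tail hypergeometric probability P(X >= k)
of observing at least the actual overlap k.  P-values are Bonferroni
corrected over the number of terms tested (terms with at least one universe
gene).  The e-value is the observed/expected overlap ratio k / (c*n/G).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from scipy.stats import hypergeom

from .exceptions import EmptyInputError, ParameterError, ParseError

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCollection:
    """Term → (name, gene set) plus the gene universe.

    Annotated genes outside the universe are dropped (and counted) at
    construction.
    """

    terms: Dict[str, Tuple[str, FrozenSet[str]]]
    universe: FrozenSet[str]
    n_dropped: int = 0

    @classmethod
    def build(
        cls,
        terms: Dict[str, Tuple[str, Iterable[str]]],
        universe: Iterable[str],
    ) -> "AnnotationCollection":
        uni = frozenset(universe)
        clean: Dict[str, Tuple[str, FrozenSet[str]]] = {}
        dropped = 0
        for term_id, (name, genes) in terms.items():
            gset = frozenset(genes)
            keep = gset & uni
            dropped += len(gset) - len(keep)
            clean[term_id] = (name, keep)
        if dropped:
            logger.warning("AnnotationCollection: dropped %d annotated genes outside the universe", dropped)
        return cls(terms=clean, universe=uni, n_dropped=dropped)

    @classmethod
    def from_gmt(cls, path, universe: Optional[Iterable[str]] = None) -> "AnnotationCollection":
        """Read GMT (term_id <tab> term_name <tab> gene...).  If ``universe``
        is omitted it defaults to the union of all annotated genes."""
        terms: Dict[str, Tuple[str, List[str]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: GMT rows need term_id, term_name and >=1 gene")
                terms[fields[0]] = (fields[1], fields[2:])
        if universe is None:
            universe = set().union(*(set(g) for _, g in terms.values())) if terms else set()
        return cls.build(terms, universe)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term_id in sorted(self.terms):
                name, genes = self.terms[term_id]
                fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def hypergeom_p(c: int, k: int, G: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for the overlap X of a
    size-c draw from G genes of which n carry the term."""
    if not (0 <= k <= min(c, n)):
        raise ParameterError(f"need 0 <= k <= min(c, n); got c={c}, k={k}, n={n}")
    if not (0 <= c <= G and 0 <= n <= G):
        raise ParameterError(f"need c <= G and n <= G; got c={c}, n={n}, G={G}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, G, n, c))


def e_value(c: int, k: int, G: int, n: int) -> float:
    """Observed/expected overlap ratio k / (c*n/G)."""
    if G <= 0:
        raise ParameterError("G must be positive")
    if c * n <= 0:
        raise ParameterError("expected overlap c*n/G must be positive")
    return k / (c * n / G)


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    c: int
    k: int
    n: int
    G: int
    p_raw: float
    p_bonferroni: float
    e_value: float


def enrich(query: Iterable[str], annotations: AnnotationCollection) -> List[EnrichmentResult]:
    """Over-representation of each annotation term in a query gene set.

    Query genes outside the universe are dropped (logged).  One result per
    term with overlap k >= 1, Bonferroni-corrected over every term with at
    least one universe gene, sorted by corrected p then descending e-value.
    """
    qset = set(query)
    effective = qset & annotations.universe
    dropped = len(qset) - len(effective)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the universe", dropped)
    if not effective:
        raise EmptyInputError("query has no genes in the universe")
    G = len(annotations.universe)
    c = len(effective)
    tested = {tid: (name, genes) for tid, (name, genes) in annotations.terms.items() if genes}
    n_tests = len(tested)
    results: List[EnrichmentResult] = []
    for term_id, (name, genes) in tested.items():
        k = len(effective & genes)
        if k == 0:
            continue
        n = len(genes)
        p = hypergeom_p(c, k, G, n)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=name,
                c=c,
                k=k,
                n=n,
                G=G,
                p_raw=p,
                p_bonferroni=min(1.0, p * n_tests),
                e_value=e_value(c, k, G, n),
            )
        )
    results.sort(key=lambda r: (r.p_bonferroni, -r.e_value, r.term_id))
    return results


def write_enrichment(results: List[EnrichmentResult], path) -> None:
    import pandas as pd

    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
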