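"""Gene-set over-representation by the hypergeometric upper tail.

Replaces web-service ontology enrichment with an explicit, reproducible
test: for a query of ``n`` genes drawn from a universe of ``N`` annotated
genes, a term annotated to ``K`` genes with ``k`` of them in the query has

    p = P[X >= k],  X ~ Hypergeometric(N, K, n)

i.e. the probability of seeing at least as many query genes in the term's
gene list by chance.  The annotation is a generic (term, gene) relation,
deliberately not tied to any ontology release.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["TermAnnotation", "hypergeom_enrich", "read_term_annotation"]


@dataclass(frozen=True)
class TermAnnotation:
    """Term -> annotated gene sets over a fixed gene universe."""

    terms: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} annotates genes outside the universe")


def read_term_annotation(path: str | Path) -> TermAnnotation:
    """Read a two-column (term TAB gene) annotation file.

    The universe is the union of all annotated genes.
    """
    terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"row {i}: expected 'term<TAB>gene', got {line!r}")
            terms.setdefault(fields[0], set()).add(fields[1])
    universe = frozenset(g for genes in terms.values() for g in genes)
    return TermAnnotation(
        terms={t: frozenset(g) for t, g in terms.items()}, universe=universe
    )


def hypergeom_enrich(
    query: GeneSet | Iterable[str],
    annotation: TermAnnotation,
    correction: str = "bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation for every term.

    Query genes outside the universe are dropped with a warning before
    testing.  Terms with zero overlap are reported with p = 1.  Returns a
    DataFrame indexed by term with columns ``term_size`` (K),
    ``query_size`` (n), ``overlap`` (k), ``p`` and ``p_adj``, sorted by
    ascending p.  ``correction`` is ``"bh"``, ``"bonferroni"`` or
    ``"none"``.
    """
    if correction not in ("bh", "bonferroni", "none"):
        raise ValueError("correction must be 'bh', 'bonferroni' or 'none'")
    if not annotation.universe:
        raise ValueError("empty annotation universe")
    symbols = set(query.symbols if isinstance(query, GeneSet) else query)
    dropped = symbols - annotation.universe
    if dropped:
        logger.warning(
            "%d query gene(s) outside the annotation universe dropped: %s",
            len(dropped), sorted(dropped)[:10],
        )
    in_universe = symbols & annotation.universe
    n = len(in_universe)
    big_n = len(annotation.universe)
    rows = []
    for term in sorted(annotation.terms):
        genes = annotation.terms[term]
        k = len(genes & in_universe)
        # P[X >= k]; survival function is exclusive, hence k - 1
        p = float(stats.hypergeom.sf(k - 1, big_n, len(genes), n)) if k > 0 else 1.0
        rows.append({"term": term, "term_size": len(genes), "query_size": n,
                     "overlap": k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "term_size", "query_size", "overlap", "p"])
    if df.empty:
        df["p_adj"] = []
        return df.set_index("term")
    if correction == "bh":
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    elif correction == "bonferroni":
        df["p_adj"] = (df["p"] * len(df)).clip(upper=1.0)
    else:
        df["p_adj"] = df["p"]
    return df.set_index("term").sort_values(["p", "term_size"], kind="stable")
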