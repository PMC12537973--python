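"""Hypergeometric over-representation analysis (ORA) of a query gene list.

For a universe of N genes, a gene set with K members inside the universe and
a query of n genes, the overlap k follows a hypergeometric distribution
under the null of random draws.  Enrichment significance is the upper tail
P(X >= k) = sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n), evaluated in
log space via the survival function of the hypergeometric distribution.
Benjamini-Hochberg correction is applied across all sets actually tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import P_FLOOR
from .io import GeneSetCollection

__all__ = ["EnrichmentResult", "ora", "member_overlap", "results_to_frame"]

ENRICHMENT_COLUMNS = [
    "set",
    "universe_size",
    "set_size",
    "query_size",
    "overlap",
    "p_value",
    "adjusted_p",
    "overlap_genes",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set ORA outcome; ``overlap_genes`` preserve query order."""

    name: str
    universe_size: int  # N
    set_size: int  # K, after universe intersection
    query_size: int  # n, after universe intersection
    overlap: int  # k
    p_value: float
    adjusted_p: float
    overlap_genes: tuple[str, ...]


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail probability P(X >= k) for overlap k of a size-n draw.

    Exact by construction: P(X >= 0) = 1 and the tail never underflows to 0
    (floored at the smallest positive normal float).
    """
    if k <= 0:
        return 1.0
    return float(max(stats.hypergeom.sf(k - 1, N, K, n), P_FLOOR))


def ora(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    min_set_size: int = 3,
    max_set_fraction: float = 0.5,
) -> list[EnrichmentResult]:
    """Test every gene set for over-representation of the query.

    Query and set members are intersected with the universe before
    counting; sets with fewer than ``min_set_size`` members or more than
    ``max_set_fraction`` of the universe after intersection are excluded
    (standard ORA hygiene against trivially small or near-universal sets).
    Results are sorted by raw p ascending with the set name as tie-break.
    """
    if not universe:
        raise ValueError("universe is empty")
    uni_order = list(dict.fromkeys(universe))
    if len(uni_order) != len(universe):
        warnings.warn("universe contained duplicates; deduplicated", stacklevel=2)
    uni = set(uni_order)
    N = len(uni)

    query_in = [g for g in dict.fromkeys(query) if g in uni]
    if not query_in:
        raise ValueError("query is empty after intersection with the universe")
    n = len(query_in)
    query_set = set(query_in)

    rows = []
    for s in sets:
        members = [g for g in s.members if g in uni]
        K = len(members)
        if K < min_set_size or K > max_set_fraction * N:
            continue
        member_set = set(members)
        overlap_genes = tuple(g for g in query_in if g in member_set)
        k = len(overlap_genes)
        rows.append((s.name, K, k, overlap_genes, hypergeom_tail(k, N, K, n)))

    if not rows:
        return []
    raw_p = np.array([r[4] for r in rows])
    adj = multipletests(raw_p, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            name=name,
            universe_size=N,
            set_size=K,
            query_size=n,
            overlap=k,
            p_value=float(p),
            adjusted_p=float(min(a, 1.0)),
            overlap_genes=genes,
        )
        for (name, K, k, genes, p), a in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.name))
    return results


def member_overlap(
    enriched: list[EnrichmentResult], query: list[str], alpha: float = 0.05
) -> list[str]:
    """Union of overlap genes across sets significant at ``alpha`` (BH).

    The union preserves the order of the query list, so downstream filters
    see genes in their original significance ranking.
    """
    hits: set[str] = set()
    for res in enriched:
        if res.adjusted_p < alpha:
            hits.update(res.overlap_genes)
    return [g for g in dict.fromkeys(query) if g in hits]


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view matching the enrichment.tsv layout."""
    return pd.DataFrame(
        [
            {
                "set": r.name,
                "universe_size": r.universe_size,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "overlap": r.overlap,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "overlap_genes": ";".join(r.overlap_genes),
            }
            for r in results
        ],
        columns=ENRICHMENT_COLUMNS,
    )
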