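"""Hypergeometric over-representation analysis of gene sets.

For a query of n genes drawn from a universe of N genes, a term covering
K genes, and k hits (query genes in the term), the enrichment p-value is
the upper hypergeometric tail

    p = sum_{j=k..min(K,n)} C(K,j) C(N-K,n-j) / C(N,n).

Terms are reported significant at raw p < 0.01 by default;
Benjamini-Hochberg adjusted p-values are attached for transparency but
do not gate the call.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_tail", "ora", "EnrichmentResult"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    adjusted_p: float


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    k: hits in the query; K: term size; n: query size; N: universe size.
    Computed through the survival function of ``scipy.stats.hypergeom``
    (stable in log space internally).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent sizes: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"hit count k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    query_genes,
    gene_sets: dict[str, set[str]],
    universe: set[str] | None = None,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Over-representation analysis of a gene list against annotation terms.

    ``universe`` defaults to the union of all annotated genes; query genes
    outside the universe are dropped with a warning. One row per term with
    at least one hit, sorted ascending by p-value, with columns
    term_id, k, K, n, N, p_value, adjusted_p, significant (raw p < p_max).
    """
    if universe is None:
        universe = set().union(*gene_sets.values()) if gene_sets else set()
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    outside = query - universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query &= universe
    n, N = len(query), len(universe)
    rows = []
    for term, members in gene_sets.items():
        members = set(members) & universe
        k = len(query & members)
        if k == 0:
            continue
        rows.append((term, k, len(members), n, N, hypergeom_tail(k, len(members), n, N)))
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_value"])
    if len(df):
        df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = df["p_value"] < p_max
        df = df.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    else:
        df["adjusted_p"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
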