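"""Hypergeometric over-representation analysis against GMT gene sets.

For a query of n genes drawn from a universe of N, a term of K genes
overlapping the query in k is scored with the upper-tail hypergeometric
probability P[X >= k] (equivalently one-sided Fisher's exact on the 2x2
overlap table); Benjamini-Hochberg correction is applied across the
tested terms and rows with FDR below the cut are flagged significant.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import AnnotationSet

__all__ = ["hypergeometric_pvalue", "enrich"]


def hypergeometric_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    N: universe size, K: term size, n: query size, k: overlap.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def enrich(
    query: Iterable[str],
    annotations: AnnotationSet,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Score every annotation term for over-representation in the query.

    Query genes outside the universe are dropped (their count is in the
    ``n_dropped`` DataFrame attribute); a query fully disjoint from the
    universe is an error.  Returns one row per term with k, K, n, N, p,
    fdr, significant flag and the overlapping genes, sorted by p.
    """
    universe = set(annotations.universe)
    raw_query = set(query)
    q = raw_query & universe
    if not q:
        raise ValueError("query has no overlap with the annotation universe")
    n_dropped = len(raw_query) - len(q)

    N, n = len(universe), len(q)
    rows = []
    for term, genes in annotations.terms.items():
        gs = set(genes) & universe
        overlap = sorted(q & gs)
        rows.append(
            {
                "term": term,
                "description": annotations.descriptions.get(term, ""),
                "k": len(overlap),
                "K": len(gs),
                "n": n,
                "N": N,
                "p": hypergeometric_pvalue(N, len(gs), n, len(overlap)),
                "genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    if out.empty:
        out["fdr"] = []
        out["significant"] = []
        return out
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_cut
    out = out.sort_index().sort_values("p", kind="stable")
    out.attrs["n_dropped"] = n_dropped
    return out
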