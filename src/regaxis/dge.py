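"""Differential expression between resistant and sensitive classes.

Per gene, an unpaired Welch t-test (unequal variances, two-sided) and a
log2 fold change computed as the difference of log2 means (resistant
minus sensitive; the data are already log2-scale).  A gene passes the
double filtration when p < p_cut and |log2FC| > fc_cut.  Genes passing
in at least ``min_drugs`` drugs form the cross-drug intersection set.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "welch_t_test",
    "log2_fold_change",
    "run_dge",
    "cross_drug_intersection",
]


def welch_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, df, p) with t = (mean_a - mean_b)/sqrt(s2a/na + s2b/nb)
    and df by the Welch-Satterthwaite approximation.  When both groups
    have zero variance: equal means give (0, na+nb-2, 1) by convention;
    unequal means are a degenerate-variance error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both groups have zero variance but differing means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def log2_fold_change(
    group_res: Sequence[float], group_sens: Sequence[float]
) -> float:
    """Difference of log2 means, resistant minus sensitive."""
    r = np.asarray(group_res, dtype=float)
    s = np.asarray(group_sens, dtype=float)
    if r.size == 0 or s.size == 0:
        raise ValueError("empty group")
    return float(r.mean() - s.mean())


def run_dge(
    expr: pd.DataFrame,
    classes: Mapping[str, str],
    p_cut: float = 0.05,
    fc_cut: float = 2.0,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch test + fold change with double filtration.

    ``expr`` is gene x sample (log2 scale); ``classes`` maps sample ->
    'sensitive' | 'resistant' and both classes need >= 2 samples (a
    single-class contrast is refused).  Returns a DataFrame indexed by
    gene with columns t, df, p, (fdr,) log2fc, direction, pass.

    Degenerate genes (zero variance in both groups, equal means) are
    reported with t=0, p=1.  Zero variance with differing means yields
    an effectively-zero p (the smallest positive float) so the gene is
    kept testable without NaNs.
    """
    res_samples = [s for s, c in classes.items() if c == "resistant"]
    sens_samples = [s for s, c in classes.items() if c == "sensitive"]
    missing = (set(res_samples) | set(sens_samples)) - set(expr.columns)
    if missing:
        raise ValueError(f"classed samples absent from matrix: {sorted(missing)}")
    if len(res_samples) < 2 or len(sens_samples) < 2:
        raise ValueError(
            "no differential contrast: both classes need at least 2 samples"
        )

    r = expr[res_samples].to_numpy(dtype=float)
    s = expr[sens_samples].to_numpy(dtype=float)
    nr, ns = r.shape[1], s.shape[1]
    mr, ms = r.mean(axis=1), s.mean(axis=1)
    vr, vs = r.var(axis=1, ddof=1), s.var(axis=1, ddof=1)

    se2 = vr / nr + vs / ns
    log2fc = mr - ms
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / np.sqrt(se2)
        df = se2**2 / ((vr / nr) ** 2 / (nr - 1) + (vs / ns) ** 2 / (ns - 1))
    p = np.empty_like(t)
    ok = se2 > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)

    # both-variance-zero genes: equal means -> null convention; else
    # infinitely separated on the observed scale
    degen = ~ok
    eq = degen & (log2fc == 0)
    ne = degen & (log2fc != 0)
    t[eq], p[eq], df[eq] = 0.0, 1.0, nr + ns - 2
    t[ne] = np.sign(log2fc[ne]) * np.inf
    p[ne] = np.finfo(float).tiny
    df[ne] = nr + ns - 2

    out = pd.DataFrame(
        {
            "t": t,
            "df": df,
            "p": p,
            "log2fc": log2fc,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "flat")),
        },
        index=expr.index,
    )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["pass"] = (out["p"] < p_cut) & (out["log2fc"].abs() > fc_cut)
    return out


def cross_drug_intersection(
    deg_tables: Mapping[str, pd.DataFrame], min_drugs: int = 3
) -> pd.DataFrame:
    """Genes passing the double filtration in at least ``min_drugs`` drugs.

    Returns a DataFrame indexed by gene with columns n_drugs and drugs
    (comma-joined, sorted), sorted by descending count then gene name.
    """
    if not deg_tables:
        raise ValueError("need at least one DEG table")
    hits: dict[str, list[str]] = {}
    for drug, table in deg_tables.items():
        for gene in table.index[table["pass"]]:
            hits.setdefault(gene, []).append(drug)
    rows = {
        gene: {"n_drugs": len(drugs), "drugs": ",".join(sorted(drugs))}
        for gene, drugs in hits.items()
        if len(drugs) >= min_drugs
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if out.empty:
        return pd.DataFrame(columns=["n_drugs", "drugs"])
    out.index.name = "gene"
    return out.sort_index().sort_values("n_drugs", ascending=False, kind="stable")
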