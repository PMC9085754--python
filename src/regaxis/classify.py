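"""Drug-response classification and response-matrix clustering.

A cell line is resistant to a drug when its log-normalized IC50
(LN_IC50) is above 0 and sensitive when below 0; extreme responders are
selected outside the ±1 band.  Drugs whose selected extremes are all of
one class carry no differential contrast and are flagged single-class so
downstream differential expression can exclude them.

Clustering of the response matrix uses the field's heatmap convention:
uncentered correlation (cosine similarity without mean-centering) as the
similarity, d = 1 - similarity as the dissimilarity, and average linkage
(UPGMA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average

__all__ = [
    "ResponseClassification",
    "classify_response",
    "select_extremes",
    "uncentered_correlation",
    "hierarchical_cluster",
    "export_heatmap_table",
]

SENSITIVE = "sensitive"
RESISTANT = "resistant"
UNCLASSIFIED = "unclassified"


@dataclass
class ResponseClassification:
    """Per-(cell line, drug) labels plus a per-drug summary.

    ``table`` is long-form with columns cell_line, drug, ln_ic50, label,
    selected.  ``per_drug`` has one row per drug with counts of selected
    sensitives/resistants and the single-class flag.
    """

    table: pd.DataFrame
    per_drug: pd.DataFrame

    def analyzable_drugs(self) -> list[str]:
        """Drugs with selected extremes in both classes."""
        ok = self.per_drug[~self.per_drug["single_class"]]
        return list(ok.index)

    def selected_samples(self, drug: str) -> dict[str, str]:
        """Map cell line -> class for the selected extremes of one drug."""
        sub = self.table[(self.table["drug"] == drug) & self.table["selected"]]
        return dict(zip(sub["cell_line"], sub["label"]))


def classify_response(ln_ic50: float) -> str:
    """Label one LN_IC50 value: >0 resistant, <0 sensitive, else unclassified.

    Exactly 0 and missing values are unclassified (the rule uses strict
    inequalities).  Total function: never raises.
    """
    if ln_ic50 is None or (isinstance(ln_ic50, float) and math.isnan(ln_ic50)):
        return UNCLASSIFIED
    if ln_ic50 > 0:
        return RESISTANT
    if ln_ic50 < 0:
        return SENSITIVE
    return UNCLASSIFIED


def select_extremes(
    table: pd.DataFrame,
    sensitive_cut: float = -1.0,
    resistant_cut: float = 1.0,
) -> ResponseClassification:
    """Classify every entry and select extreme responders per drug.

    An entry is selected when its LN_IC50 lies below ``sensitive_cut``
    or above ``resistant_cut``.  Drugs with zero selected sensitives or
    zero selected resistants are flagged ``single_class`` (no
    differential contrast possible).
    """
    if not sensitive_cut < resistant_cut:
        raise ValueError("sensitive_cut must be below resistant_cut")

    long = table.stack(future_stack=True).rename("ln_ic50").reset_index()
    long.columns = ["cell_line", "drug", "ln_ic50"]
    long["label"] = long["ln_ic50"].map(classify_response)
    long["selected"] = (long["ln_ic50"] < sensitive_cut) | (
        long["ln_ic50"] > resistant_cut
    )
    long.loc[long["ln_ic50"].isna(), "selected"] = False

    rows = {}
    for drug in table.columns:
        sub = long[(long["drug"] == drug) & long["selected"]]
        n_sens = int((sub["label"] == SENSITIVE).sum())
        n_res = int((sub["label"] == RESISTANT).sum())
        rows[drug] = {
            "n_selected_sensitive": n_sens,
            "n_selected_resistant": n_res,
            "single_class": n_sens == 0 or n_res == 0,
        }
    per_drug = pd.DataFrame.from_dict(rows, orient="index")
    per_drug.index.name = "drug"
    return ResponseClassification(table=long, per_drug=per_drug)


def uncentered_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine similarity without mean-centering: sum(xy)/sqrt(sum(x^2) sum(y^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    nx_ = float(np.dot(x, x))
    ny_ = float(np.dot(y, y))
    if nx_ == 0.0 or ny_ == 0.0:
        raise ValueError("uncentered correlation undefined for a zero vector")
    return float(np.dot(x, y) / math.sqrt(nx_ * ny_))


def _pairwise_uncentered_distance(items: np.ndarray) -> np.ndarray:
    """Condensed distance 1 - uncentered correlation with pairwise NaN deletion."""
    n = items.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(np.isnan(items[i]) | np.isnan(items[j]))
            if not mask.any():
                raise ValueError(
                    f"rows {i} and {j} share no observed values; similarity undefined"
                )
            out.append(1.0 - uncentered_correlation(items[i][mask], items[j][mask]))
    return np.asarray(out)


def _leaf_order(linkage: np.ndarray, n: int) -> list[int]:
    """Deterministic leaf order: at each merge the subtree containing the
    smaller original index goes left."""
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, _h, _cnt) in enumerate(linkage):
        left, right = members.pop(int(a)), members.pop(int(b))
        if min(right) < min(left):
            left, right = right, left
        members[n + step] = left + right
    (order,) = members.values()
    return order


def hierarchical_cluster(
    matrix: pd.DataFrame, axis: Literal["rows", "cols"] = "rows"
) -> tuple[np.ndarray, list]:
    """Average-linkage (UPGMA) clustering under 1 - uncentered correlation.

    Returns the scipy linkage matrix and the ordered labels of the
    clustered axis.  Leaf order is deterministic: ties and left/right
    placement are resolved by the smallest original index.
    """
    data = matrix.to_numpy(dtype=float)
    labels = list(matrix.index)
    if axis == "cols":
        data = data.T
        labels = list(matrix.columns)
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")

    dist = _pairwise_uncentered_distance(data)
    z = average(dist)
    order = _leaf_order(z, data.shape[0])
    return z, [labels[i] for i in order]


def export_heatmap_table(
    matrix: pd.DataFrame,
    row_order: Iterable,
    col_order: Iterable,
    path: str | None = None,
) -> pd.DataFrame:
    """Reorder the matrix for heatmap rendering and optionally write TSV."""
    row_order = list(row_order)
    col_order = list(col_order)
    if sorted(row_order) != sorted(matrix.index) or sorted(col_order) != sorted(
        matrix.columns
    ):
        raise ValueError("row_order/col_order must be permutations of the axes")
    ordered = matrix.loc[row_order, col_order]
    if path is not None:
        ordered.to_csv(path, sep="\t")
    return ordered
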