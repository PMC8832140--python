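"""Scoring normalized test-data DE calls against the benchmark gold standard.

The benchmark data's DE statuses (p < alpha, strict) are the gold standard;
every normalized test-data result is cross-tabulated against it to give
TP/FP/TN/FN and the derived TPR/FPR/FDR/FNR.  Rates with a zero denominator
are reported as NaN ("NA" on disk), never silently 0.  Concordance-at-the-top
curves compare two p-value rankings at increasing list sizes, and method
p-value profiles are clustered hierarchically (Euclidean distance, Ward
linkage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .de_testing import DEResult, adjust_bh
from .errors import AlignmentError, DomainError


@dataclass(frozen=True)
class GoldStandard:
    marker_ids: tuple
    de_status: np.ndarray      # boolean, benchmark p < alpha
    alpha: float


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 tabulation of test calls vs the gold standard, with rates.

    Undefined rates (zero denominator) are NaN.
    """

    method: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else float("nan")

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def fnr(self) -> float:
        return self.fn / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    def as_row(self) -> dict:
        return {
            "method": self.method, "TP": self.tp, "FP": self.fp,
            "TN": self.tn, "FN": self.fn, "TPR": self.tpr, "FPR": self.fpr,
            "FDR": self.fdr, "FNR": self.fnr,
        }


@dataclass(frozen=True)
class CATCurve:
    list_sizes: tuple
    concordance: tuple

    def as_frame(self, method: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "method": method, "k": list(self.list_sizes),
            "concordance": list(self.concordance),
        })


def make_gold_standard(benchmark_de: DEResult, alpha: float,
                       adjust: bool = False) -> GoldStandard:
    """Dichotomize benchmark p-values at alpha (strict <).

    With ``adjust=True`` BH-adjusted p-values are thresholded instead.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    p = adjust_bh(benchmark_de.p_values) if adjust else benchmark_de.p_values
    return GoldStandard(benchmark_de.marker_ids, p < alpha, alpha)


def confusion(test_de: DEResult, gold: GoldStandard, alpha: float,
              method: str = "", adjust: bool = False) -> ConfusionMetrics:
    """Cross-tabulate test-data calls (p < alpha, strict) against the gold
    standard.  Marker sets must match exactly."""
    if tuple(test_de.marker_ids) != tuple(gold.marker_ids):
        raise AlignmentError("test and gold-standard marker sets differ")
    p = adjust_bh(test_de.p_values) if adjust else test_de.p_values
    calls = p < alpha
    truth = gold.de_status
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    tn = int(np.sum(~calls & ~truth))
    fn = int(np.sum(~calls & truth))
    return ConfusionMetrics(method or test_de.backend, tp, fp, tn, fn)


def default_list_sizes(n_markers: int) -> tuple:
    """CAT default list sizes: 10, 20, ... up to min(G, 300), plus G."""
    top = min(n_markers, 300)
    sizes = list(range(10, top + 1, 10))
    if not sizes:
        sizes = [n_markers]
    if sizes[-1] != n_markers and n_markers <= 300:
        sizes.append(n_markers)
    return tuple(sizes)


def _ranking(de: DEResult) -> list:
    """Marker IDs sorted ascending by p, ties broken lexicographically."""
    order = sorted(zip(de.p_values, de.marker_ids), key=lambda t: (t[0], t[1]))
    return [m for _, m in order]


def cat_curve(p_a: DEResult, p_b: DEResult,
              list_sizes: Optional[Sequence[int]] = None) -> CATCurve:
    """Concordance at the top: |top-k(a) ∩ top-k(b)| / k for each k."""
    shared = set(p_a.marker_ids) & set(p_b.marker_ids)
    if not shared:
        raise AlignmentError("no shared markers between the two rankings")
    g = len(shared)
    if list_sizes is None:
        list_sizes = default_list_sizes(g)
    list_sizes = tuple(int(k) for k in list_sizes)
    if any(k < 1 or k > g for k in list_sizes):
        raise DomainError(f"list sizes must lie in [1, {g}]")
    rank_a = [m for m in _ranking(p_a) if m in shared]
    rank_b = [m for m in _ranking(p_b) if m in shared]
    conc = tuple(
        len(set(rank_a[:k]) & set(rank_b[:k])) / k for k in list_sizes
    )
    return CATCurve(list_sizes, conc)


@dataclass(frozen=True)
class Dendrogram:
    """Ward-linkage merge tree over method p-value profiles."""

    method_names: tuple
    linkage: np.ndarray        # scipy linkage matrix (m-1 x 4)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.method_names[node.id]}:{length:g}"
            kids = ",".join(rec(c, node.dist) for c in
                            (node.get_left(), node.get_right()))
            return f"({kids}):{length:g}"

        return rec(tree, tree.dist) + ";"


def pvalue_dendrogram(p_table: pd.DataFrame) -> Dendrogram:
    """Hierarchically cluster method p-value columns (Euclidean, Ward).

    Columns are sorted by method name first so ties break deterministically
    by name order.  Missing values are rejected.
    """
    if p_table.shape[1] < 2:
        raise DomainError("need at least 2 methods to cluster")
    if p_table.isna().any().any():
        raise DomainError("missing p-values in the method table")
    p_table = p_table[sorted(p_table.columns)]
    dists = pdist(p_table.to_numpy().T, metric="euclidean")
    link = hierarchy.linkage(dists, method="ward")
    return Dendrogram(tuple(p_table.columns), link)


def metrics_table(metrics: Sequence[ConfusionMetrics]) -> pd.DataFrame:
    """One row per method: method,TP,FP,TN,FN,TPR,FPR,FDR,FNR."""
    cols = ["method", "TP", "FP", "TN", "FN", "TPR", "FPR", "FDR", "FNR"]
    return pd.DataFrame([m.as_row() for m in metrics], columns=cols)
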