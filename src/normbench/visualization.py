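"""Figure functions: a pure, testable figure-data layer plus rendering.

Each figure separates computation (returning plain arrays/DataFrames written
as TSV alongside the image) from matplotlib rendering, so downstream checks
never depend on pixel output.  Rendering failures are logged and non-fatal;
they never corrupt the computed tables.
"""

from __future__ import annotations

import logging
import os
from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .benchmark_metrics import CATCurve, ConfusionMetrics, Dendrogram
from .data_io import CountMatrix
from .de_testing import DEResult
from .errors import DomainError

logger = logging.getLogger(__name__)

SUPPORTED_FORMATS = ("svg", "pdf", "png")


# ---------------------------------------------------------------------------
# figure-data layer
# ---------------------------------------------------------------------------

def rle_data(counts: CountMatrix) -> pd.DataFrame:
    """Relative Log Expression deviations: log2(x+1) minus per-marker median.

    Returns the G x n deviation matrix; per-sample boxplot statistics follow
    from it (see :func:`rle_box_stats`).
    """
    z = np.log2(counts.counts + 1.0)
    dev = z - np.median(z, axis=1, keepdims=True)
    return pd.DataFrame(dev, index=list(counts.marker_ids),
                        columns=list(counts.sample_ids))


def rle_box_stats(deviations: pd.DataFrame) -> pd.DataFrame:
    """Median, quartiles and 1.5*IQR whiskers per sample."""
    rows = []
    for s in deviations.columns:
        v = deviations[s].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_lim) & (v <= hi_lim)]
        rows.append({
            "sample": s, "median": med, "q1": q1, "q3": q3,
            "whisker_low": inside.min() if inside.size else q1,
            "whisker_high": inside.max() if inside.size else q3,
        })
    return pd.DataFrame(rows)


def volcano_data(de: DEResult) -> pd.DataFrame:
    """(log2FC, -log10 p) pairs per marker; p = 0 clipped to machine-min."""
    p = np.clip(de.p_values, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "marker": list(de.marker_ids),
        "log2_fold_change": de.log2_fold_change,
        "neg_log10_p": -np.log10(p),
    })


def venn_data(calls_a, calls_b, universe: Sequence[str]) -> dict:
    """Region counts (a-only, both, b-only) over a shared marker universe."""
    ua, ub, uu = set(calls_a), set(calls_b), set(universe)
    if not ua <= uu or not ub <= uu:
        raise DomainError("call sets must be subsets of the marker universe")
    return {
        "a_only": len(ua - ub),
        "both": len(ua & ub),
        "b_only": len(ub - ua),
    }


def fdr_fnr_scatter_data(metrics: Sequence[ConfusionMetrics]) -> pd.DataFrame:
    """One labelled (FNR, FDR) point per method; NA rates excluded."""
    rows = []
    for m in sorted(metrics, key=lambda m: m.method):
        if np.isnan(m.fdr) or np.isnan(m.fnr):
            logger.info("method %s has undefined FDR/FNR; excluded from "
                        "scatter", m.method)
            continue
        rows.append({"method": m.method, "FNR": m.fnr, "FDR": m.fdr})
    return pd.DataFrame(rows, columns=["method", "FNR", "FDR"])


def fdr_fnr_boxplot_data(per_pair: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-method FDR/FNR distributions over simulated pairs.

    Expects columns pair, method, FDR, FNR; returns long format
    (method, rate, value) sorted by method name, NA dropped with a notice.
    """
    needed = {"method", "FDR", "FNR"}
    if not needed <= set(per_pair.columns):
        raise DomainError(f"per-pair table needs columns {sorted(needed)}")
    long = per_pair.melt(id_vars=["method"], value_vars=["FDR", "FNR"],
                         var_name="rate", value_name="value")
    n_na = int(long["value"].isna().sum())
    if n_na:
        logger.info("dropping %d undefined rate value(s) from boxplot data",
                    n_na)
    return (long.dropna(subset=["value"])
                .sort_values(["method", "rate"], kind="stable")
                .reset_index(drop=True))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _save(fig, out_dir, name, fmt):
    path = os.path.join(out_dir, f"{name}.{fmt}")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def render_rle(deviations: pd.DataFrame, out_dir, fmt="svg", name="rle"):
    stats_df = rle_box_stats(deviations)
    fig, ax = plt.subplots(figsize=(max(6, 0.2 * len(deviations.columns)), 4))
    ax.boxplot([deviations[c] for c in deviations.columns],
               tick_labels=list(deviations.columns), showfliers=False)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("RLE (log2)")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    stats_df.to_csv(os.path.join(out_dir, f"{name}_data.tsv"), sep="\t",
                    index=False)
    return _save(fig, out_dir, name, fmt)


def render_volcano(vdata: pd.DataFrame, out_dir, fmt="svg", name="volcano",
                   alpha: Optional[float] = None):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(vdata["log2_fold_change"], vdata["neg_log10_p"], s=8,
               alpha=0.6, edgecolors="none")
    if alpha is not None:
        ax.axhline(-np.log10(alpha), color="red", lw=0.8, ls="--")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    vdata.to_csv(os.path.join(out_dir, f"{name}_data.tsv"), sep="\t",
                 index=False)
    return _save(fig, out_dir, name, fmt)


def render_venn(regions: dict, out_dir, fmt="svg", name="venn",
                label_a="benchmark", label_b="test"):
    """Two-circle Venn drawn with plain matplotlib patches."""
    fig, ax = plt.subplots(figsize=(4, 4))
    for cx, color in ((-0.4, "tab:blue"), (0.4, "tab:orange")):
        ax.add_patch(plt.Circle((cx, 0), 1.0, alpha=0.35, color=color))
    ax.text(-0.9, 0, str(regions["a_only"]), ha="center", fontsize=14)
    ax.text(0.0, 0, str(regions["both"]), ha="center", fontsize=14)
    ax.text(0.9, 0, str(regions["b_only"]), ha="center", fontsize=14)
    ax.text(-0.7, 1.15, label_a, ha="center")
    ax.text(0.7, 1.15, label_b, ha="center")
    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.4, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    pd.DataFrame([regions]).to_csv(os.path.join(out_dir, f"{name}_data.tsv"),
                                   sep="\t", index=False)
    return _save(fig, out_dir, name, fmt)


def render_fdr_fnr_scatter(sdata: pd.DataFrame, out_dir, fmt="svg",
                           name="fdr_fnr"):
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.scatter(sdata["FNR"], sdata["FDR"], s=25)
    for _, row in sdata.iterrows():
        ax.annotate(row["method"], (row["FNR"], row["FDR"]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("FNR")
    ax.set_ylabel("FDR")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    sdata.to_csv(os.path.join(out_dir, f"{name}_data.tsv"), sep="\t",
                 index=False)
    return _save(fig, out_dir, name, fmt)


def render_cat(curves: dict, out_dir, fmt="svg", name="cat"):
    """``curves`` maps method name -> CATCurve (vs the common reference)."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    rows = []
    for method in sorted(curves):
        c: CATCurve = curves[method]
        ax.plot(c.list_sizes, c.concordance, marker=".", label=method, lw=1)
        rows.append(c.as_frame(method))
    ax.set_xlabel("list size k")
    ax.set_ylabel("concordance at the top")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=6, ncol=2)
    pd.concat(rows, ignore_index=True).to_csv(
        os.path.join(out_dir, f"{name}_data.tsv"), sep="\t", index=False)
    return _save(fig, out_dir, name, fmt)


def render_dendrogram(dendro: Dendrogram, out_dir, fmt="svg",
                      name="dendrogram"):
    fig, ax = plt.subplots(figsize=(6, 4))
    hierarchy.dendrogram(dendro.linkage, labels=list(dendro.method_names),
                         ax=ax, leaf_rotation=90)
    ax.set_ylabel("Ward height")
    with open(os.path.join(out_dir, f"{name}.nwk"), "w") as fh:
        fh.write(dendro.to_newick() + "\n")
    return _save(fig, out_dir, name, fmt)


def render_fdr_fnr_boxplot(long: pd.DataFrame, out_dir, fmt="svg",
                           name="fdr_fnr_boxplot"):
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, rate in zip(axes, ("FDR", "FNR")):
        sub = long[long["rate"] == rate]
        methods = sorted(sub["method"].unique())
        ax.boxplot([sub.loc[sub["method"] == m, "value"] for m in methods],
                   tick_labels=methods)
        ax.set_title(rate)
        ax.tick_params(axis="x", rotation=90, labelsize=7)
    axes[0].set_ylabel("rate")
    long.to_csv(os.path.join(out_dir, f"{name}_data.tsv"), sep="\t",
                index=False)
    return _save(fig, out_dir, name, fmt)


def check_format(fmt: str) -> str:
    if fmt not in SUPPORTED_FORMATS:
        raise DomainError(
            f"unknown figure format {fmt!r}; supported: {SUPPORTED_FORMATS}"
        )
    return fmt


def render_all(out_dir, fmt="svg", *, rle_before=None, rle_after=None,
               volcano=None, venn=None, scatter=None, cat=None,
               dendrogram=None, boxplot=None, alpha=None) -> list:
    """Render every supplied figure; failures are logged, never fatal.

    Returns the list of files written.  Figure-data TSVs are written by the
    individual renderers before the image, so a rendering failure cannot
    corrupt them.
    """
    check_format(fmt)
    os.makedirs(out_dir, exist_ok=True)
    written = []
    jobs = [
        ("rle_before", rle_before, lambda d: render_rle(d, out_dir, fmt, "rle_before")),
        ("rle_after", rle_after, lambda d: render_rle(d, out_dir, fmt, "rle_after")),
        ("volcano", volcano, lambda d: render_volcano(d, out_dir, fmt, alpha=alpha)),
        ("venn", venn, lambda d: render_venn(d, out_dir, fmt)),
        ("fdr_fnr", scatter, lambda d: render_fdr_fnr_scatter(d, out_dir, fmt)),
        ("cat", cat, lambda d: render_cat(d, out_dir, fmt)),
        ("dendrogram", dendrogram, lambda d: render_dendrogram(d, out_dir, fmt)),
        ("fdr_fnr_boxplot", boxplot, lambda d: render_fdr_fnr_boxplot(d, out_dir, fmt)),
    ]
    for label, data, fn in jobs:
        if data is None:
            continue
        try:
            written.append(fn(data))
        except Exception:                       # noqa: BLE001
            logger.exception("rendering %s failed; continuing", label)
    return written
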