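"""End-to-end workflows: benchmark assessment and simulated-pair assessment.

``run_benchmark`` executes the three-step assessment on one paired study:
normalize the test data with each requested method, call DE in the
un-normalized benchmark and each normalized test data set, and score the
test calls against the benchmark gold standard (confusion rates, CAT curves
vs no normalization, p-value dendrogram, figures).  A "none" pseudo-method
(no normalization) is always included for reference.  ``run_simulated``
repeats the core over a bank of shuffled label assignments and collects the
per-pair rates.
"""

from __future__ import annotations

import hashlib
import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .benchmark_metrics import (
    ConfusionMetrics,
    cat_curve,
    confusion,
    make_gold_standard,
    metrics_table,
    pvalue_dendrogram,
)
from .data_io import PairedStudy, write_results, write_run_metadata
from .de_testing import run_de
from .errors import IncompatibilityError, NormBenchError
from .label_shuffle_sim import BankEntry
from .normalization import builtin_methods, normalize
from .visualization import (
    fdr_fnr_boxplot_data,
    fdr_fnr_scatter_data,
    render_all,
    rle_data,
    venn_data,
    volcano_data,
)

logger = logging.getLogger(__name__)

#: name of the reference pseudo-method (test data left un-normalized)
NO_NORMALIZATION = "none"

DEFAULT_METHODS = tuple(builtin_methods())


@dataclass
class BenchmarkRun:
    """In-memory results of one paired-benchmark assessment."""

    benchmark_de: "DEResult"
    test_de: dict                      # method -> DEResult
    metrics: list                      # list[ConfusionMetrics]
    cat_curves: dict                   # method -> CATCurve (vs none)
    dendrogram: object
    skipped: dict = field(default_factory=dict)   # method -> reason

    @property
    def metrics_frame(self) -> pd.DataFrame:
        return metrics_table(self.metrics)


def assess_study(study: PairedStudy, methods: Sequence[str] = DEFAULT_METHODS,
                 de_backend: str = "voom", alpha: float = 0.01,
                 adjust: bool = False, seed: int = 0,
                 method_params: Optional[dict] = None) -> BenchmarkRun:
    """The three-step assessment core, no I/O.

    Methods incompatible with the chosen backend (covariate methods under
    the NB exact test) are skipped with a logged reason rather than aborting
    the whole run.
    """
    method_params = method_params or {}
    bench_de = run_de(study.benchmark, study.groups, backend=de_backend)
    gold = make_gold_standard(bench_de, alpha, adjust=adjust)

    test_de = {NO_NORMALIZATION: run_de(study.test, study.groups,
                                        backend=de_backend)}
    skipped = {}
    for m in methods:
        params = dict(method_params.get(m, {}))
        if m == "SVA":
            params.setdefault("seed", seed)
        try:
            nr = normalize(study.test, m, groups=study.groups, **params)
            test_de[m] = run_de(study.test, study.groups,
                                backend=de_backend, norm=nr)
        except IncompatibilityError as exc:
            logger.warning("skipping method %s: %s", m, exc)
            skipped[m] = str(exc)

    metrics = [
        confusion(de, gold, alpha, method=name, adjust=adjust)
        for name, de in test_de.items()
    ]
    curves = {
        name: cat_curve(de, test_de[NO_NORMALIZATION])
        for name, de in test_de.items() if name != NO_NORMALIZATION
    }
    p_table = pd.DataFrame(
        {name: de.p_values for name, de in test_de.items()},
        index=list(study.benchmark.marker_ids),
    )
    p_table["benchmark"] = bench_de.p_values
    dendro = pvalue_dendrogram(p_table) if p_table.shape[1] >= 2 else None
    return BenchmarkRun(bench_de, test_de, metrics, curves, dendro,
                        skipped=skipped)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_benchmark(study: PairedStudy, out_dir,
                  methods: Sequence[str] = DEFAULT_METHODS,
                  de_backend: str = "voom", alpha: float = 0.01,
                  adjust: bool = False, seed: int = 0,
                  fig_format: str = "svg",
                  input_paths: Optional[dict] = None,
                  focus_method: Optional[str] = None) -> BenchmarkRun:
    """Full assessment with all outputs written under ``out_dir``.

    Writes the metrics table, per-method DE tables, CAT curves, the
    dendrogram (Newick + figure), the seven figures for ``focus_method``
    (default: first requested method), and a manifest JSON.
    """
    os.makedirs(out_dir, exist_ok=True)
    run = assess_study(study, methods=methods, de_backend=de_backend,
                       alpha=alpha, adjust=adjust, seed=seed)

    outputs = {}

    metrics_path = os.path.join(out_dir, "metrics.tsv")
    write_results(run.metrics_frame, metrics_path)
    outputs["metrics"] = metrics_path

    de_rows = []
    for name, de in run.test_de.items():
        for i, m in enumerate(de.marker_ids):
            de_rows.append({
                "method": name, "marker": m, "p_value": de.p_values[i],
                "log2_fold_change": de.log2_fold_change[i],
                "mean_log_expression": de.mean_log_expression[i],
                "statistic": de.statistic[i],
            })
    de_path = os.path.join(out_dir, "de_results.tsv")
    write_results(pd.DataFrame(de_rows), de_path)
    outputs["de_results"] = de_path

    cat_rows = [c.as_frame(m) for m, c in sorted(run.cat_curves.items())]
    if cat_rows:
        cat_path = os.path.join(out_dir, "cat_curves.tsv")
        write_results(pd.concat(cat_rows, ignore_index=True), cat_path)
        outputs["cat_curves"] = cat_path

    focus = focus_method or (methods[0] if methods else None)
    if focus is not None and focus not in run.test_de:
        focus = NO_NORMALIZATION
    gold_calls = {
        m for m, flag in zip(run.benchmark_de.marker_ids,
                             run.benchmark_de.p_values < alpha) if flag
    }
    focus_de = run.test_de.get(focus)
    focus_calls = {
        m for m, p in zip(focus_de.marker_ids, focus_de.p_values) if p < alpha
    } if focus_de is not None else set()

    figure_files = render_all(
        out_dir, fmt=fig_format,
        rle_before=rle_data(study.test),
        volcano=volcano_data(focus_de) if focus_de is not None else None,
        venn=venn_data(gold_calls, focus_calls,
                       study.benchmark.marker_ids),
        scatter=fdr_fnr_scatter_data(run.metrics),
        cat=run.cat_curves or None,
        dendrogram=run.dendrogram,
        alpha=alpha,
    )
    outputs["figures"] = figure_files

    manifest = {
        "version": __version__,
        "parameters": {
            "methods": list(methods), "de_backend": de_backend,
            "alpha": alpha, "adjust": adjust, "seed": seed,
            "focus_method": focus, "fig_format": fig_format,
        },
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (input_paths or {}).items()
        },
        "skipped_methods": run.skipped,
        "outputs": outputs,
    }
    write_run_metadata(os.path.join(out_dir, "manifest.json"), **manifest)
    return run


def run_simulated(study: PairedStudy, bank: Sequence[BankEntry], out_dir,
                  methods: Sequence[str] = DEFAULT_METHODS,
                  de_backend: str = "voom", alpha: float = 0.01,
                  seed: int = 0, fig_format: str = "svg") -> pd.DataFrame:
    """Assess every extracted pair; emit the long per-pair metrics table.

    Each bank entry's shuffled labels replace the study's groups and the
    benchmark-assessment core runs unchanged.  Returns the long table
    (pair, method, TP..FNR); also writes it and the FDR/FNR boxplot data
    under ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not bank:
        warnings.warn("empty pair extraction; nothing to assess",
                      RuntimeWarning)
        return pd.DataFrame(
            columns=["pair", "method", "TP", "FP", "TN", "FN",
                     "TPR", "FPR", "FDR", "FNR"])
    rows = []
    for entry in bank:
        shuffled = PairedStudy(study.benchmark, study.test,
                               entry.assignment.labels)
        run = assess_study(shuffled, methods=methods, de_backend=de_backend,
                           alpha=alpha, seed=seed)
        for m in run.metrics:
            row = m.as_row()
            row["pair"] = entry.index
            rows.append(row)
    long = pd.DataFrame(rows)[
        ["pair", "method", "TP", "FP", "TN", "FN", "TPR", "FPR", "FDR", "FNR"]
    ]
    write_results(long, os.path.join(out_dir, "simulated_metrics.tsv"))
    box = fdr_fnr_boxplot_data(long)
    render_all(out_dir, fmt=fig_format, boxplot=box)
    write_run_metadata(
        os.path.join(out_dir, "manifest.json"),
        version=__version__,
        parameters={"methods": list(methods), "de_backend": de_backend,
                    "alpha": alpha, "seed": seed,
                    "n_pairs": len(bank)},
    )
    return long
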