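"""The nine depth-normalization methods under a uniform contract.

Six scaling methods (Total Count, Upper Quartile, Median, TMM, DESeq
median-of-ratios, PoissonSeq) return strictly positive per-sample scale
factors ``s_i`` dividing the raw counts; three regression-based methods
(Quantile Normalization, SVA, RUV with sub-methods g/r/s) either rewrite the
matrix directly (QN) or return an n x k unwanted-variation covariate matrix
``W`` to be placed in the differential-expression design.

Scale factors are anchored to geometric mean 1 before being combined with
library size, so methods are comparable; this anchoring is a package
convention, documented in the methods note.

The module keeps a registry of built-in methods (canonical names "TC", "UQ",
"Med", "TMM", "DESeq", "PoissonSeq", "QN", "SVA", "RUVg", "RUVr", "RUVs" —
the three RUV entries are sub-methods of a single RUV family, giving nine
methods in six scaling + three regression families).  User methods can be
registered with :func:`register_method`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CountMatrix, GroupAssignment
from .errors import (
    ControlError,
    ConvergenceError,
    DegenerateCenteringError,
    DegeneratePercentileError,
    DomainError,
    NoReferenceError,
    RankError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationResult:
    """Output of one normalization method on one count matrix.

    Exactly one of ``scale_factors`` / ``covariates`` is present, except for
    quantile normalization which carries neither (it rewrites the matrix
    directly).  ``normalized`` always has the shape and IDs of the input;
    for covariate methods it is an artifact-adjusted matrix intended for
    visualization only — DE must put ``covariates`` in the design instead.
    ``effective_lib_sizes`` are the column totals of the normalized matrix.
    """

    method: str
    scale_factors: Optional[np.ndarray]
    covariates: Optional[np.ndarray]
    normalized: np.ndarray
    effective_lib_sizes: np.ndarray
    marker_ids: tuple = ()
    sample_ids: tuple = ()

    def __post_init__(self):
        if self.scale_factors is not None and self.covariates is not None:
            raise DomainError("a method returns scale factors OR covariates")
        if self.scale_factors is not None:
            s = np.asarray(self.scale_factors, dtype=float)
            if np.any(~np.isfinite(s)) or np.any(s <= 0):
                raise DomainError("scale factors must be strictly positive finite")
            object.__setattr__(self, "scale_factors", s)
        if self.covariates is not None:
            object.__setattr__(
                self, "covariates", np.asarray(self.covariates, dtype=float)
            )
        object.__setattr__(self, "normalized", np.asarray(self.normalized, float))
        object.__setattr__(
            self, "effective_lib_sizes", np.asarray(self.effective_lib_sizes, float)
        )


def _gmean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def _scaling_result(method: str, cm: CountMatrix, s: np.ndarray) -> NormalizationResult:
    y = cm.counts / s[np.newaxis, :]
    return NormalizationResult(
        method=method,
        scale_factors=s,
        covariates=None,
        normalized=y,
        effective_lib_sizes=y.sum(axis=0),
        marker_ids=cm.marker_ids,
        sample_ids=cm.sample_ids,
    )


# ---------------------------------------------------------------------------
# scaling methods
# ---------------------------------------------------------------------------

def norm_total_count(counts: CountMatrix, groups=None) -> NormalizationResult:
    """Total Count: s_i = d_i / mean(d); all effective depths equal mean depth."""
    d = counts.library_sizes
    s = d / d.mean()
    return _scaling_result("TC", counts, s)


def norm_percentile(counts: CountMatrix, groups=None, q: float = 0.75) -> NormalizationResult:
    """Scaling by the q-th percentile of each sample's counts.

    q=0.5 is Median ("Med"), q=0.75 Upper Quartile ("UQ"), q=0.9 "P90".
    Percentiles are computed over markers positive in at least one sample,
    with linear interpolation between order statistics, then anchored to
    geometric mean 1.
    """
    if not 0 < q < 1:
        raise DomainError(f"percentile fraction q must be in (0,1), got {q}")
    expressed = counts.counts.sum(axis=1) > 0
    sub = counts.counts[expressed]
    p = np.quantile(sub, q, axis=0, method="linear")
    if np.any(p <= 0):
        bad = [counts.sample_ids[i] for i in np.where(p <= 0)[0]]
        raise DegeneratePercentileError(
            f"{q:.0%} percentile is zero for sample(s): {bad}"
        )
    s = p / _gmean(p)
    name = {0.5: "Med", 0.75: "UQ", 0.9: "P90"}.get(q, f"P{int(round(q * 100))}")
    return _scaling_result(name, counts, s)


def _tmm_reference(counts: CountMatrix) -> int:
    """Default TMM reference: sample whose upper quartile of count fractions
    is closest to the mean upper quartile."""
    frac = counts.counts / counts.library_sizes[np.newaxis, :]
    uq = np.quantile(frac, 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_factor_one(x_i, x_r, d_i, d_r, trim_logfc, trim_abundance):
    both = (x_i > 0) & (x_r > 0)
    if not np.any(both):
        raise DomainError("sample shares no positive markers with TMM reference")
    xi, xr = x_i[both], x_r[both]
    pi, pr = xi / d_i, xr / d_r
    M = np.log2(pi / pr)
    A = 0.5 * np.log2(pi * pr)
    w = 1.0 / ((1.0 - pi) / xi + (1.0 - pr) / xr)  # delta-method binomial variance

    n = len(M)
    # double trimming on ranks, edgeR-style bounds
    rank_m = stats.rankdata(M, method="ordinal")
    rank_a = stats.rankdata(A, method="ordinal")
    lo_m = np.floor(n * trim_logfc) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_abundance) + 1
    hi_a = n + 1 - lo_a
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < 10:
        warnings.warn(
            "fewer than 10 markers survive TMM trimming; using untrimmed "
            "weighted mean", RuntimeWarning,
        )
        keep = np.ones(n, dtype=bool)
    f = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    return float(f)


def norm_tmm(counts: CountMatrix, groups=None, ref_sample=None,
             trim_logfc: float = 0.30, trim_abundance: float = 0.05) -> NormalizationResult:
    """Trimmed Mean of M-values.

    For each sample vs the reference, log-ratios M and average abundances A
    are formed over markers positive in both; the highest/lowest
    ``trim_logfc`` of M and ``trim_abundance`` of A are trimmed; the factor
    is the precision-weighted mean of the surviving M values on the count
    scale.  Factors are anchored to geometric mean 1 and combined with
    library size: s_i = f_i * d_i / mean(d).
    """
    d = counts.library_sizes
    if ref_sample is None:
        r = _tmm_reference(counts)
    else:
        r = counts.sample_ids.index(str(ref_sample))
    x_r, d_r = counts.counts[:, r], d[r]
    f = np.ones(counts.n_samples)
    for i in range(counts.n_samples):
        if i == r:
            continue
        f[i] = _tmm_factor_one(counts.counts[:, i], x_r, d[i], d_r,
                               trim_logfc, trim_abundance)
    f /= _gmean(f)
    s = f * d / d.mean()
    return _scaling_result("TMM", counts, s)


def norm_deseq(counts: CountMatrix, groups=None) -> NormalizationResult:
    """DESeq median-of-ratios size factors.

    Each marker's pseudo-reference is its geometric mean across samples
    (markers with any zero excluded); f_i is the median over markers of
    x_gi / ref_g, anchored to geometric mean 1.
    """
    x = counts.counts
    all_pos = np.all(x > 0, axis=1)
    if not np.any(all_pos):
        raise NoReferenceError("no marker has positive counts in every sample")
    sub = x[all_pos]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    f = np.median(sub / ref[:, np.newaxis], axis=0)
    s = f / _gmean(f)
    return _scaling_result("DESeq", counts, s)


def norm_poissonseq(counts: CountMatrix, groups=None, max_iter: int = 10,
                    gof_quantile_window: float = 0.5) -> NormalizationResult:
    """PoissonSeq-style iterated least-variant-set depth estimation.

    Depth proportions are re-estimated from the markers whose Poisson
    goodness-of-fit statistic falls in the central ``gof_quantile_window``
    (default middle 50%), iterating to convergence.
    """
    if not 0 < gof_quantile_window <= 1:
        raise DomainError("gof_quantile_window must be in (0, 1]")
    x = counts.counts
    n = counts.n_samples
    d = counts.library_sizes
    s_hat = d / d.sum()
    lo_q = 0.5 - gof_quantile_window / 2
    hi_q = 0.5 + gof_quantile_window / 2
    row_tot = x.sum(axis=1)
    converged = False
    for _ in range(max_iter):
        expected = s_hat[np.newaxis, :] * row_tot[:, np.newaxis]
        gof = np.sum((x - expected) ** 2 / expected, axis=1)
        lo, hi = np.quantile(gof, [lo_q, hi_q])
        kept = (gof >= lo) & (gof <= hi)
        if not np.any(kept):
            raise ConvergenceError("PoissonSeq kept-marker set became empty")
        new = x[kept].sum(axis=0) / x[kept].sum()
        if np.max(np.abs(new - s_hat) / s_hat) < 1e-6:
            s_hat = new
            converged = True
            break
        s_hat = new
    if not converged:
        warnings.warn("PoissonSeq did not converge; returning last iterate",
                      RuntimeWarning)
    s = s_hat * n
    return _scaling_result("PoissonSeq", counts, s)


# ---------------------------------------------------------------------------
# regression-based methods
# ---------------------------------------------------------------------------

def norm_quantile(counts: CountMatrix, groups=None) -> NormalizationResult:
    """Classic full-quantile normalization.

    Every column is mapped onto the rank-wise mean of the sorted columns;
    tied values receive the mean of the rank-averages over the positions the
    tie occupies in sort order.  Returns the rewritten matrix with neither
    scale factors nor covariates.
    """
    x = counts.counts
    g, n = x.shape
    target = np.sort(x, axis=0).mean(axis=1)  # rank-average profile
    y = np.empty_like(x)
    for j in range(n):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(g)
        mapped[order] = target
        # ties: average the target values over each tied block
        ser = pd.Series(mapped).groupby(col).transform("mean")
        y[:, j] = ser.to_numpy()
    return NormalizationResult(
        method="QN", scale_factors=None, covariates=None, normalized=y,
        effective_lib_sizes=y.sum(axis=0),
        marker_ids=counts.marker_ids, sample_ids=counts.sample_ids,
    )


def _log1p_matrix(counts: CountMatrix) -> np.ndarray:
    """log(x + 1); the +1 pseudo-count keeps zeros at zero."""
    return np.log1p(counts.counts)


def _group_design(counts: CountMatrix, groups: GroupAssignment) -> np.ndarray:
    g = groups.indicator(counts.sample_ids)
    return np.column_stack([np.ones_like(g), g])


def _first_pass_pvalues(z: np.ndarray, counts: CountMatrix,
                        groups: GroupAssignment) -> np.ndarray:
    """Per-marker two-sample t-test p-values on the log scale (first pass)."""
    g = groups.indicator(counts.sample_ids).astype(bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(z[:, ~g], z[:, g], axis=1, equal_var=True)
    p = np.nan_to_num(res.pvalue, nan=1.0)
    return p


def _empirical_controls(z: np.ndarray, counts: CountMatrix,
                        groups: GroupAssignment) -> np.ndarray:
    """Empirical negative controls: the half of markers with the largest
    first-pass DE p-values (least evidence of group signal)."""
    p = _first_pass_pvalues(z, counts, groups)
    order = np.argsort(-p, kind="stable")
    keep = order[: max(1, counts.n_markers // 2)]
    mask = np.zeros(counts.n_markers, dtype=bool)
    mask[keep] = True
    return mask


def _control_mask(counts: CountMatrix, controls) -> np.ndarray:
    control_set = set(map(str, controls))
    mask = np.array([m in control_set for m in counts.marker_ids])
    if not mask.any():
        raise ControlError("control set is disjoint from the marker set")
    return mask


def _adjusted_matrix(z, W, counts, groups):
    """Remove the fitted W-component from z for visualization only."""
    X = np.column_stack([_group_design(counts, groups), W])
    beta, *_ = np.linalg.lstsq(X, z.T, rcond=None)
    kW = W.shape[1]
    z_adj = z - (W @ beta[-kW:, :]).T if kW else z
    return np.clip(np.expm1(z_adj), 0.0, None)


def _covariate_result(method, counts, groups, W, z) -> NormalizationResult:
    if W.shape[1] > 0:
        normalized = _adjusted_matrix(z, W, counts, groups)
    else:
        normalized = counts.counts.copy()
    return NormalizationResult(
        method=method, scale_factors=None, covariates=W, normalized=normalized,
        effective_lib_sizes=normalized.sum(axis=0),
        marker_ids=counts.marker_ids, sample_ids=counts.sample_ids,
    )


def norm_ruv(counts: CountMatrix, groups: GroupAssignment, variant: str = "g",
             k: int = 1, controls=None) -> NormalizationResult:
    """Remove Unwanted Variation on z = log(x+1); variants g, r, s.

    RUVg takes the first k sample-space singular directions of the
    (row-centred) control-marker submatrix; RUVr those of the residual matrix
    after a first-pass group-means fit on all markers; RUVs those of the
    control submatrix after within-group centring.  If no control set is
    given, empirical controls are the half of markers with the largest
    first-pass p-values.  The returned matrix is an adjusted version for
    visualization only — DE designs must use the covariates W directly.
    """
    if variant not in ("g", "r", "s"):
        raise DomainError(f"unknown RUV variant {variant!r}")
    if k < 1:
        raise RankError("k must be >= 1")
    if k >= counts.n_samples:
        raise RankError(f"k={k} must be smaller than n={counts.n_samples}")
    z = _log1p_matrix(counts)
    method = f"RUV{variant}"

    if variant == "r":
        X = _group_design(counts, groups)
        beta, *_ = np.linalg.lstsq(X, z.T, rcond=None)
        R = z - (X @ beta).T
        basis = R
    else:
        if controls is None:
            mask = _empirical_controls(z, counts, groups)
        else:
            mask = _control_mask(counts, controls)
        zc = z[mask]
        if variant == "g":
            basis = zc - zc.mean(axis=1, keepdims=True)
        else:  # RUVs: within-group centring of control rows
            centered = zc.copy()
            g = groups.indicator(counts.sample_ids)
            for val in (0.0, 1.0):
                cols = g == val
                if cols.sum() < 2:
                    raise DegenerateCenteringError(
                        "RUVs needs >= 2 samples per group for centring"
                    )
                centered[:, cols] -= centered[:, cols].mean(axis=1, keepdims=True)
            if np.allclose(centered, 0.0):
                raise DegenerateCenteringError(
                    "within-group centring removed all variation"
                )
            basis = centered

    _, sv, vt = np.linalg.svd(basis, full_matrices=False)
    if len(sv) < k:
        raise RankError(f"matrix rank {len(sv)} < requested k={k}")
    W = vt[:k].T  # n x k sample scores
    return _covariate_result(method, counts, groups, W, z)


def norm_sva(counts: CountMatrix, groups: GroupAssignment,
             k: Optional[int] = None, n_permutations: int = 20,
             seed: int = 0) -> NormalizationResult:
    """Surrogate-variable estimation on z = log(x+1) residuals.

    Group means are removed; if ``k`` is not given it is estimated by
    permutation parallel analysis (each row of the residual matrix permuted
    independently, B=20 times; components whose singular value exceeds the
    95th percentile of the permuted singular values are kept).  W holds the
    first k sample-space singular directions of the residual matrix.  An
    estimated k of 0 returns an empty covariate set with a logged notice and
    DE proceeds unadjusted.
    """
    if k is not None and k < 1:
        raise RankError("k must be >= 1 when given")
    if k is not None and k >= counts.n_samples:
        raise RankError(f"k={k} must be smaller than n={counts.n_samples}")
    z = _log1p_matrix(counts)
    X = _group_design(counts, groups)
    beta, *_ = np.linalg.lstsq(X, z.T, rcond=None)
    R = z - (X @ beta).T

    _, sv, vt = np.linalg.svd(R, full_matrices=False)
    if k is None:
        rng = np.random.default_rng(seed)
        n_comp = len(sv)
        perm_sv = np.empty((n_permutations, n_comp))
        for b in range(n_permutations):
            Rp = np.take_along_axis(
                R, rng.permuted(
                    np.tile(np.arange(R.shape[1]), (R.shape[0], 1)), axis=1
                ), axis=1,
            )
            perm_sv[b] = np.linalg.svd(Rp, compute_uv=False)[:n_comp]
        thresh = np.quantile(perm_sv, 0.95, axis=0)
        exceeds = sv > thresh
        k_est = 0
        for flag in exceeds:
            if flag:
                k_est += 1
            else:
                break
        k = k_est
        if k == 0:
            logger.info("SVA estimated k=0 surrogate variables; DE will "
                        "proceed unadjusted")
    W = vt[:k].T if k > 0 else np.empty((counts.n_samples, 0))
    return _covariate_result("SVA", counts, groups, W, z)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethodEntry:
    name: str
    family: str          # nine families; RUVg/r/s share family "RUV"
    kind: str            # "scaling" or "regression"
    needs_groups: bool
    func: Callable


_REGISTRY: dict[str, MethodEntry] = {}


def register_method(name: str, func: Callable, family: Optional[str] = None,
                    kind: str = "scaling", needs_groups: bool = False) -> None:
    """Register a normalization method under ``name``.

    ``func(counts, groups=None, **params)`` must return a
    :class:`NormalizationResult`-shaped record.  User plugins appear in all
    outputs exactly like built-ins.
    """
    _REGISTRY[name] = MethodEntry(name, family or name, kind, needs_groups, func)


_BUILTIN_NAMES: tuple = ()


def builtin_methods() -> dict[str, MethodEntry]:
    """The built-in registry (canonical method names -> entries).

    User-registered plugins are dispatchable via :func:`normalize` and
    listed by :func:`registered_methods`, but never shadow this census.
    """
    return {n: _REGISTRY[n] for n in _BUILTIN_NAMES}


def registered_methods() -> dict[str, MethodEntry]:
    """Every dispatchable method, built-ins and user plugins alike."""
    return dict(_REGISTRY)


def method_families() -> dict[str, str]:
    """Map family name -> kind for the built-in methods (nine families)."""
    fams: dict[str, str] = {}
    for entry in builtin_methods().values():
        fams.setdefault(entry.family, entry.kind)
    return fams


def normalize(counts: CountMatrix, method: str,
              groups: Optional[GroupAssignment] = None,
              **params) -> NormalizationResult:
    """Run a registered normalization method by name."""
    if method not in _REGISTRY:
        raise DomainError(
            f"unknown normalization method {method!r}; "
            f"known: {sorted(_REGISTRY)}"
        )
    entry = _REGISTRY[method]
    if entry.needs_groups and groups is None:
        raise DomainError(f"method {method!r} requires a group assignment")
    res = entry.func(counts, groups, **params)
    # keep the registry name even where the underlying function is shared
    if res.method != method:
        res = NormalizationResult(
            method=method, scale_factors=res.scale_factors,
            covariates=res.covariates, normalized=res.normalized,
            effective_lib_sizes=res.effective_lib_sizes,
            marker_ids=res.marker_ids, sample_ids=res.sample_ids,
        )
    return res


def _register_builtins() -> None:
    register_method("TC", norm_total_count, family="TC", kind="scaling")
    register_method("UQ", lambda c, g=None, **kw: norm_percentile(c, g, q=0.75),
                    family="UQ", kind="scaling")
    register_method("Med", lambda c, g=None, **kw: norm_percentile(c, g, q=0.5),
                    family="Med", kind="scaling")
    register_method("TMM", norm_tmm, family="TMM", kind="scaling")
    register_method("DESeq", norm_deseq, family="DESeq", kind="scaling")
    register_method("PoissonSeq", norm_poissonseq, family="PoissonSeq",
                    kind="scaling")
    register_method("QN", norm_quantile, family="QN", kind="regression")
    register_method("SVA", norm_sva, family="SVA", kind="regression",
                    needs_groups=True)
    for v in ("g", "r", "s"):
        register_method(
            f"RUV{v}",
            (lambda variant: lambda c, g=None, **kw: norm_ruv(
                c, g, variant=variant, **kw))(v),
            family="RUV", kind="regression", needs_groups=True,
        )
    global _BUILTIN_NAMES
    _BUILTIN_NAMES = tuple(_REGISTRY)


_register_builtins()
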