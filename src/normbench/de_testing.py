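"""Two differential-expression backends for two-group count comparisons.

``de_voom`` is a precision-weighted moderated-t pipeline: log-CPM transform,
per-marker least squares, a lowess mean-variance trend turned into
observation weights, a weighted refit, and empirical-Bayes variance
moderation.  ``de_nb_exact`` is a negative-binomial exact test with a common
qCML dispersion estimated on depth-equalized pseudo-counts.  Both accept the
output of any normalization method: scale factors adjust the effective
library sizes; unwanted-variation covariates enter the voom design (the NB
exact test cannot absorb continuous covariates and raises an explicit
incompatibility error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .data_io import CountMatrix, GroupAssignment
from .errors import DegenerateDesignError, DomainError, IncompatibilityError
from .normalization import NormalizationResult

#: dispersion below which the NB exact test switches to its Poisson limit
_PHI_POISSON_LIMIT = 1e-6
#: per-marker pseudo-count total above which the conditional distribution is
#: approximated by a normal rather than summed exactly
_EXACT_TOTAL_CAP = 500_000


@dataclass(frozen=True)
class DEResult:
    """Per-marker differential-expression summaries for one backend run."""

    marker_ids: tuple
    p_values: np.ndarray
    log2_fold_change: np.ndarray   # group 2 minus group 1 (sorted level order)
    mean_log_expression: np.ndarray
    statistic: np.ndarray
    backend: str
    adjusted_p: Optional[np.ndarray] = None

    def __post_init__(self):
        p = np.asarray(self.p_values, dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
            raise DomainError("p-values must be finite and in [0, 1]")
        if len(p) != len(self.marker_ids):
            raise DomainError("one p-value per marker required")
        object.__setattr__(self, "p_values", p)

    def with_bh(self) -> "DEResult":
        return DEResult(
            self.marker_ids, self.p_values, self.log2_fold_change,
            self.mean_log_expression, self.statistic, self.backend,
            adjusted_p=adjust_bh(self.p_values),
        )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# voom-style backend
# ---------------------------------------------------------------------------

def _effective_lib_sizes(counts: CountMatrix,
                         norm: Optional[NormalizationResult]):
    """Resolve (count matrix to model, voom library sizes, design covariates).

    Scale factors s_i become voom library sizes L_i = s_i * mean(d) — for
    Total Count this is d_i itself, for TMM it is the classic f_i * d_i
    effective library size.  Covariate methods keep raw L_i = d_i and pass W
    into the design.  A matrix-rewriting method (quantile normalization) is
    modelled through its rewritten matrix with that matrix's column totals.
    """
    d = counts.library_sizes
    x = counts.counts
    W = None
    if norm is None:
        L = d.copy()
    elif norm.scale_factors is not None:
        L = norm.scale_factors * d.mean()
    elif norm.covariates is not None and norm.covariates.shape[1] > 0:
        L = d.copy()
        W = norm.covariates
    elif norm.covariates is not None:    # estimated k = 0: unadjusted
        L = d.copy()
    else:                                # QN: rewritten matrix
        x = norm.normalized
        L = x.sum(axis=0)
    return x, L, W


def _fit_fdist(s2: np.ndarray, df: float):
    """Moment-matching fit of a scaled F distribution to sample variances.

    Returns (prior df d0, prior variance s0^2); d0 may be inf.  Method of
    moments on log variances, with the digamma/trigamma corrections for the
    log-chi-square moments.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 1e-30
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s20 = np.exp(emean)
    return float(d0), float(s20)


def _trigamma_inverse(y: float) -> float:
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def _build_design(counts: CountMatrix, groups: GroupAssignment,
                  W: Optional[np.ndarray]) -> np.ndarray:
    g = groups.indicator(counts.sample_ids)
    cols = [np.ones_like(g), g]
    if W is not None:
        cols.extend(W.T)
    return np.column_stack(cols)


def de_voom(counts: CountMatrix, groups: GroupAssignment,
            norm: Optional[NormalizationResult] = None,
            prior_df: Optional[float] = None,
            lowess_frac: float = 0.5) -> DEResult:
    """Precision-weighted moderated-t differential expression.

    Steps: log2-CPM with a 0.5 offset on effective library sizes; ordinary
    least squares per marker; a lowess smooth of sqrt(residual sd) against
    average log-count evaluated at each observation's fitted log-count gives
    inverse-quartic precision weights; weighted refit; empirical-Bayes
    squeezing of the residual variances toward a common prior (moment
    matching on log variances); two-sided moderated-t p-values with
    df = residual df + prior df.

    ``prior_df`` overrides the estimated prior degrees of freedom (np.inf
    forces the common-variance z-test limit).
    """
    for lev in groups.levels:
        if sum(1 for l in groups.labels if l == lev) < 2:
            raise DegenerateDesignError(f"group {lev!r} has < 2 samples")
    x, L, W = _effective_lib_sizes(counts, norm)
    if np.any(L <= 0):
        raise DomainError("effective library sizes must be positive")
    X = _build_design(counts, groups, W)
    n, p = X.shape[0], X.shape[1]
    df_res = n - p
    if df_res <= 0:
        raise DegenerateDesignError("zero residual degrees of freedom")

    z = np.log2((x + 0.5) / (L + 1.0)[np.newaxis, :] * 1e6)

    # first pass: ordinary least squares, shared design
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    beta = (H @ z.T).T                     # G x p
    fitted = (X @ beta.T).T                # G x n (log-CPM scale)
    resid = z - fitted
    sigma2 = (resid ** 2).sum(axis=1) / df_res
    sigma = np.sqrt(sigma2)

    # mean-variance trend on the log-count scale
    sx = z.mean(axis=1) + np.mean(np.log2(L + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    lo = lowess(sy, sx, frac=lowess_frac, return_sorted=True)
    lo_x, lo_y = lo[:, 0], np.maximum(lo[:, 1], 1e-6)

    fitted_logcount = fitted + (np.log2(L + 1.0) - np.log2(1e6))[np.newaxis, :]
    interp = np.interp(np.clip(fitted_logcount, lo_x[0], lo_x[-1]), lo_x, lo_y)
    w = interp ** -4.0

    # weighted refit, per marker
    G = z.shape[0]
    beta_g = np.empty(G)
    v_g = np.empty(G)          # unscaled variance of the group coefficient
    s2_g = np.empty(G)
    for gi in range(G):
        wg = w[gi]
        Xw = X * wg[:, np.newaxis]
        A = X.T @ Xw
        Ainv = np.linalg.inv(A)
        b = Ainv @ (Xw.T @ z[gi])
        r = z[gi] - X @ b
        s2_g[gi] = np.sum(wg * r * r) / df_res
        beta_g[gi] = b[1]
        v_g[gi] = Ainv[1, 1]

    if prior_df is None:
        d0, s20 = _fit_fdist(s2_g, df_res)
    else:
        d0 = float(prior_df)
        _, s20 = _fit_fdist(s2_g, df_res)
    if np.isinf(d0):
        s2_post = np.full_like(s2_g, s20)
        df_total = np.inf
    else:
        s2_post = (df_res * s2_g + d0 * s20) / (df_res + d0)
        df_total = df_res + d0

    t_stat = beta_g / np.sqrt(s2_post * v_g)
    if np.isinf(df_total):
        p_values = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p_values = 2.0 * stats.t.sf(np.abs(t_stat), df=df_total)

    return DEResult(
        marker_ids=counts.marker_ids,
        p_values=np.clip(p_values, 0.0, 1.0),
        log2_fold_change=beta_g,
        mean_log_expression=z.mean(axis=1),
        statistic=t_stat,
        backend="voom",
    )


# ---------------------------------------------------------------------------
# negative-binomial exact backend
# ---------------------------------------------------------------------------

def _pseudo_counts(x: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Depth-equalize counts to the geometric-mean library size, rounded."""
    target = np.exp(np.mean(np.log(L)))
    return np.rint(x * (target / L)[np.newaxis, :])


def _conditional_loglik(phi: float, y1: np.ndarray, y2: np.ndarray) -> float:
    """qCML conditional log-likelihood of a common NB dispersion.

    For each group with n samples sharing a mean, conditioning on the group
    total z removes the mean: the contribution is
    sum_i lgamma(y_i + r) - n lgamma(r) + lgamma(n r) - lgamma(z + n r),
    with r = 1/phi.  Summed over both groups and all markers.
    """
    r = 1.0 / phi
    total = 0.0
    for y in (y1, y2):
        n = y.shape[1]
        zt = y.sum(axis=1)
        total += float(
            np.sum(special.gammaln(y + r))
            - y.shape[0] * n * special.gammaln(r)
            + y.shape[0] * special.gammaln(n * r)
            - np.sum(special.gammaln(zt + n * r))
        )
    return total


def estimate_common_dispersion(y1: np.ndarray, y2: np.ndarray) -> float:
    """Maximize the conditional likelihood over log10 phi in [-6, 1]."""
    grid = np.linspace(-6.0, 1.0, 29)
    ll = np.array([_conditional_loglik(10.0 ** g, y1, y2) for g in grid])
    best = int(np.argmax(ll))
    if best == 0:
        warnings.warn("dispersion maximized at the lower boundary; "
                      "using the Poisson limit", RuntimeWarning)
        return 0.0
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_conditional_loglik(10.0 ** g, y1, y2),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(10.0 ** res.x)


def _exact_pvalue(z1: int, z2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact conditional NB test for one marker.

    Conditions on t = z1 + z2; the null distribution of the group-1 total is
    proportional to NB(s; n1/phi, n1*mu) * NB(t-s; n2/phi, n2*mu) with
    mu = t/(n1+n2) (binomial(t, n1/(n1+n2)) in the Poisson limit).  The
    smaller inclusive tail is doubled and capped at 1.
    """
    t = int(z1 + z2)
    if t == 0:
        return 1.0
    if t > _EXACT_TOTAL_CAP:
        return _normal_approx_pvalue(z1, t, n1, n2, phi)
    s = np.arange(t + 1)
    if phi <= _PHI_POISSON_LIMIT:
        logp = stats.binom.logpmf(s, t, n1 / (n1 + n2))
    else:
        r = 1.0 / phi
        mu = t / (n1 + n2)
        logp = (
            stats.nbinom.logpmf(s, n1 * r, (n1 * r) / (n1 * r + n1 * mu))
            + stats.nbinom.logpmf(t - s, n2 * r, (n2 * r) / (n2 * r + n2 * mu))
        )
        logp -= special.logsumexp(logp)
    prob = np.exp(logp)
    prob /= prob.sum()
    lower = prob[: int(z1) + 1].sum()
    upper = prob[int(z1):].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def _normal_approx_pvalue(z1, t, n1, n2, phi):
    """Conditional-normal approximation for very large totals."""
    mu = t / (n1 + n2)
    m1, m2 = n1 * mu, n2 * mu
    v1 = m1 + phi * mu * m1
    v2 = m2 + phi * mu * m2
    cond_mean = m1 + v1 / (v1 + v2) * (t - m1 - m2)
    cond_sd = np.sqrt(v1 * v2 / (v1 + v2))
    zscore = (z1 - cond_mean) / cond_sd
    return float(min(1.0, 2.0 * stats.norm.sf(abs(zscore))))


def de_nb_exact(counts: CountMatrix, groups: GroupAssignment,
                norm: Optional[NormalizationResult] = None,
                dispersion: Optional[float] = None) -> DEResult:
    """Negative-binomial exact test with a common qCML dispersion.

    Counts are depth-equalized to the geometric-mean effective library size;
    a single dispersion is estimated by conditional maximum likelihood
    (unless supplied); each marker is tested by the exact conditional NB
    split test with tail doubling.  Covariate-based normalizations are
    incompatible with this backend.
    """
    if norm is not None and norm.covariates is not None \
            and norm.covariates.shape[1] > 0:
        raise IncompatibilityError(
            "the NB exact test cannot absorb unwanted-variation covariates; "
            "use the voom backend for RUV/SVA"
        )
    x, L, _ = _effective_lib_sizes(counts, norm)
    g = groups.indicator(counts.sample_ids).astype(bool)
    if g.sum() < 1 or (~g).sum() < 1:
        raise DegenerateDesignError("both groups need samples")
    y = _pseudo_counts(x, L)
    y1, y2 = y[:, ~g], y[:, g]
    n1, n2 = y1.shape[1], y2.shape[1]

    phi = estimate_common_dispersion(y1, y2) if dispersion is None else dispersion
    if phi <= _PHI_POISSON_LIMIT and dispersion is None:
        phi = 0.0

    G = y.shape[0]
    p_values = np.empty(G)
    for gi in range(G):
        p_values[gi] = _exact_pvalue(
            int(y1[gi].sum()), int(y2[gi].sum()), n1, n2, phi
        )

    cpm = (x + 0.5) / (L + 1.0)[np.newaxis, :] * 1e6
    lfc = np.log2(cpm[:, g].mean(axis=1)) - np.log2(cpm[:, ~g].mean(axis=1))
    with np.errstate(divide="ignore"):
        stat = np.sign(lfc) * stats.norm.isf(np.clip(p_values, 1e-300, 1.0) / 2)
    return DEResult(
        marker_ids=counts.marker_ids,
        p_values=np.clip(p_values, 0.0, 1.0),
        log2_fold_change=lfc,
        mean_log_expression=np.log2(cpm).mean(axis=1),
        statistic=stat,
        backend="nbexact",
    )


BACKENDS = {"voom": de_voom, "nbexact": de_nb_exact}


def run_de(counts: CountMatrix, groups: GroupAssignment,
           backend: str = "voom",
           norm: Optional[NormalizationResult] = None, **kw) -> DEResult:
    """Dispatch to a DE backend by name ('voom' is the default)."""
    if backend not in BACKENDS:
        raise DomainError(f"unknown DE backend {backend!r}")
    return BACKENDS[backend](counts, groups, norm=norm, **kw)
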