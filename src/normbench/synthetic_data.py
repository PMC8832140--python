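"""Generative paired-study simulator.

Emulates the structure of the motivating design: one benchmark matrix
collected under uniform handling (near-uniform depths, no technical
artifacts) and one test matrix of the same biology re-measured with
sample-specific depth variation — optionally correlated with the group
labels — and handling artifacts on a subset of markers.  Counts are
negative-binomial with lognormal marker means; differentially expressed
markers receive a log2-scale group shift of random sign.

The generator exists so the whole pipeline is testable without any data
download; it does not attempt to match the empirical data's exact
distributions, only their structure (two groups of 27 samples, clean vs
artifact-laden replicate measurement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CountMatrix, GroupAssignment, PairedStudy
from .errors import DomainError


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generative paired-study model.

    Defaults mirror the motivating design: two groups of 27 samples, ~20%
    of markers DE with a 3-unit log2 shift (the DE pattern the example
    workflow extracts), lognormal marker means spanning a few orders of
    magnitude, NB dispersion 0.15, near-uniform benchmark depths
    (log-sd 0.1) versus variable test depths (log-sd 0.5) partially
    confounded with group, and handling artifacts on 20% of markers.
    """

    n_markers: int = 600
    n_per_group: int = 27
    de_proportion: float = 0.2
    log2_effect: float = 3.0
    base_mean_log: float = 4.0
    base_mean_sd: float = 1.5
    nb_dispersion: float = 0.15
    depth_log_sd_benchmark: float = 0.1
    depth_log_sd_test: float = 0.5
    handling_frac: float = 0.2
    handling_log_sd: float = 0.5
    confound_strength: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_markers < 1 or self.n_per_group < 2:
            raise DomainError("need >= 1 marker and >= 2 samples per group")
        for name in ("de_proportion", "handling_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must be in [0, 1]")
        if not 0 <= self.confound_strength <= 1:
            raise DomainError("confound_strength must be in [0, 1]")
        for name in ("base_mean_sd", "nb_dispersion", "depth_log_sd_benchmark",
                     "depth_log_sd_test", "handling_log_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind one generated paired study."""

    de_markers: tuple              # marker IDs with a planted group shift
    effect_signs: np.ndarray       # +/-1 per DE marker
    depth_factors_benchmark: np.ndarray
    depth_factors_test: np.ndarray
    handled_markers: tuple         # markers carrying test-only artifacts
    group_labels: tuple


def _nb_draw(rng, mean, dispersion):
    """NB(mean, dispersion) via gamma-Poisson mixing; Poisson when phi = 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def generate_paired_study(spec: SyntheticSpec):
    """Draw one paired study and its ground-truth record.

    Returns ``(PairedStudy, SyntheticTruth)``.  Marker means are lognormal;
    DE markers get a +/- ``log2_effect`` shift (random sign) in group 2 in
    both matrices (the biology is shared).  The benchmark draws depth
    factors with ``depth_log_sd_benchmark``; the test draws new depth
    factors with ``depth_log_sd_test`` at correlation ``confound_strength``
    with the group indicator, and multiplies a ``handling_frac`` subset of
    markers by per-observation lognormal handling artifacts.
    """
    rng = np.random.default_rng(spec.seed)
    G, npg = spec.n_markers, spec.n_per_group
    n = 2 * npg
    width = max(3, len(str(G)))
    marker_ids = tuple(f"miR-{i:0{width}d}" for i in range(1, G + 1))
    sample_ids = tuple(f"S{i:02d}" for i in range(1, n + 1))
    group_labels = tuple(["A"] * npg + ["B"] * npg)
    g_ind = np.array([0.0] * npg + [1.0] * npg)

    mu = rng.lognormal(spec.base_mean_log, spec.base_mean_sd, size=G)
    n_de = int(round(spec.de_proportion * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    shift = np.zeros(G)
    shift[de_idx] = signs * spec.log2_effect
    # per-marker per-sample expected counts before depth
    base = mu[:, np.newaxis] * 2.0 ** (shift[:, np.newaxis] * g_ind[np.newaxis, :])

    log_delta_b = rng.normal(0.0, spec.depth_log_sd_benchmark, size=n)
    delta_b = np.exp(log_delta_b)

    rho = spec.confound_strength
    g_pm = 2.0 * g_ind - 1.0       # +/-1 coding so corr(logdelta, group) = rho
    eps = rng.normal(0.0, 1.0, size=n)
    log_delta_t = spec.depth_log_sd_test * (
        rho * g_pm + np.sqrt(max(0.0, 1.0 - rho ** 2)) * eps
    )
    delta_t = np.exp(log_delta_t)

    n_handled = int(round(spec.handling_frac * G))
    handled_idx = rng.choice(G, size=n_handled, replace=False)
    handling = np.ones((G, n))
    if n_handled and spec.handling_log_sd > 0:
        handling[handled_idx] = rng.lognormal(
            0.0, spec.handling_log_sd, size=(n_handled, n)
        )

    bench_counts = _nb_draw(rng, base * delta_b[np.newaxis, :],
                            spec.nb_dispersion)
    test_counts = _nb_draw(rng, base * delta_t[np.newaxis, :] * handling,
                           spec.nb_dispersion)

    # guard against the (vanishingly rare) all-zero library
    for counts in (bench_counts, test_counts):
        zero = counts.sum(axis=0) == 0
        if zero.any():
            counts[0, zero] = 1

    benchmark = CountMatrix(marker_ids, sample_ids, bench_counts.astype(float))
    test = CountMatrix(marker_ids, sample_ids, test_counts.astype(float))
    groups = GroupAssignment(sample_ids, group_labels)
    study = PairedStudy(benchmark, test, groups)
    truth = SyntheticTruth(
        de_markers=tuple(marker_ids[i] for i in sorted(de_idx)),
        effect_signs=signs,
        depth_factors_benchmark=delta_b,
        depth_factors_test=delta_t,
        handled_markers=tuple(marker_ids[i] for i in sorted(handled_idx)),
        group_labels=group_labels,
    )
    return study, truth


#: fixed seed for the deterministic toy fixture
_FIXTURE_SEED = 20240117


def fixture_small() -> PairedStudy:
    """Deterministic 50-marker x 12-sample toy pair for tests and docs."""
    spec = SyntheticSpec(
        n_markers=50, n_per_group=6, de_proportion=0.2, log2_effect=2.0,
        base_mean_log=4.0, base_mean_sd=1.0, nb_dispersion=0.1,
        depth_log_sd_benchmark=0.05, depth_log_sd_test=0.3,
        handling_frac=0.2, handling_log_sd=0.3, confound_strength=0.5,
        seed=_FIXTURE_SEED,
    )
    study, _ = generate_paired_study(spec)
    return study
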