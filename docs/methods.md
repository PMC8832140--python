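# Methods

This note records the statistical procedures implemented in `normbench`,
the defaults and why they were chosen, and the known limitations.

## The paired-benchmark design

Two count matrices over the same markers and samples: a *benchmark* matrix
collected under uniform handling, and a *test* matrix of the same biology
with realistic depth/handling artifacts.  DE statuses in the un-normalized
benchmark (p < α, strict inequality; raw p-values by default, BH-adjusted
with `adjust=True`) define the gold standard.  Each normalization method is
applied to the test matrix only; its DE calls are cross-tabulated against
the gold standard.  Rates with zero denominators (e.g. FDR when a method
calls nothing) are reported as NA, never 0, so silent methods are not
flattered.  Default α = 0.01; it is a user choice, not an estimate.

## Normalization contract

Scaling methods return strictly positive per-sample factors `s_i` dividing
the raw counts (`y = x / s`).  Factors are anchored to geometric mean 1 and
then combined with library size where the method estimates a depth-free
ratio (TMM); anchoring is a convention chosen to make methods comparable —
nothing downstream depends on the absolute scale.  Regression methods
return an n × k covariate matrix `W` that enters the DE design; their
"adjusted" matrix (`exp(z − Wα̂) − 1`, clipped at 0, on `z = log(x+1)`) is
for visualization only.  Quantile normalization rewrites the matrix
directly and carries neither factors nor covariates.

Method specifics:

* **TC** — `s_i = d_i / mean(d)` with `d_i` the library size; effective
  depths all equal the mean depth.
* **UQ / Med / P90** — the q-th percentile (q = 0.75 / 0.5 / 0.9) of each
  sample's counts over markers expressed in at least one sample, linear
  interpolation between order statistics, geometric-mean anchored.  One
  code path; the registry exposes UQ and Med, P90 is registered on demand.
* **TMM** — per sample vs a reference (default: the sample whose upper
  quartile of count fractions is closest to the mean upper quartile), over
  markers positive in both: log-ratios `M`, abundances `A`, double trimming
  (30% on M, 5% on A — the method's canonical defaults), precision weights
  from the delta-method binomial variance, factor `2^(Σ wM / Σ w)`.  Fewer
  than 10 surviving markers triggers a documented fallback to the untrimmed
  weighted mean with a warning.
* **DESeq** — median across markers of the ratio to a geometric-mean
  pseudo-reference computed over markers positive in every sample.
* **PoissonSeq** — iterated least-variant-set estimation: depth proportions
  re-estimated from markers whose Poisson goodness-of-fit statistic lies in
  the central 50% window, to convergence (max relative change < 1e-6,
  at most 10 iterations; non-convergence returns the last iterate with a
  warning).
* **QN** — full-quantile: each column mapped onto the rank-wise mean of the
  sorted columns; a tied block receives the mean of the rank-average values
  over the positions the block occupies in sort order.
* **RUVg / RUVr / RUVs** — on `z = log(x+1)` (the +1 keeps zeros at zero):
  sample-space singular directions of, respectively, the row-centred
  control-marker submatrix, the residual matrix after a group-means fit, or
  the within-group-centred control submatrix.  When no control set is given
  the empirical controls are the half of markers with the largest
  first-pass two-sample-t p-values — a deliberately conservative rule for
  miRNA panels with no spike-ins; it is overridable.
* **SVA** — sample-space singular directions of the group-means residual;
  the number of surrogate variables is estimated by permutation parallel
  analysis (20 independent row permutations, 95th-percentile threshold per
  component, counting leading components only).  An estimate of 0 returns
  an empty covariate set and DE proceeds unadjusted.

Agreement with the R implementations of these methods is targeted at the
property level (identical factors on clean synthetic cases within
tolerance), not byte level.

## DE backends

**voom-style (default).**  Effective library sizes: with scale factors,
`L_i = s_i · mean(d)` — for TC this reduces to the plain library size, for
TMM to the classic `f_i·d_i` effective size; the stored
`NormalizationResult.effective_lib_sizes` are the column totals of the
normalized matrix (for TC these are all the mean depth).  Then log2-CPM
with a 0.5 offset, per-marker OLS on `[1, group, W]`, a lowess smooth
(span 0.5) of `sqrt(residual sd)` against average log-count evaluated at
each observation's fitted log-count giving inverse-quartic weights, a
weighted refit, and empirical-Bayes moderation: residual variances are
squeezed toward a prior fitted by moment matching on log variances
(trigamma inversion by Newton iteration); moderated t has
`df = residual df + prior df`.  Note that with the depth-inclusive factor
convention, "all factors 1" asserts the data are already depth-matched;
this coincides exactly with supplying no normalization precisely on
equal-depth data, where such factors legitimately arise.

**NB exact.**  Counts are depth-equalized to the geometric-mean effective
library size and rounded; a single dispersion φ is estimated by maximizing
the conditional likelihood (exact, via group totals) over a log10 grid on
[−6, 1] refined by bounded scalar minimization; each marker is tested by
the exact conditional split test — the group-1 total conditioned on the
marker total, smaller inclusive tail doubled, capped at 1.  φ ≤ 1e-6 uses
the Poisson limit, where the conditional law is exactly binomial.
Per-marker totals above 5·10^5 pseudo-counts use a conditional-normal
approximation instead of exact summation.  Tagwise dispersion shrinkage is
deliberately omitted; the common-dispersion exact test is the implemented
core.  Continuous covariates cannot enter an exact conditional test, so
RUV/SVA with this backend raises an explicit incompatibility error (the
workflow skips such combinations with a logged reason).

BH adjustment uses the standard step-up procedure.

## Scoring

CAT curves rank markers ascending by p-value with lexicographic tie-break
and report `|top-k(a) ∩ top-k(b)| / k`; default list sizes 10, 20, … up to
min(G, 300).  Method p-value profiles are clustered with Euclidean distance
and Ward linkage (variance-update form); columns are sorted by method name
first so ties resolve deterministically; the tree exports to Newick.

## Anchor-shuffle simulation

The benchmark samples are clustered into two groups (Ward linkage on
Euclidean distances between per-sample log2-CPM profiles — the same
conventions as the dendrogram; the clustering is pluggable).  Nine anchor
samples per cluster (configurable) seed the two new groups; the remaining
samples are allocated uniformly at random, balanced to n/2 per group by
default so simulated groups match the 27/27 design (an unbalanced
Bernoulli(½) mode is available).  Each simulated pair is characterized by
the proportion of markers called DE in the shuffled benchmark (voom,
α = 0.01 by default) and the median over those markers of the absolute
group difference of mean log2-CPM.  Banks of pairs store only child seeds
(sha256 of "master:index", mod 2^31 — platform independent) plus patterns,
so any pair is reconstructable bit-identically.

## The generative simulator

`SyntheticSpec` draws marker means from LogNormal(meanlog 4, sdlog 1.5)
(counts spanning a few orders of magnitude with a heavy upper tail, as in
miRNA panels), negative-binomial counts with common dispersion 0.15, and
two groups of 27 samples.  A `de_proportion` fraction of markers (default
0.2) receives a ±`log2_effect` group shift (default 3.0, random sign) —
the DE pattern the example workflow extracts from the simulation bank.
The benchmark draws depth factors with log-sd 0.1 (near-uniform depths);
the test draws new depth factors with log-sd 0.5 correlated with the group
indicator at `confound_strength` (default 0.5), and multiplies a 20%
subset of markers by per-observation LogNormal(0, 0.5) handling artifacts.
`fixture_small()` is a fixed-seed 50 × 12 miniature used in tests and docs.

What the generator does *not* emulate: the empirical data's exact
abundance distribution, marker-marker correlation, batch structure beyond
a single depth confounder, or tagwise dispersions.  Passing tests
therefore demonstrate correctness of the machinery and the direction of
the confounding phenomenon, not performance on any particular real data
set.

A consequence of relative-abundance data worth noting: a large planted
shift on many markers changes total library mass, so after depth (CPM)
normalization every null marker acquires an apparent group shift
(composition bias).  At the default 3-unit shift on 20% of markers this
contaminates un-normalized benchmark characterizations; recovery checks of
planted patterns are run at modest shifts where the pattern is
identifiable.

## Problem sizes

Test-suite and acceptance computations use 150–2000 markers and 12–54
samples — sizes at which every property checked (factor recovery, type-I
calibration, dispersion recovery, batch-factor recovery) has comfortable
Monte-Carlo margins.  The confounding comparison uses 20 replicate pairs
of 300 markers.

## Known limitations

* Two-group designs only; no multi-factor or continuous outcomes.
* The NB backend has no quasi-likelihood F-test or robust moderation.
* RLE uses log2(x+1); the pseudo-count is a convention.
* The dendrogram requires at least two method columns.
* Markers all-zero in both matrices are dropped at alignment; the
  empirical filtering rule of the original data release is not public, so
  this is the package's own convention.
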