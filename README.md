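# normbench

Paired-benchmark assessment of depth-normalization methods for small-RNA
(miRNA) sequencing count data.

## The problem

Sequencing depth and sample-handling artifacts distort between-sample
comparisons of count data, and many normalization methods exist to correct
them. Which one should a miRNA study use?  `normbench` answers this with a
*paired benchmark* design: the same specimens measured twice, once under
uniform handling (the **benchmark** data, trusted) and once under realistic
conditions with depth and handling artifacts (the **test** data).
Differential-expression (DE) calls in the un-normalized benchmark serve as a
gold standard; each normalization method is judged by how well DE calls in
the normalized test data reproduce it.

For markers ranked by DE p-value at a significance level α, each method's
calls are cross-tabulated against the gold standard to give

```
TPR = TP/(TP+FN)   FPR = FP/(FP+TN)   FDR = FP/(TP+FP)   FNR = FN/(TP+FN)
```

together with concordance-at-the-top (CAT) curves of the p-value rankings
and a Ward-linkage dendrogram of the methods' p-value profiles.

## What is included

* **Nine normalization methods** under one contract — six scaling methods
  (Total Count, Upper Quartile, Median, TMM, DESeq median-of-ratios,
  PoissonSeq) returning per-sample scale factors `s_i`, and three
  regression-based methods (Quantile Normalization, SVA, RUV with
  sub-methods RUVg/RUVr/RUVs) returning either a rewritten matrix or an
  n × k unwanted-variation covariate matrix `W` for the DE design.  User
  methods plug in via `register_method`.
* **Two DE backends** — a precision-weighted moderated-t pipeline (voom
  style: log2-CPM, lowess mean–variance trend, weighted least squares,
  empirical-Bayes variance moderation) and a negative-binomial exact test
  with a common conditional-ML dispersion.
* **Benchmark scoring** — gold standard, confusion rates, CAT curves,
  p-value dendrograms (Newick export), and the seven standard figures (RLE,
  volcano, Venn, FDR–FNR scatter and boxplot, CAT, dendrogram), each with a
  pure figure-data layer written as TSV.
* **An anchor-shuffle simulator** — new two-group label assignments drawn
  by clustering the benchmark samples into two clusters, anchoring nine
  samples per cluster, and randomly allocating the rest; banks of shuffled
  pairs are characterized by DE pattern and reconstructable from seeds
  alone.
* **A generative simulator** — synthetic paired studies (negative-binomial
  counts, two groups of 27 samples by default, clean benchmark vs
  artifact-laden test) so the whole pipeline runs with no data download.

## Worked example

```python
import normbench as nb

# a synthetic paired study: 600 markers, 27 + 27 samples, 20% DE,
# test data with depth artifacts half-confounded with the groups
study, truth = nb.generate_paired_study(nb.SyntheticSpec(seed=1))

# register P90 (scaling by the 90th percentile) as a user method
nb.register_method("P90",
                   lambda c, g=None, **kw: nb.norm_percentile(c, g, q=0.9))

run = nb.assess_study(study, methods=["P90", "TC", "UQ", "Med", "TMM"],
                      alpha=0.01)
tab = run.metrics_frame.set_index("method")
print(tab.loc["P90", ["FDR", "FNR"]])
```

prints

```
FDR    0.494505
FNR    0.268817
```

i.e. on this synthetic pair, 49.5% of P90's DE calls are not in the
benchmark gold standard and 26.9% of the gold-standard DE markers are
missed.  `run.cat_curves["P90"]` holds P90's concordance with the
un-normalized ranking, and `run.dendrogram.to_newick()` the method
clustering.  The same workflow runs from the shell:

```sh
normbench simulate-synthetic --seed 1 --out-dir data/
normbench run --benchmark data/benchmark.tsv --test data/test.tsv \
    --groups data/groups.tsv --methods TC,UQ,Med,TMM --de voom \
    --alpha 0.01 --out-dir results/ --seed 1
normbench simulate --benchmark data/benchmark.tsv --test data/test.tsv \
    --groups data/groups.tsv --n 100 --seed 1 --out bank.tsv
normbench extract --bank bank.tsv --de-prop 0.2 --diff 3 --n 20 --out sel.tsv
normbench run-simulated --benchmark data/benchmark.tsv --test data/test.tsv \
    --groups data/groups.tsv --bank sel.tsv --out-dir sim_results/
```

### Assessing your own data

Any pair of marker-by-sample count tables (TSV/CSV, markers in rows) over
the same samples works, e.g. the deposited paired tumour miRNA data set
(27 myxofibrosarcoma vs 27 pleomorphic malignant fibrous histiocytoma
samples, measured once uniformly and once in collection order) available at
https://github.com/LXQin/PRECISION.seq.DATA.  On that pair, percentile-based
methods (P90, Upper Quartile, Median) are expected to track each other in
the CAT curves and cluster together in the p-value dendrogram, with large
benchmark-based FDR and FNR — an optional integration check; the synthetic
generator does not reproduce that data set's distributions.

## Layout

```
src/normbench/
  data_io.py            count-matrix / annotation I/O, validation, alignment
  normalization.py      the nine methods + registry
  de_testing.py         voom-style and NB-exact DE backends, BH adjustment
  benchmark_metrics.py  gold standard, confusion rates, CAT, dendrogram
  label_shuffle_sim.py  anchor-shuffle simulator and pattern banks
  synthetic_data.py     generative paired-study simulator
  visualization.py      figure-data layers + rendering
  pipeline.py           end-to-end workflows
  cli.py                `normbench` command-line interface
```

See `docs/methods.md` for the statistical details and design choices.
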