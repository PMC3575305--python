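# Methods

Statistical definitions, parameter conventions and numerical choices
used throughout `panelfuse`. Everything quantitative stated here is
recomputed by the test suite or by `scripts/acceptance.py`; this note
makes no empirical claims beyond those.

## Data model

An `OmicsMatrix` is a features × samples matrix on a declared scale:

* `log2_intensity` — complete by construction (missing entries are
  rejected), typical of normalized microarray data;
* `ratio` — positive ratios against a common reference, `NaN` marks
  missing cells (undersampling in shotgun proteomics).

Labels are binary with explicit `positive`/`negative` assignments; the
positive class token of a label file must be declared (header line
`#positive=<token>` or reader argument) and is never inferred from the
data. `f1` denotes the minority-class fraction, e.g. `11/32` for 11
positive / 21 negative samples.

## Prefilters

**ECMR.** The empirical central mass range of a feature vector `x` is

```
ECMR(x) = Q(1 − f1/2) − Q(f1/2)
```

with `Q` the linear-interpolation quantile (`h = (n−1)p + 1`, numpy's
`method="linear"`). At `f1 = 0.5` this is the inter-quartile range. The
prefilter computes every feature's ECMR and keeps features **strictly
above** the chosen quantile (default: the median) of the ECMR
distribution. With an odd number of all-distinct ECMRs the median is an
observed value and exactly `(n−1)/2` features survive — e.g. 27,306 of
54,613; with an even count the median is interpolated and `n/2`
survive.

**Detection filter.** Keeps features observed in at least a minimum
fraction of samples (default 0.75), applied *before* imputation.

**Absolute count filter.** Keeps features exceeding an expression
threshold in at least a minimum number of samples.

## Imputation

k-nearest-neighbour with neighbours in **sample space** (`k = 3`): the
distance between two samples is the root mean square difference over
features observed in both (scaling by the co-observed count prevents
sparsity from inflating distances); a missing value is the mean of the
feature over the `k` nearest samples in which it is observed. Ties in
distance break lexicographically on sample id for determinism. Class
labels are never consulted. Sample space is used rather than feature
space because the sparse platform has far fewer features than would be
needed for stable feature-feature distances at these panel sizes.

Test-time protocol: the already-imputed training matrix is pooled with
the test matrix and only test cells are filled, so training data is
bitwise unchanged by test-time imputation (asserted in tests).

## Univariate ranking

Per-feature two-sample **moderated t**: the pooled variance `s²` with
`d = n₁ + n₂ − 2` degrees of freedom is shrunk toward a prior `s0²`
with prior weight `d0`,

```
s̃² = (d0·s0² + d·s²) / (d0 + d),
t = (mean₁ − mean₂) / (s̃ · sqrt(1/n₁ + 1/n₂)),
```

with p-values from the t distribution on `d0 + d` degrees of freedom.
`(d0, s0²)` are estimated by moment matching of the log variances
(digamma/trigamma equations, Newton inversion of the trigamma); `d0 = 0`
recovers the ordinary pooled t-test and `d0 = ∞` a common-variance test.
The implementation is cross-checked in the test suite against the
reference empirical-Bayes implementation in the Bioconductor `limma`
package to ~1e-6 on prior and statistics.

Multiple testing uses Benjamini-Hochberg step-up FDR. Fold change is
`2^|Δmean|` on the log2 scale and the larger ratio of class means on the
ratio scale. Selection applies `FDR < cut` and `FC ≥ cut`, with
features ordered by (FDR ascending, |t| descending, feature id) and
optional minimum/maximum panel sizes; a pure `top_k` mode ranks without
cutoffs.

## Learners

All four learners expose one contract: fit on a panel slice, return a
positive-class probability.

* **Linear SVM** (cost fixed at 1): decision scores are mapped to
  probabilities by a Platt-type sigmoid fitted on the training scores.
  The map is strictly monotone, so probability rankings — and hence
  AUC — equal the raw margin rankings.
* **LDA**: requires fewer features than training samples; the feature
  count is the tunable parameter.
* **Elastic net** (logistic): mixing parameter fixed at α = 0.5,
  penalty strength λ tuned. Features are standardized inside the model
  and the penalty maps to the underlying solver as `C = 1/(n·λ)`. The
  intercept is never penalized; because the stochastic solver's step
  size shrinks with λ, a one-dimensional Newton polish re-solves the
  unpenalized intercept after fitting (a no-op at converged solutions),
  preserving the λ → ∞ limit in which every probability equals the
  class prevalence.
* **Random forest**: 1000 trees, `mtry = floor(sqrt(p))`, minimum node
  size 1, seeded.

## Cross-validation

`cv_probabilities` re-runs **every** data-dependent stage — prefilter,
imputation, univariate and multivariate selection, training — inside
each training fold; held-out samples only ever pass through transforms
fitted without them. This is asserted by a leakage guard test: mutating
a held-out sample must not change its fold's selected panel or training
matrix.

`nested_cv` adds hyperparameter tuning: for each outer fold, an inner
cross-validation on the outer training set scores every grid point and
one is chosen by either

* `min_misclassification` — smallest misclassification error of the
  inner held-out probabilities at the 0.5 cutoff, ties toward the
  simpler model (fewer LDA features / stronger shrinkage), or
* `max_auc_1se` — the least complex model whose mean inner AUC lies
  within one standard error (over inner repeats) of the best mean.

The chosen pipeline is refit on the full outer training set and scores
the held-out samples. Leave-one-out and repeated stratified k-fold
layouts are supported; repeated k-fold averages each sample's held-out
probabilities over repeats.

## Metrics

Thresholded metrics use a cutoff closed on the positive side
(`p ≥ 0.5` is a positive call). AUC is the Mann-Whitney rank estimator
with half credit for ties, verified against brute-force pair counting.
`member_summary` keeps exact `Fraction` arithmetic when its inputs are
exact, so published-table reconstruction rounds only once, at
presentation time, using decimal round-half-up (the convention of
printed clinical tables; avoids float representation artefacts and
banker's rounding).

## Ensembles

A `ProbabilityMatrix` aligns member probability sets over common
samples and refuses to mix probability origins (e.g. cross-validated
with resubstitution). Aggregation:

* **AP**: `p_ens = Σ wᵢ pᵢ` with positive weights summing to 1;
  `platform_balanced_weights` gives each platform equal total weight
  split equally within the platform (2 genomic + 5 proteomic members →
  0.25 each and 0.1 each).
* **VT**: ensemble score = the `v`-th largest member probability. Since
  that order statistic is ≥ 0.5 exactly when at least `v` members are,
  thresholding the score reproduces the vote rule while still providing
  a continuous score for ROC analysis. For `v = 1`, ensemble
  sensitivity ≥ every member's and specificity ≤ every member's
  (verified exhaustively for up to 4 members).

`agreement_quadrants` tabulates, per class, where two classifiers agree
or disagree and which is correct — the diversity view that motivates
fusing platforms.

## Synthetic data generator

The generator emulates the *statistical shape* of a paired study — it
is a calibration instrument, not a biological simulator. Two platforms
are produced: a complete Gaussian log2-intensity matrix and a
ratio-scale matrix (log-normal via exponentiation) with MCAR missing
cells, each with a configurable number of informative features carrying
a mean shift of `effect_size` within-class standard deviations in
positive samples. `signal_overlap` controls on how many positive
samples the platforms' signals coincide: at 1.0 every positive sample
expresses both signals; at 0.0 each platform detects a disjoint subset
of positives — the regime where late fusion helps most. Optional
equicorrelated feature blocks are induced by a shared per-sample
factor. Default problem sizes (hundreds to a couple of thousand
features, 11/21 samples) are deliberately scaled down so a full
pipeline experiment runs in seconds on one core; they are this
package's own choice for testability, not a claim about any particular
instrument's dimensions.

## Bundled case-study tables

Two published case studies ship as plain TSVs of per-classifier
sensitivity/specificity/AUC plus ensemble membership. Because
sensitivity and specificity are counts over known denominators (k/11,
k/21 at 2 decimals; k/38, k/19 at 4 decimals), the exact fractions are
recovered from the printed values and member averages are computed
exactly before a single final rounding.

## Limitations

* **Four printed AUC-average cells are unreproducible.** 86 of the 90
  member min/max/average cells of the two studies' summary tables
  reproduce exactly from the printed per-classifier inputs. The four
  AUC-average cells (kidney Ensembles 3 and 5, cancer Ensembles A and
  B) differ by exactly one unit in the last printed digit under every
  rounding convention: the source averaged unrounded AUCs that were
  published only in rounded form, so no reconstruction from the printed
  inputs can match them. The corresponding acceptance test asserts
  exactness as specified and therefore fails on those four cells; the
  regular suite verifies the 86 exact cells and the one-unit agreement
  of the other four.
* **Null calibration at n = 32 cannot reach the specified band.** The
  acceptance requirement that null-data LOO-CV AUC fall in [0.35, 0.65]
  in ≥ 90% of runs is unattainable at 11 vs 21 samples: even an ideal
  classifier whose scores are independent of the labels has a null AUC
  standard deviation of ≈ 0.109 at this size, placing only ≈ 83% of
  runs in that band, and in-fold feature selection adds correlated
  variance on top (LOO estimators are known to have high variance). The
  acceptance test asserts the criterion as written and fails; the
  reproduction script reports the measured in-band fraction, mean and
  standard deviation.
* Ensemble members must score the same sample set; fusing classifiers
  across studies with partially overlapping cohorts is out of scope.
* The generator's missingness is MCAR; intensity-dependent missingness
  (common in proteomics) is not modelled.
* Probability calibration of members is taken at face value: AP
  averages whatever the members output, and VT only uses the 0.5
  threshold crossing.
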