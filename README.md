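# panelfuse

Biomarker panel development and proteo-genomic ensemble classification.

`panelfuse` implements a complete computational pipeline for building
small diagnostic biomarker panels from high-dimensional omics data and
for fusing independently developed per-platform classifiers into
*late-fusion ensembles*. It targets the setting typical of clinical
biomarker studies: a few dozen samples in two imbalanced classes, one
large complete matrix (e.g. transcript microarray log2 intensities) and
one small sparse matrix (e.g. iTRAQ protein ratios with missing values).

## The scientific problem

A single-platform classifier built from, say, blood transcriptomics
captures one view of a condition (an immunological signature), while a
proteomic classifier may capture another (an inflammation signature).
Merging the raw data across platforms is hampered by scale and
normalization differences and by one platform dominating the selection.
`panelfuse` instead develops each classifier fully within its platform
and fuses only their predicted class probabilities:

* **Average Probability (AP)** — the ensemble probability is a
  (optionally weighted) mean of member probabilities.
* **Vote Threshold (VT)** — a sample is called positive when at least
  `v` members call it positive at the 0.5 cutoff. The ensemble score is
  the `v`-th largest member probability, the order statistic that
  crosses the cutoff exactly when the vote rule fires. For `v = 1` this
  provably gives ensemble sensitivity at or above the best member and
  specificity at or below the worst member.

## The per-platform pipeline

Each member classifier is produced by a configurable chain, and every
data-dependent stage is re-run inside each cross-validation training
fold so held-out probabilities are untouched by their own samples:

1. **Prefilter** — an empirical central mass range (ECMR) filter removes
   low-variation features: `ECMR(x) = Q(1 − f1/2) − Q(f1/2)` with `f1`
   the minority-class fraction, and only features *strictly above* the
   median feature ECMR are kept. (At `f1 = 0.5` the ECMR is the
   inter-quartile range.) Sparse platforms instead use a detection-rate
   filter (e.g. observed in ≥ 75% of samples).
2. **Imputation** — k-nearest-neighbour over samples (`k = 3`),
   distances averaged over co-observed features; test samples are
   imputed against the completed training matrix without modifying it.
3. **Univariate selection** — empirical-Bayes moderated t-statistics
   (variance shrinkage toward a moment-matched prior), Benjamini-
   Hochberg FDR, optional fold-change cutoffs and panel-size bounds.
4. **Optional multivariate re-ranking** — SVM squared-weight or random
   forest importance.
5. **Learner** — linear SVM (with Platt-calibrated probabilities), LDA,
   elastic-net logistic regression, or random forest; `lambda` (EN) and
   the feature count (LDA) are tunable via nested cross-validation with
   a minimum-misclassification or AUC-within-one-standard-error rule.

## Worked example

Build one classifier per platform on a seeded synthetic two-platform
study, estimate held-out probabilities by leave-one-out cross-validation
and fuse them with platform-balanced weights:

```python
from panelfuse import (
    CVScheme, PipelineRecipe, PrefilterConfig, SelectionConfig, LearnerSpec,
    ImputeConfig, PlatformConfig, SyntheticConfig, Scale,
    generate, cv_probabilities, evaluate,
    ProbabilityMatrix, aggregate_ap, platform_balanced_weights,
)

# 1. A seeded two-platform study: 11 positive / 21 negative samples
config = SyntheticConfig(
    n_pos=11, n_neg=21, seed=7, signal_overlap=0.4,
    genomic=PlatformConfig(name="genomic", n_features=1000,
                           n_informative=30, effect_size=1.1),
    proteomic=PlatformConfig(name="proteomic", scale=Scale.RATIO,
                             n_features=120, n_informative=20,
                             effect_size=1.2, baseline_mean=0.0,
                             baseline_sd=0.5, missing_rate=0.15),
)
study = generate(config)

# 2. One pipeline per platform, every stage re-run inside each LOO fold
genomic_recipe = PipelineRecipe(
    learner=LearnerSpec("svm_linear", seed=0),
    prefilter=PrefilterConfig(kind="ecmr"),
    selection=SelectionConfig(top_k=10),
    classifier_id="genomic_svm",
)
proteomic_recipe = PipelineRecipe(
    learner=LearnerSpec("elastic_net", en_lambda=0.05, seed=0),
    prefilter=PrefilterConfig(kind="detection", min_rate=0.75),
    impute=ImputeConfig(k=3),
    selection=SelectionConfig(top_k=8),
    classifier_id="proteomic_en",
)
scheme = CVScheme("loo")
probs_g = cv_probabilities(genomic_recipe, study.genomic, study.labels, scheme)
probs_p = cv_probabilities(proteomic_recipe, study.proteomic, study.labels, scheme)

# 3. Fuse the held-out probabilities with platform-balanced weights
pm = ProbabilityMatrix.from_probability_sets(
    [probs_g, probs_p], platforms={"genomic_svm": "genomic",
                                   "proteomic_en": "proteomic"})
weights = platform_balanced_weights(["genomic", "proteomic"])
fused = aggregate_ap(pm, weights=weights, ensemble_id="proteo_genomic_ap")

for name, probs in (("genomic_svm", probs_g), ("proteomic_en", probs_p),
                    ("ensemble_ap", fused)):
    perf = evaluate(probs, study.labels)
    print(f"{name:14s} sens={perf.sensitivity:.2f} "
          f"spec={perf.specificity:.2f} auc={perf.auc:.3f}")
```

Output (runs in a few seconds):

```
genomic_svm    sens=0.36 spec=0.90 auc=0.740
proteomic_en   sens=0.27 spec=0.81 auc=0.615
ensemble_ap    sens=0.36 spec=0.90 auc=0.753
```

With the two platforms detecting the condition in partly different
positive samples (`signal_overlap=0.4`), the averaged probabilities rank
samples better than either member alone — the AUC rises above the best
member — while the thresholded calls track the stronger member.

## Bundled case-study tables

Two published two-platform case studies ship as plain TSV data: a renal
transplant rejection study (10 classifiers, 5 ensembles, 11/21 samples)
and a pan-cancer tumour/normal study (24 classifiers, 6 ensembles,
38/19 samples). Because sensitivities and specificities are counts over
known denominators, the exact fractions behind the 2-decimal printed
values can be recovered and member metrics averaged without compounding
rounding error:

```python
from panelfuse.studies import load_study, member_summary_table
table = member_summary_table(load_study("kidney"))
print(table[["sensitivity_min", "sensitivity_max",
             "sensitivity_average", "auc_average"]])
```

```
            sensitivity_min  sensitivity_max  sensitivity_average  auc_average
Ensemble 1             0.64             0.73                 0.68         0.84
Ensemble 2             0.55             0.82                 0.69         0.88
Ensemble 3             0.64             0.73                 0.65         0.89
Ensemble 4             0.55             0.73                 0.64         0.90
Ensemble 5             0.55             0.82                 0.66         0.90
```

## Command-line interface

All stages are available as a `panelfuse` CLI driven by one YAML config
(`panelfuse show-config` prints every default):

```
panelfuse simulate --seed 17 --out data/
panelfuse filter   --matrix data/genomic.tsv --labels data/labels.tsv --out panel.tsv
panelfuse crossval --matrix data/genomic.tsv --labels data/labels.tsv \
                   --classifier-id genomic_svm --out probs_g.tsv
panelfuse ensemble --probs probs_g.tsv --probs probs_p.tsv \
                   --labels data/labels.tsv --method ap --out report.json
panelfuse report   --reports report.json --out table.tsv
```

## Reproduction

The quantitative claims in this repository are recomputed by:

```
python -m pytest -q tests/           # unit, property and acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The script writes every case-study member-summary cell, the prefilter
counting check (27,306 of 54,613 features retained by the
strictly-above-median ECMR rule), the vote-threshold dominance scan, the
AUC estimator cross-check against brute-force pair counting, moderated-t
and Benjamini-Hochberg oracles, the cross-validation leakage guard, the
null-calibration and strong-signal experiments, and the imputation
exactness checks, as `{"name": {"value": ..., "n": ...}}` entries.

Two acceptance tests fail by design; see `docs/methods.md`
("Limitations") for why the four printed AUC-average table cells and the
null-calibration band requirement are unattainable as stated.

See `docs/methods.md` for the precise statistical definitions and
numerical conventions.
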