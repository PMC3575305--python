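"""Calibration and sanity experiments on synthetic data.

These seeded experiments characterise the behaviour of the full pipeline
(held-out probability estimation with in-fold feature selection) under
known conditions: a null condition with no class signal, a strong-signal
condition, feature-recovery under a moderate signal, and the dependence of
the ensemble gain on how much the two platforms' signals overlap. They are
used both by the test suite and by the reproduction script.

Feature-space sizes default to a few hundred features so a full experiment
runs in minutes on one core; the class shape (11 positive / 21 negative)
mirrors the transplant case study.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .crossval import CVScheme, PipelineRecipe, PrefilterConfig, cv_probabilities
from .data_model import LabelSet, OmicsMatrix
from .feature_selection import SelectionConfig, moderated_t, univariate_select
from .imputation import ImputeConfig
from .learners import LearnerSpec
from .metrics import auc as rank_auc
from .synthetic import PlatformConfig, SyntheticConfig, generate

__all__ = [
    "base_config",
    "default_recipe",
    "loo_auc",
    "null_calibration",
    "signal_sanity",
    "feature_recovery",
    "diversity_gain",
]


def base_config(seed: int, effect_size: float, n_features: int = 300,
                n_informative: int = 50, signal_overlap: float = 1.0) -> SyntheticConfig:
    """Synthetic study in the 11/21 case-study shape with a scaled-down
    genomic-like feature space."""
    return SyntheticConfig(
        n_pos=11, n_neg=21, seed=seed, signal_overlap=signal_overlap,
        genomic=PlatformConfig(name="genomic", n_features=n_features,
                               n_informative=n_informative, effect_size=effect_size),
        proteomic=PlatformConfig(name="proteomic", scale="ratio", n_features=100,
                                 n_informative=20, effect_size=effect_size,
                                 baseline_mean=0.0, baseline_sd=0.5,
                                 missing_rate=0.15),
    )


def default_recipe(kind: str = "svm_linear", top_k: int = 10, seed: int = 0,
                   prefilter: str = "ecmr") -> PipelineRecipe:
    """Standard pipeline: ECMR prefilter, moderated-t top-k panel, one learner."""
    return PipelineRecipe(
        learner=LearnerSpec(kind, seed=seed),
        prefilter=PrefilterConfig(kind=prefilter),
        impute=ImputeConfig(k=3),
        selection=SelectionConfig(top_k=top_k),
    )


def loo_auc(recipe: PipelineRecipe, matrix: OmicsMatrix, labels: LabelSet) -> float:
    probs = cv_probabilities(recipe, matrix, labels, CVScheme("loo"))
    return rank_auc(probs, labels)


def null_calibration(n_runs: int = 50, seed: int = 0, n_features: int = 300) -> list[float]:
    """LOO-CV AUCs of the standard pipeline on data with zero class effect.

    With no signal the held-out AUC should scatter around 0.5; systematic
    departures would indicate information leaking from held-out samples into
    feature selection or training.
    """
    aucs = []
    for r in range(n_runs):
        cfg = base_config(seed=seed + r, effect_size=0.0, n_features=n_features)
        ds = generate(cfg)
        recipe = default_recipe("svm_linear", seed=seed + r)
        aucs.append(loo_auc(recipe, ds.genomic, ds.labels))
    return aucs


def signal_sanity(seed: int = 0, effect_size: float = 3.0,
                  n_features: int = 300) -> dict[str, float]:
    """LOO-CV AUC of each learner kind on strongly separated classes."""
    cfg = base_config(seed=seed, effect_size=effect_size, n_features=n_features)
    ds = generate(cfg)
    out = {}
    for kind in ("svm_linear", "lda", "elastic_net", "random_forest"):
        recipe = default_recipe(kind, seed=seed)
        out[kind] = loo_auc(recipe, ds.genomic, ds.labels)
    return out


def feature_recovery(n_seeds: int = 20, seed: int = 0, effect_size: float = 2.0,
                     n_features: int = 2000, n_informative: int = 50,
                     top_k: int = 50) -> float:
    """Average fraction of truly informative features in the univariate
    top-k panel, over seeds."""
    fractions = []
    for r in range(n_seeds):
        cfg = base_config(seed=seed + r, effect_size=effect_size,
                          n_features=n_features, n_informative=n_informative)
        ds = generate(cfg)
        stats = moderated_t(ds.genomic, ds.labels)
        panel = univariate_select(stats, SelectionConfig(top_k=top_k))
        truth = set(ds.informative["genomic"])
        fractions.append(len(truth & set(panel.feature_ids)) / top_k)
    return float(np.mean(fractions))


def diversity_gain(overlaps: tuple[float, ...] = (0.0, 0.5, 1.0),
                   n_seeds: int = 3, seed: int = 0,
                   effect_size: float = 1.5) -> dict[float, float]:
    """Mean AP-ensemble AUC gain over the best member, per signal overlap.

    Lower overlap means the two platforms detect the condition in different
    positive samples, making the per-platform classifiers more complementary
    and the fusion gain larger.
    """
    from .ensemble import ProbabilityMatrix, aggregate_ap

    gains: dict[float, list[float]] = {o: [] for o in overlaps}
    for o in overlaps:
        for r in range(n_seeds):
            cfg = base_config(seed=seed + r, effect_size=effect_size,
                              n_features=200, signal_overlap=o)
            ds = generate(cfg)
            probs_g = cv_probabilities(
                replace(default_recipe("svm_linear", seed=seed + r),
                        classifier_id="genomic_svm"),
                ds.genomic, ds.labels, CVScheme("loo"))
            probs_p = cv_probabilities(
                replace(default_recipe("svm_linear", seed=seed + r, prefilter="detection"),
                        classifier_id="proteomic_svm"),
                ds.proteomic, ds.labels, CVScheme("loo"))
            pm = ProbabilityMatrix.from_probability_sets([probs_g, probs_p])
            ens = aggregate_ap(pm)
            best = max(rank_auc(probs_g, ds.labels), rank_auc(probs_p, ds.labels))
            gains[o].append(rank_auc(ens, ds.labels) - best)
    return {o: float(np.mean(v)) for o, v in gains.items()}
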