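"""Pipeline orchestration and cross-validated probability estimation.

A :class:`PipelineRecipe` chains the selection stages (prefilter ->
imputation -> univariate selection -> optional multivariate ranking) in
front of a learner. Cross-validation re-runs *every* data-dependent stage
inside each training fold, so the held-out probabilities are untouched by
information from their own samples; this is what makes them usable for
unbiased performance estimation and for downstream ensembling. When a
tuning grid is present, :func:`nested_cv` evaluates each grid point with an
inner cross-validation on the outer training set only, picks one by the
configured criterion, refits on the full outer training set and scores the
held-out samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .data_model import FeaturePanel, LabelSet, OmicsMatrix, PerformanceSummary, ProbabilitySet
from .feature_selection import (
    SelectionConfig,
    absolute_count_filter,
    detection_filter,
    ecmr_prefilter,
    moderated_t,
    multivariate_rank,
    random_forest_importance,
    svm_squared_weights,
    univariate_select,
)
from .imputation import ImputeConfig, knn_impute_test, knn_impute_train
from .learners import LearnerSpec, TrainedClassifier, predict_proba, train
from .metrics import auc as rank_auc
from .metrics import confusion_metrics, evaluate

logger = logging.getLogger(__name__)

__all__ = [
    "CVScheme",
    "PrefilterConfig",
    "MultivariateConfig",
    "PipelineRecipe",
    "FittedPipeline",
    "fit_pipeline",
    "predict_pipeline",
    "cv_probabilities",
    "nested_cv",
    "one_se_select",
    "cv_performance",
]


@dataclass
class CVScheme:
    """Cross-validation layout: leave-one-out or (repeated, stratified) k-fold."""

    kind: str = "loo"  # loo | kfold
    k: int = 10
    repeats: int = 1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("loo", "kfold"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def splits(self, labels: LabelSet, sample_ids: Sequence[str]
               ) -> Iterator[tuple[int, list[str], list[str]]]:
        """Yield (repeat_index, train_ids, test_ids) folds."""
        ids = list(sample_ids)
        if self.kind == "loo":
            for sid in ids:
                yield 0, [s for s in ids if s != sid], [sid]
            return
        if self.k > len(ids):
            raise ValueError(f"k = {self.k} exceeds {len(ids)} samples")
        from sklearn.model_selection import KFold, StratifiedKFold

        y = labels.y(ids)
        for r in range(self.repeats):
            seed = self.seed + r
            splitter = (StratifiedKFold(self.k, shuffle=True, random_state=seed)
                        if self.stratified else KFold(self.k, shuffle=True, random_state=seed))
            for train_idx, test_idx in splitter.split(np.zeros(len(ids)), y):
                yield r, [ids[i] for i in train_idx], [ids[i] for i in test_idx]


@dataclass
class PrefilterConfig:
    """Which pre-filter to run before univariate ranking."""

    kind: str = "ecmr"  # ecmr | detection | absolute_count | none
    q: float = 0.5            # ecmr: quantile of feature ECMRs to cut at
    min_rate: float = 0.75    # detection: minimum observed fraction
    expr_threshold: float = 0.0  # absolute_count
    min_samples: int = 1         # absolute_count

    def __post_init__(self) -> None:
        if self.kind not in ("ecmr", "detection", "absolute_count", "none"):
            raise ValueError(f"unknown prefilter kind {self.kind!r}")


@dataclass
class MultivariateConfig:
    """Model-importance reranking applied after univariate selection."""

    importance: str = "svm"  # svm | rf
    top_m: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.importance not in ("svm", "rf"):
            raise ValueError(f"unknown importance kind {self.importance!r}")


@dataclass
class PipelineRecipe:
    """Ordered stage configuration from raw matrix to trained classifier."""

    learner: LearnerSpec
    prefilter: PrefilterConfig | None = None
    impute: ImputeConfig | None = None
    selection: SelectionConfig | None = None
    multivariate: MultivariateConfig | None = None
    tuning_grid: dict[str, list] | None = None
    criterion: str = "min_misclassification"  # min_misclassification | max_auc_1se
    frozen_panel: FeaturePanel | None = None
    classifier_id: str | None = None

    def __post_init__(self) -> None:
        if self.criterion not in ("min_misclassification", "max_auc_1se"):
            raise ValueError(f"unknown selection criterion {self.criterion!r}")

    def grid_specs(self) -> list[LearnerSpec]:
        """Expand the tuning grid into concrete learner specs, ordered from
        the simplest model to the most complex."""
        if not self.tuning_grid:
            return [self.learner]
        import itertools

        keys = sorted(self.tuning_grid)
        specs = []
        for combo in itertools.product(*(self.tuning_grid[k] for k in keys)):
            specs.append(replace(self.learner, **dict(zip(keys, combo))))
        specs.sort(key=_complexity)
        return specs


def _complexity(spec: LearnerSpec) -> tuple:
    """Ordering key: smaller is simpler. Fewer LDA features and stronger
    elastic-net shrinkage count as simpler."""
    lda_k = spec.lda_n_features if spec.lda_n_features is not None else np.inf
    return (lda_k, -spec.en_lambda)


@dataclass
class FittedPipeline:
    """A trained classifier plus the completed training matrix it saw
    (needed to impute test samples) and the per-stage feature counts."""

    classifier: TrainedClassifier
    train_matrix: OmicsMatrix
    panel: FeaturePanel
    stage_counts: list[tuple[str, int]] = field(default_factory=list)


def _run_prefilter(cfg: PrefilterConfig, matrix: OmicsMatrix, labels: LabelSet) -> FeaturePanel | None:
    if cfg.kind == "none":
        return None
    if cfg.kind == "ecmr":
        return ecmr_prefilter(matrix, labels.subset(matrix.sample_ids), q=cfg.q)
    if cfg.kind == "detection":
        return detection_filter(matrix, min_rate=cfg.min_rate)
    return absolute_count_filter(matrix, cfg.expr_threshold, cfg.min_samples)


def fit_pipeline(recipe: PipelineRecipe, matrix: OmicsMatrix, labels: LabelSet) -> FittedPipeline:
    """Run all selection stages on the given (training) data and fit the learner."""
    labels = labels.subset(matrix.sample_ids)
    labels.require_both_classes()
    counts: list[tuple[str, int]] = [("input", matrix.n_features)]
    m = matrix

    if recipe.frozen_panel is not None:
        m = m.subset_features(recipe.frozen_panel.feature_ids)
        counts.append(("frozen_panel", m.n_features))
        if not m.is_complete:
            m = knn_impute_train(m, recipe.impute or ImputeConfig())
        panel = recipe.frozen_panel
        clf = train(recipe.learner, m, labels, panel, classifier_id=recipe.classifier_id)
        counts.append(("panel", len(clf.panel)))
        return FittedPipeline(clf, m, clf.panel, counts)

    if recipe.prefilter is not None and recipe.prefilter.kind == "detection":
        pre = _run_prefilter(recipe.prefilter, m, labels)
        m = m.subset_features(pre.feature_ids)
        counts.append(("detection_filter", m.n_features))

    if not m.is_complete:
        m = knn_impute_train(m, recipe.impute or ImputeConfig())
        counts.append(("imputed", m.n_features))

    if recipe.prefilter is not None and recipe.prefilter.kind in ("ecmr", "absolute_count"):
        pre = _run_prefilter(recipe.prefilter, m, labels)
        m = m.subset_features(pre.feature_ids)
        counts.append((f"{recipe.prefilter.kind}_prefilter", m.n_features))

    if recipe.selection is not None:
        stats = moderated_t(m, labels)
        panel = univariate_select(stats, recipe.selection)
        counts.append(("univariate", len(panel)))
    else:
        # fall through with all surviving features, in matrix order
        panel = FeaturePanel(list(m.feature_ids), {f: 0.0 for f in m.feature_ids},
                             stage="passthrough")

    if recipe.multivariate is not None:
        fn = (svm_squared_weights if recipe.multivariate.importance == "svm"
              else lambda X, y: random_forest_importance(X, y, seed=recipe.multivariate.seed))
        panel = multivariate_rank(m, labels, panel, fn,
                                  top_m=min(recipe.multivariate.top_m, len(panel)))
        counts.append(("multivariate", len(panel)))

    m = m.subset_features(panel.feature_ids)
    clf = train(recipe.learner, m, labels, panel, classifier_id=recipe.classifier_id)
    counts.append(("panel", len(clf.panel)))
    for stage, n in counts:
        logger.debug("stage %s: %d features", stage, n)
    return FittedPipeline(clf, m, clf.panel, counts)


def predict_pipeline(fit: FittedPipeline, test: OmicsMatrix,
                     impute: ImputeConfig | None = None,
                     origin: str = "cv_heldout") -> ProbabilitySet:
    """Score new samples with a fitted pipeline.

    Test samples are first restricted to the features the training pipeline
    kept; missing test entries are imputed against the completed training
    matrix (training cells are never modified)."""
    sub = test.subset_features(fit.train_matrix.feature_ids)
    if not sub.is_complete:
        sub = knn_impute_test(fit.train_matrix, sub, impute or ImputeConfig())
    return predict_proba(fit.classifier, sub, origin=origin)


def cv_probabilities(recipe: PipelineRecipe, matrix: OmicsMatrix, labels: LabelSet,
                     scheme: CVScheme, return_details: bool = False):
    """Held-out probability of the positive class for every sample.

    Every data-dependent stage re-runs inside each training fold. For
    repeated k-fold, each sample's probabilities are averaged over repeats.
    """
    labels = labels.subset(matrix.sample_ids)
    per_sample: dict[str, list[float]] = {s: [] for s in matrix.sample_ids}
    details = []
    for rep, train_ids, test_ids in scheme.splits(labels, matrix.sample_ids):
        fold_labels = labels.subset(train_ids)
        if fold_labels.n_pos == 0 or fold_labels.n_neg == 0:
            raise ValueError(
                "a training fold lost a whole class; use stratified folds or larger k"
            )
        fit = fit_pipeline(recipe, matrix.subset_samples(train_ids), fold_labels)
        probs = predict_pipeline(fit, matrix.subset_samples(test_ids),
                                 impute=recipe.impute)
        for sid, p in probs.probabilities.items():
            per_sample[sid].append(p)
        if return_details:
            details.append((rep, test_ids, fit))
    cid = recipe.classifier_id or f"{recipe.learner.kind}_cv"
    result = ProbabilitySet(
        cid, {s: float(np.mean(ps)) for s, ps in per_sample.items()},
        origin="cv_heldout",
    )
    if return_details:
        return result, details
    return result


def _per_repeat_auc(recipe: PipelineRecipe, matrix: OmicsMatrix, labels: LabelSet,
                    scheme: CVScheme) -> tuple[list[float], float]:
    """Inner-CV evaluation of a fixed recipe: per-repeat AUCs and overall
    misclassification error at the 0.5 cutoff."""
    labels = labels.subset(matrix.sample_ids)
    per_rep: dict[int, dict[str, float]] = {}
    for rep, train_ids, test_ids in scheme.splits(labels, matrix.sample_ids):
        fit = fit_pipeline(recipe, matrix.subset_samples(train_ids),
                           labels.subset(train_ids))
        probs = predict_pipeline(fit, matrix.subset_samples(test_ids),
                                 impute=recipe.impute)
        per_rep.setdefault(rep, {}).update(probs.probabilities)
    aucs = []
    all_probs: dict[str, list[float]] = {}
    for rep in sorted(per_rep):
        ps = ProbabilitySet("inner", per_rep[rep], origin="cv_heldout")
        aucs.append(rank_auc(ps, labels))
        for s, p in per_rep[rep].items():
            all_probs.setdefault(s, []).append(p)
    mean_probs = ProbabilitySet("inner", {s: float(np.mean(v)) for s, v in all_probs.items()},
                                origin="cv_heldout")
    mis = confusion_metrics(mean_probs, labels)["misclassification_error"]
    return aucs, mis


def one_se_select(candidates: Sequence[tuple[object, float, float, float]]) -> object:
    """One-standard-error rule over (model_id, complexity, mean_auc, se_auc).

    Returns the least-complex candidate whose mean AUC is within one
    standard error of the best candidate's mean AUC.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("empty candidate list")
    for _, _, _, se in cands:
        if se < 0:
            raise ValueError("standard errors must be non-negative")
    best = max(cands, key=lambda c: c[2])
    floor = best[2] - best[3]
    eligible = [c for c in cands if c[2] >= floor]
    return min(eligible, key=lambda c: c[1])[0]


def _choose_spec(recipe: PipelineRecipe, matrix: OmicsMatrix, labels: LabelSet,
                 inner: CVScheme) -> LearnerSpec:
    """Evaluate each grid point with the inner CV and apply the criterion."""
    specs = recipe.grid_specs()
    if len(specs) == 1:
        return specs[0]
    results = []  # (spec, complexity_rank, aucs, misclass)
    for rank, spec in enumerate(specs):
        candidate = replace(recipe, learner=spec, tuning_grid=None)
        try:
            aucs, mis = _per_repeat_auc(candidate, matrix, labels, inner)
        except ValueError as exc:
            logger.warning("dropping infeasible grid point %s: %s", spec, exc)
            continue
        results.append((spec, rank, aucs, mis))
    if not results:
        raise ValueError("no feasible grid point in this fold")
    if recipe.criterion == "min_misclassification":
        # ties break toward the simpler model (specs are ordered simple->complex)
        return min(results, key=lambda r: (r[3], r[1]))[0]
    cands = []
    for spec, rank, aucs, _ in results:
        mean = float(np.mean(aucs))
        se = float(np.std(aucs, ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0
        cands.append((spec, rank, mean, se))
    return one_se_select(cands)


def nested_cv(recipe: PipelineRecipe, matrix: OmicsMatrix, labels: LabelSet,
              outer: CVScheme, inner: CVScheme
              ) -> tuple[ProbabilitySet, list[LearnerSpec]]:
    """Hyperparameter tuning inside each outer training fold.

    For every outer fold the inner CV evaluates each grid point on the outer
    training set only; the chosen pipeline is refit on the full outer
    training set and scores the held-out samples. Returns the held-out
    probabilities and the learner spec chosen in each outer fold.
    """
    labels = labels.subset(matrix.sample_ids)
    per_sample: dict[str, list[float]] = {s: [] for s in matrix.sample_ids}
    chosen: list[LearnerSpec] = []
    for rep, train_ids, test_ids in outer.splits(labels, matrix.sample_ids):
        train_m = matrix.subset_samples(train_ids)
        train_l = labels.subset(train_ids)
        spec = _choose_spec(recipe, train_m, train_l, inner)
        chosen.append(spec)
        fit = fit_pipeline(replace(recipe, learner=spec, tuning_grid=None),
                           train_m, train_l)
        probs = predict_pipeline(fit, matrix.subset_samples(test_ids),
                                 impute=recipe.impute)
        for sid, p in probs.probabilities.items():
            per_sample[sid].append(p)
    cid = recipe.classifier_id or f"{recipe.learner.kind}_nested_cv"
    result = ProbabilitySet(
        cid, {s: float(np.mean(ps)) for s, ps in per_sample.items()},
        origin="cv_heldout",
    )
    return result, chosen


def cv_performance(probs: ProbabilitySet, labels: LabelSet,
                   cutoff: float = 0.5) -> PerformanceSummary:
    """Performance summary of held-out probabilities."""
    return evaluate(probs, labels, cutoff=cutoff)
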