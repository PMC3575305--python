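"""Uniform adapter over the four supervised learners.

All learners share one contract: fit on a (panel features x training
samples) slice plus binary labels, and return a probability of the positive
class for new samples. Supported kinds:

* ``svm_linear`` -- linear-kernel SVM; decision scores are mapped to
  probabilities by a Platt-type sigmoid fitted on the training scores, a
  strictly monotone map so probability rankings (and hence AUC) match the
  raw margin rankings.
* ``lda`` -- linear discriminant analysis; requires fewer features than
  training samples, so wide panels must be cut down (typically by tuning
  the feature count).
* ``elastic_net`` -- elastic-net-penalized logistic regression with the
  L1/L2 mixing weight fixed (default 0.5) and the penalty strength lambda
  tuned.
* ``random_forest`` -- seeded random forest with mtry = floor(sqrt(p)) and
  minimum node size 1.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .data_model import FeaturePanel, LabelSet, OmicsMatrix, ProbabilitySet

__all__ = ["LearnerSpec", "TrainedClassifier", "train", "predict_proba",
           "save_classifier", "load_classifier"]

KINDS = ("svm_linear", "lda", "elastic_net", "random_forest")

_SERIAL_VERSION = 1


@dataclass(frozen=True)
class LearnerSpec:
    """Learner kind plus hyperparameters.

    ``en_lambda`` and ``lda_n_features`` are the tunable parameters (penalty
    strength and feature count); the others are held at fixed defaults.
    """

    kind: str
    svm_cost: float = 1.0
    en_alpha: float = 0.5       # L1/L2 mixing, fixed
    en_lambda: float = 0.1      # penalty strength, tuned
    lda_n_features: int | None = None  # tuned; None = use full panel
    rf_n_trees: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}; choose from {KINDS}")
        if not (0.0 <= self.en_alpha <= 1.0):
            raise ValueError(f"elastic-net alpha must lie in [0,1], got {self.en_alpha}")
        if self.en_lambda < 0:
            raise ValueError("elastic-net lambda must be >= 0")


@dataclass
class TrainedClassifier:
    """A fitted model bound to the exact feature panel it was trained on."""

    classifier_id: str
    spec: LearnerSpec
    panel: FeaturePanel
    model: object
    platform: str = "generic"
    # Platt sigmoid coefficients for SVM score -> probability mapping
    calibration: tuple[float, float] | None = None


def _design(matrix: OmicsMatrix, panel: FeaturePanel) -> np.ndarray:
    sub = matrix.subset_features(panel.feature_ids)
    if not sub.is_complete:
        raise ValueError("training/prediction matrix must be complete (impute first)")
    return sub.values.T  # samples x features


def _fit_platt(scores: np.ndarray, y: np.ndarray, seed: int) -> tuple[float, float]:
    """Fit p = sigmoid(a*score + b) on training decision scores.

    A mild ridge penalty keeps the fit finite on separable data; the map is
    monotone in the score either way, so rankings are preserved.
    """
    lr = LogisticRegression(C=1e3, solver="lbfgs", max_iter=1000, random_state=seed)
    lr.fit(scores.reshape(-1, 1), y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def _polish_intercept(pipeline, X: np.ndarray, y: np.ndarray) -> None:
    """Re-solve the unpenalized intercept exactly, holding coefficients fixed.

    The saga step size shrinks with the penalty strength, so at very large
    lambda the solver can stop with the (unpenalized) intercept far from its
    optimum. A 1-D Newton solve with the linear predictor fixed restores the
    convention that the intercept is never shrunk; at a converged solution
    this is a no-op.
    """
    scaler, lr = pipeline.named_steps.values()
    z = scaler.transform(X) @ lr.coef_.ravel()
    b = float(lr.intercept_[0])
    yy = (y == lr.classes_[1]).astype(float)
    for _ in range(100):
        p = 1.0 / (1.0 + np.exp(-(z + b)))
        g = float((p - yy).sum())
        h = float((p * (1 - p)).sum())
        if abs(g) < 1e-12 or h <= 0:
            break
        b -= g / h
    lr.intercept_[0] = b


def train(spec: LearnerSpec, matrix: OmicsMatrix, labels: LabelSet,
          panel: FeaturePanel, classifier_id: str | None = None) -> TrainedClassifier:
    """Fit one classifier on the panel's feature slice of the matrix."""
    labels.require_both_classes()
    use_panel = panel
    if spec.kind == "lda":
        n_train = matrix.n_samples
        k = spec.lda_n_features if spec.lda_n_features is not None else len(panel)
        if k >= n_train:
            raise ValueError(
                f"LDA needs fewer features than training samples "
                f"({k} features vs {n_train} samples); tune lda_n_features"
            )
        use_panel = panel.head(k) if k < len(panel) else panel

    X = _design(matrix, use_panel)
    y = labels.y(matrix.sample_ids)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")

    calibration = None
    if spec.kind == "svm_linear":
        model = SVC(kernel="linear", C=spec.svm_cost, random_state=spec.seed)
        model.fit(X, y)
        calibration = _fit_platt(model.decision_function(X), y, spec.seed)
    elif spec.kind == "lda":
        model = LinearDiscriminantAnalysis()
        model.fit(X, y)
    elif spec.kind == "elastic_net":
        # glmnet conventions: standardize features, penalty strength lambda
        # with C = 1 / (n * lambda)
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        n = X.shape[0]
        lam = max(spec.en_lambda, 1e-12)
        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(
                solver="saga", l1_ratio=spec.en_alpha,
                C=1.0 / (n * lam), max_iter=20000, random_state=spec.seed, tol=1e-6,
            ),
        )
        model.fit(X, y)
        _polish_intercept(model, X, y)
    else:  # random_forest
        model = RandomForestClassifier(
            n_estimators=spec.rf_n_trees, max_features="sqrt",
            min_samples_leaf=1, random_state=spec.seed,
        )
        model.fit(X, y)

    cid = classifier_id or f"{spec.kind}_{len(use_panel)}"
    return TrainedClassifier(cid, spec, use_panel, model,
                             platform=matrix.platform, calibration=calibration)


def predict_proba(clf: TrainedClassifier, matrix: OmicsMatrix,
                  origin: str = "test") -> ProbabilitySet:
    """Probability of the positive class for every sample in the matrix."""
    X = _design(matrix, clf.panel)
    if clf.spec.kind == "svm_linear":
        scores = clf.model.decision_function(X)
        a, b = clf.calibration
        p = 1.0 / (1.0 + np.exp(-(a * scores + b)))
    else:
        proba = clf.model.predict_proba(X)
        pos_col = int(np.flatnonzero(clf.model.classes_ == 1)[0])
        p = proba[:, pos_col]
    p = np.clip(p, 0.0, 1.0)
    return ProbabilitySet(clf.classifier_id,
                          dict(zip(matrix.sample_ids, map(float, p))),
                          origin=origin)


def save_classifier(clf: TrainedClassifier, path: str | Path) -> None:
    payload = {"version": _SERIAL_VERSION, "classifier": clf}
    Path(path).write_bytes(pickle.dumps(payload))


def load_classifier(path: str | Path) -> TrainedClassifier:
    payload = pickle.loads(Path(path).read_bytes())
    if payload.get("version") != _SERIAL_VERSION:
        raise ValueError(f"unsupported classifier file version: {payload.get('version')}")
    return payload["classifier"]
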