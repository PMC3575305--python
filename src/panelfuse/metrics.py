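"""Classification performance metrics.

Thresholded metrics (sensitivity, specificity, misclassification error) use
a probability cutoff that is closed on the positive side: a sample is called
positive when its probability is at or above the cutoff. The AUC is the
rank-based Mann-Whitney estimator with half credit for ties, so it depends
only on the ordering of the probabilities.
"""

from __future__ import annotations

from fractions import Fraction
from numbers import Real
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .data_model import LabelSet, PerformanceSummary, ProbabilitySet

__all__ = ["confusion_metrics", "auc", "evaluate", "member_summary"]


def _aligned(probs: ProbabilitySet, labels: LabelSet) -> tuple[np.ndarray, np.ndarray]:
    ids = probs.sample_ids
    unlabeled = [s for s in ids if s not in labels.assignment]
    if unlabeled:
        raise ValueError(f"samples without labels: {unlabeled[:5]}")
    return probs.array(ids), labels.y(ids)


def confusion_metrics(probs: ProbabilitySet, labels: LabelSet,
                      cutoff: float = 0.5) -> dict[str, float]:
    """Sensitivity, specificity and misclassification error at a cutoff.

    Predicted positive iff p >= cutoff (a probability exactly at the cutoff
    counts as a positive call).
    """
    p, y = _aligned(probs, labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute confusion metrics")
    pred = p >= cutoff
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    return {
        "sensitivity": tp / n_pos,
        "specificity": tn / n_neg,
        "misclassification_error": ((n_pos - tp) + (n_neg - tn)) / (n_pos + n_neg),
    }


def auc(probs: ProbabilitySet, labels: LabelSet) -> float:
    """Mann-Whitney AUC: the fraction of (positive, negative) pairs where the
    positive sample scores higher, counting ties as half."""
    p, y = _aligned(probs, labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(p)  # average ranks handle ties with half credit
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate(probs: ProbabilitySet, labels: LabelSet, cutoff: float = 0.5) -> PerformanceSummary:
    """Full performance summary (thresholded metrics plus AUC)."""
    cm = confusion_metrics(probs, labels, cutoff=cutoff)
    return PerformanceSummary(
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        misclassification_error=cm["misclassification_error"],
        auc=auc(probs, labels),
        cutoff=cutoff,
    )


def member_summary(values: Sequence[Real]) -> dict[str, Real]:
    """Min, max and arithmetic mean of one metric over ensemble members.

    Exact arithmetic is preserved when the inputs are exact (`Fraction`),
    so table presentation can round once at the end.
    """
    vals = list(values)
    if not vals:
        raise ValueError("member_summary needs at least one value")
    if all(isinstance(v, (Fraction, int)) for v in vals):
        avg: Real = Fraction(sum(Fraction(v) for v in vals), len(vals))
    else:
        avg = float(np.mean([float(v) for v in vals]))
    return {"min": min(vals), "max": max(vals), "average": avg}
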