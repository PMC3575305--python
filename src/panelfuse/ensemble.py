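"""Late-fusion ensemble classifiers over per-platform probability outputs.

Two aggregation rules are provided. Average Probability (AP) takes a
(possibly weighted) mean of member probabilities; Vote Threshold (VT) calls
a sample positive when at least v members vote positive at the cutoff, and
scores it with the v-th largest member probability so that the score crosses
the cutoff exactly when the vote rule fires. For v = 1 this makes the
ensemble score the maximum member probability, which guarantees ensemble
sensitivity at or above the best member and specificity at or below the
worst member.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_model import EnsembleReport, EnsembleSpec, LabelSet, ProbabilitySet
from .metrics import evaluate, member_summary

__all__ = [
    "ProbabilityMatrix",
    "aggregate_ap",
    "aggregate_vt",
    "platform_balanced_weights",
    "agreement_quadrants",
    "ensemble_report",
    "read_membership",
    "write_membership",
]


@dataclass
class ProbabilityMatrix:
    """Member classifiers x samples matrix of positive-class probabilities."""

    classifier_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platforms: dict[str, str] | None = None  # classifier_id -> platform tag
    origin: str = "cv_heldout"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.classifier_ids), len(self.sample_ids)):
            raise ValueError("probability matrix shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("every member must score every sample")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("probabilities must lie in [0,1]")

    @classmethod
    def from_probability_sets(cls, sets: Sequence[ProbabilitySet],
                              platforms: Mapping[str, str] | None = None) -> "ProbabilityMatrix":
        if not sets:
            raise ValueError("need at least one probability set")
        sample_ids = sets[0].sample_ids
        for ps in sets[1:]:
            if set(ps.sample_ids) != set(sample_ids):
                raise ValueError("probability sets cover different samples")
        values = np.array([ps.array(sample_ids) for ps in sets])
        origins = {ps.origin for ps in sets}
        if len(origins) > 1:
            raise ValueError(
                f"refusing to mix probability origins in one ensemble: {sorted(origins)}"
            )
        return cls([ps.classifier_id for ps in sets], list(sample_ids), values,
                   platforms=dict(platforms) if platforms else None,
                   origin=origins.pop())

    def select(self, members: Sequence[str]) -> "ProbabilityMatrix":
        idx = {c: i for i, c in enumerate(self.classifier_ids)}
        missing = [m for m in members if m not in idx]
        if missing:
            raise KeyError(f"members without probabilities: {missing}")
        rows = [idx[m] for m in members]
        return ProbabilityMatrix(list(members), list(self.sample_ids),
                                 self.values[rows, :], platforms=self.platforms,
                                 origin=self.origin)


def _check_weights(pm: ProbabilityMatrix, weights: Sequence[float] | None) -> np.ndarray:
    m = len(pm.classifier_ids)
    if weights is None:
        return np.full(m, 1.0 / m)
    w = np.asarray(weights, dtype=float)
    if w.shape != (m,):
        raise ValueError(f"expected {m} weights, got {w.shape}")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()}")
    return w


def aggregate_ap(pm: ProbabilityMatrix, weights: Sequence[float] | None = None,
                 ensemble_id: str = "ensemble") -> ProbabilitySet:
    """Average-probability aggregation: ensemble p = sum_i w_i p_i."""
    w = _check_weights(pm, weights)
    agg = w @ pm.values
    return ProbabilitySet(ensemble_id,
                          dict(zip(pm.sample_ids, map(float, agg))),
                          origin=pm.origin)


def aggregate_vt(pm: ProbabilityMatrix, v: int = 1, cutoff: float = 0.5,
                 ensemble_id: str = "ensemble") -> ProbabilitySet:
    """Vote-threshold aggregation.

    A member votes positive when its probability is at or above the cutoff;
    the ensemble calls positive when at least ``v`` members vote positive.
    The ensemble score is the v-th largest member probability, the order
    statistic that crosses the cutoff exactly when the vote count reaches v.
    """
    m = len(pm.classifier_ids)
    if not (1 <= v <= m):
        raise ValueError(f"vote threshold {v} outside [1, {m}]")
    scores = np.sort(pm.values, axis=0)[m - v, :]  # v-th largest per sample
    votes = (pm.values >= cutoff).sum(axis=0)
    assert bool(np.all((scores >= cutoff) == (votes >= v)))
    return ProbabilitySet(ensemble_id,
                          dict(zip(pm.sample_ids, map(float, scores))),
                          origin=pm.origin)


def platform_balanced_weights(platforms: Sequence[str]) -> list[float]:
    """Give each platform's classifier group equal total weight, split
    equally within the group (e.g. 2 genomic + 5 proteomic members get
    weights 0.25 each and 0.1 each)."""
    if not platforms:
        raise ValueError("no platforms given")
    groups = sorted(set(platforms))
    per_group = 1.0 / len(groups)
    counts = {g: platforms.count(g) for g in groups}
    return [per_group / counts[p] for p in platforms]


def agreement_quadrants(probs_a: ProbabilitySet, probs_b: ProbabilitySet,
                        labels: LabelSet, cutoff: float = 0.5) -> dict[str, dict[str, int]]:
    """Pairwise classifier agreement counts, per class.

    Each sample lands in exactly one quadrant of the (p_a, p_b) plane:
    concordant_correct, concordant_wrong, discordant_a_correct or
    discordant_b_correct.
    """
    if set(probs_a.sample_ids) != set(probs_b.sample_ids):
        raise ValueError("the two probability sets cover different samples")
    out = {cls: {"concordant_correct": 0, "concordant_wrong": 0,
                 "discordant_a_correct": 0, "discordant_b_correct": 0}
           for cls in ("positive", "negative")}
    for sid in probs_a.sample_ids:
        y = labels.assignment[sid]
        truth = y == "positive"
        call_a = probs_a.probabilities[sid] >= cutoff
        call_b = probs_b.probabilities[sid] >= cutoff
        if call_a == call_b:
            key = "concordant_correct" if call_a == truth else "concordant_wrong"
        else:
            key = "discordant_a_correct" if call_a == truth else "discordant_b_correct"
        out[y][key] += 1
    return out


def ensemble_report(pm: ProbabilityMatrix, labels: LabelSet, spec: EnsembleSpec,
                    cutoff: float = 0.5) -> EnsembleReport:
    """Evaluate one ensemble and its members on the same probability matrix."""
    sub = pm.select(spec.members)
    if spec.method == "AP":
        agg = aggregate_ap(sub, spec.weights, ensemble_id=spec.ensemble_id)
    else:
        agg = aggregate_vt(sub, v=spec.vote_threshold, cutoff=cutoff,
                           ensemble_id=spec.ensemble_id)
    ens_perf = evaluate(agg, labels, cutoff=cutoff)
    member_metrics = {}
    for i, member in enumerate(spec.members):
        ps = ProbabilitySet(member, dict(zip(sub.sample_ids, map(float, sub.values[i]))),
                            origin=sub.origin)
        member_metrics[member] = evaluate(ps, labels, cutoff=cutoff)
    summary = {}
    for metric in ("sensitivity", "specificity", "misclassification_error", "auc"):
        summary[metric] = {k: float(v) for k, v in member_summary(
            [getattr(member_metrics[m], metric) for m in spec.members]).items()}
    return EnsembleReport(spec=spec, ensemble=ens_perf,
                          member_metrics=member_metrics, member_summary=summary,
                          origin=pm.origin)


def read_membership(path: str | Path) -> dict[str, list[str]]:
    """Read an ensemble membership TSV (rows = classifiers, columns =
    ensembles, cell 'X' marks membership). Returns ensemble_id -> members."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ensemble_ids = header[1:]
        members: dict[str, list[str]] = {e: [] for e in ensemble_ids}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            clf = parts[0]
            cells = parts[1:] + [""] * (len(ensemble_ids) - len(parts) + 1)
            for e, cell in zip(ensemble_ids, cells):
                if cell.strip().upper() == "X":
                    members[e].append(clf)
    empty = [e for e, m in members.items() if not m]
    if empty:
        raise ValueError(f"ensemble(s) with no members: {empty}")
    return members


def write_membership(members: Mapping[str, Sequence[str]], path: str | Path) -> None:
    path = Path(path)
    ensemble_ids = list(members)
    classifiers: list[str] = []
    for ms in members.values():
        for m in ms:
            if m not in classifiers:
                classifiers.append(m)
    with path.open("w") as fh:
        fh.write("classifier\t" + "\t".join(ensemble_ids) + "\n")
        for clf in classifiers:
            cells = ["X" if clf in members[e] else "" for e in ensemble_ids]
            fh.write(clf + "\t" + "\t".join(cells) + "\n")
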