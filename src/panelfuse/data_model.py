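"""Core data containers and TSV readers/writers.

The package operates on feature-by-sample expression matrices from one or
more molecular platforms (microarray log2 intensities, mass-spectrometry
abundance ratios, ...), a binary sample labelling, ordered feature panels
produced by the selection stages, and per-sample class probabilities
produced by classifiers. All on-disk formats are plain tab-separated text.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "OmicsMatrix",
    "LabelSet",
    "FeaturePanel",
    "ProbabilitySet",
    "PerformanceSummary",
    "EnsembleSpec",
    "EnsembleReport",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_panel",
    "write_panel",
    "read_probabilities",
    "write_probabilities",
    "write_report",
    "read_report",
]

POSITIVE = "positive"
NEGATIVE = "negative"

_MISSING_TOKENS = {"", "na"}


class Scale(str, Enum):
    """Value scale of an omics matrix.

    ``log2_intensity`` matrices (e.g. RMA-normalised microarray data) are
    complete by construction; ``ratio`` matrices (e.g. iTRAQ abundance
    ratios against a pooled control) may contain missing entries.
    """

    LOG2_INTENSITY = "log2_intensity"
    RATIO = "ratio"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """A features x samples value matrix with an explicit missing mask.

    Values are stored as a float array with ``nan`` marking missing cells;
    the mask is derived, never inferred from sentinel values like 0.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform: str = "generic"
    scale: Scale = Scale.LOG2_INTENSITY

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.scale = Scale(self.scale)
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.feature_ids)} features, {len(self.sample_ids)} samples)"
            )
        if np.isinf(self.values).any():
            raise ValueError("matrix contains non-finite (inf) values")
        if self.scale == Scale.LOG2_INTENSITY and self.missing_mask.any():
            raise ValueError("log2_intensity matrix must not contain missing entries")

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (features x samples) array, True where the value is missing."""
        return np.isnan(self.values)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, platform: str = "generic", scale: Scale | str = Scale.LOG2_INTENSITY
    ) -> "OmicsMatrix":
        return cls(
            feature_ids=list(map(str, frame.index)),
            sample_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
            platform=platform,
            scale=Scale(scale),
        )

    def subset_features(self, features: Sequence[str]) -> "OmicsMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in features if f not in idx]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        rows = [idx[f] for f in features]
        return OmicsMatrix(list(features), list(self.sample_ids), self.values[rows, :],
                           platform=self.platform, scale=self.scale)

    def subset_samples(self, samples: Sequence[str]) -> "OmicsMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return OmicsMatrix(list(self.feature_ids), list(samples), self.values[:, cols],
                           platform=self.platform, scale=self.scale)


@dataclass
class LabelSet:
    """Binary class assignment per sample.

    The positive class (e.g. acute rejection, tumour) is always declared
    explicitly; it is never inferred from token order or alphabetically,
    because sensitivity and specificity depend on which class is positive.
    """

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.assignment.values()} - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"unknown class token(s): {sorted(bad)}")
        if not self.assignment:
            raise ValueError("empty label set")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment)

    @property
    def n_pos(self) -> int:
        return sum(1 for c in self.assignment.values() if c == POSITIVE)

    @property
    def n_neg(self) -> int:
        return sum(1 for c in self.assignment.values() if c == NEGATIVE)

    @property
    def f1(self) -> float:
        """Fraction of the smaller class, min(N_pos, N_neg) / N."""
        n = self.n_pos + self.n_neg
        return min(self.n_pos, self.n_neg) / n

    def y(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """0/1 response vector (1 = positive) in the given sample order."""
        ids = self.sample_ids if sample_ids is None else sample_ids
        try:
            return np.array([1 if self.assignment[s] == POSITIVE else 0 for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} has no label") from exc

    def subset(self, sample_ids: Sequence[str]) -> "LabelSet":
        return LabelSet({s: self.assignment[s] for s in sample_ids})

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError("both classes must be non-empty for training operations")


@dataclass
class FeaturePanel:
    """An ordered list of selected features with per-stage scores.

    ``stage`` records which pipeline stage produced the panel (ecmr_prefilter,
    detection_filter, univariate, multivariate, ...), and ``provenance`` the
    thresholds it used, so the funnel from raw feature space down to the
    biomarker panel stays auditable.
    """

    feature_ids: list[str]
    scores: dict[str, float]
    stage: str = "unspecified"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.feature_ids:
            raise ValueError("empty feature panel")
        _check_unique(self.feature_ids, "panel feature")
        missing = [f for f in self.feature_ids if f not in self.scores]
        if missing:
            raise ValueError(f"panel features without a score: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __iter__(self):
        return iter(self.feature_ids)

    def head(self, k: int) -> "FeaturePanel":
        if k < 1 or k > len(self.feature_ids):
            raise ValueError(f"cannot take top {k} of a {len(self.feature_ids)}-feature panel")
        ids = self.feature_ids[:k]
        return FeaturePanel(ids, {f: self.scores[f] for f in ids},
                            stage=self.stage, provenance=dict(self.provenance))


@dataclass
class ProbabilitySet:
    """Per-sample probability of the positive class from one classifier."""

    classifier_id: str
    probabilities: dict[str, float]
    origin: str = "cv_heldout"  # cv_heldout | test | train_resub

    def __post_init__(self) -> None:
        for s, p in self.probabilities.items():
            if not (0.0 <= p <= 1.0) or math.isnan(p):
                raise ValueError(f"probability for sample {s!r} outside [0,1]: {p}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.probabilities)

    def array(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.sample_ids if sample_ids is None else sample_ids
        return np.array([self.probabilities[s] for s in ids], dtype=float)


@dataclass
class PerformanceSummary:
    """Threshold metrics at a probability cutoff plus rank-based AUC."""

    sensitivity: float
    specificity: float
    misclassification_error: float
    auc: float
    cutoff: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "misclassification_error", "auc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0,1]: {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "misclassification_error": self.misclassification_error,
            "auc": self.auc,
            "cutoff": self.cutoff,
        }


@dataclass
class EnsembleSpec:
    """Membership, weights and aggregation rule of one ensemble classifier."""

    ensemble_id: str
    members: list[str]
    method: str = "AP"  # AP (average probability) | VT (vote threshold)
    weights: list[float] | None = None
    vote_threshold: int = 1

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        _check_unique(self.members, "member classifier")
        if self.method not in ("AP", "VT"):
            raise ValueError(f"unknown aggregation method {self.method!r}")
        if self.weights is None:
            self.weights = [1.0 / len(self.members)] * len(self.members)
        if len(self.weights) != len(self.members):
            raise ValueError("one weight per member required")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")
        total = sum(self.weights)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        if self.method == "VT":
            if not (1 <= self.vote_threshold <= len(self.members)):
                raise ValueError(
                    f"vote threshold {self.vote_threshold} outside [1, {len(self.members)}]"
                )


@dataclass
class EnsembleReport:
    """Ensemble metrics next to the min/max/average of its members' metrics."""

    spec: EnsembleSpec
    ensemble: PerformanceSummary
    member_metrics: dict[str, PerformanceSummary]
    member_summary: dict[str, dict[str, float]]  # metric -> {min,max,average}
    origin: str = "cv_heldout"

    def __post_init__(self) -> None:
        for metric, stats in self.member_summary.items():
            if not stats["min"] <= stats["average"] + 1e-12 or not stats["average"] <= stats["max"] + 1e-12:
                raise ValueError(f"member summary for {metric} violates min <= average <= max")


# ---------------------------------------------------------------------------
# TSV / JSON readers and writers
# ---------------------------------------------------------------------------

def _parse_cell(token: str, where: str) -> float:
    if token.strip().lower() in _MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell {token!r} at {where}") from exc


def read_matrix(path: str | Path, platform: str = "generic",
                scale: Scale | str = Scale.LOG2_INTENSITY) -> OmicsMatrix:
    """Read a features x samples TSV (header = sample ids, first column =
    feature ids). Empty cells and "NA" (case-insensitive) are missing."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path.name}:{lineno}: ragged row ({len(parts)-1} cells, "
                    f"expected {len(sample_ids)})"
                )
            feature_ids.append(parts[0])
            rows.append([_parse_cell(tok, f"{path.name}:{lineno}") for tok in parts[1:]])
    if not feature_ids:
        raise ValueError(f"{path}: no feature rows")
    return OmicsMatrix(feature_ids, sample_ids, np.array(rows, dtype=float),
                       platform=platform, scale=Scale(scale))


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, fid in enumerate(matrix.feature_ids):
            cells = ["NA" if math.isnan(v) else repr(float(v)) for v in matrix.values[i]]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


def read_labels(path: str | Path, positive_class: str | None = None) -> LabelSet:
    """Read a two-column sample_id / class TSV.

    The positive class token is taken from a ``#positive=<token>`` header
    line if present, otherwise from the ``positive_class`` argument; one of
    the two must declare it.
    """
    path = Path(path)
    assignment: dict[str, str] = {}
    declared = positive_class
    tokens: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("positive="):
                    declared = body.split("=", 1)[1].strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}")
            sid, cls = parts[0].strip(), parts[1].strip()
            if sid.lower() == "sample_id":  # optional header row
                continue
            if sid in tokens:
                raise ValueError(f"{path.name}:{lineno}: duplicate sample id {sid!r}")
            tokens[sid] = cls
    if declared is None:
        raise ValueError(f"{path}: positive class not declared (use '#positive=<token>' header)")
    classes = sorted(set(tokens.values()))
    if declared not in classes and len(classes) == 2:
        raise ValueError(f"{path}: declared positive class {declared!r} not among {classes}")
    if len(classes) > 2:
        raise ValueError(f"{path}: more than two class tokens: {classes}")
    for sid, cls in tokens.items():
        assignment[sid] = POSITIVE if cls == declared else NEGATIVE
    return LabelSet(assignment)


def write_labels(labels: LabelSet, path: str | Path,
                 positive_token: str = "positive", negative_token: str = "negative") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#positive={positive_token}\n")
        fh.write("sample_id\tclass\n")
        for sid, cls in labels.assignment.items():
            fh.write(f"{sid}\t{positive_token if cls == POSITIVE else negative_token}\n")


def write_panel(panel: FeaturePanel, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#stage={panel.stage}\n")
        if panel.provenance:
            fh.write(f"#provenance={json.dumps(panel.provenance, sort_keys=True)}\n")
        fh.write("feature_id\tscore\n")
        for fid in panel.feature_ids:
            fh.write(f"{fid}\t{panel.scores[fid]!r}\n")


def read_panel(path: str | Path) -> FeaturePanel:
    path = Path(path)
    stage = "unspecified"
    provenance: dict = {}
    feature_ids: list[str] = []
    scores: dict[str, float] = {}
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("stage="):
                    stage = body.split("=", 1)[1]
                elif body.startswith("provenance="):
                    provenance = json.loads(body.split("=", 1)[1])
                continue
            fid, score = line.split("\t")
            if fid == "feature_id":
                continue
            feature_ids.append(fid)
            scores[fid] = float(score)
    return FeaturePanel(feature_ids, scores, stage=stage, provenance=provenance)


def write_probabilities(probs: ProbabilitySet, path: str | Path, cutoff: float = 0.5) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#classifier={probs.classifier_id}\n")
        fh.write(f"#origin={probs.origin}\n")
        fh.write("sample_id\tprobability\tpredicted_class\n")
        for sid, p in probs.probabilities.items():
            cls = POSITIVE if p >= cutoff else NEGATIVE
            fh.write(f"{sid}\t{p!r}\t{cls}\n")


def read_probabilities(path: str | Path) -> ProbabilitySet:
    path = Path(path)
    classifier_id = path.stem
    origin = "cv_heldout"
    probabilities: dict[str, float] = {}
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("classifier="):
                    classifier_id = body.split("=", 1)[1]
                elif body.startswith("origin="):
                    origin = body.split("=", 1)[1]
                continue
            parts = line.split("\t")
            if parts[0] == "sample_id":
                continue
            probabilities[parts[0]] = float(parts[1])
    return ProbabilitySet(classifier_id, probabilities, origin=origin)


def write_report(report: EnsembleReport, path: str | Path) -> None:
    """Write an ensemble report as JSON (unrounded values)."""
    path = Path(path)
    payload = {
        "ensemble_id": report.spec.ensemble_id,
        "method": report.spec.method,
        "members": report.spec.members,
        "weights": report.spec.weights,
        "vote_threshold": report.spec.vote_threshold,
        "origin": report.origin,
        "ensemble": report.ensemble.as_dict(),
        "member_metrics": {m: s.as_dict() for m, s in report.member_metrics.items()},
        "member_summary": report.member_summary,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
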