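"""k-nearest-neighbour imputation of missing expression values.

Neighbours are other *samples*: a missing value for feature f in sample s is
the average of f over the k samples nearest to s, with distance computed
over features observed in both samples (scaled by the number of co-observed
coordinates so sparsity does not inflate distances). Class labels are never
consulted. Test samples are imputed by pooling the already-imputed training
matrix with the test matrix and drawing neighbours from the pool, so the
training data is never modified by test-time imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import OmicsMatrix

__all__ = ["ImputeConfig", "knn_impute_train", "knn_impute_test"]


@dataclass
class ImputeConfig:
    """Imputation settings: k neighbours, sample-wise by default."""

    k: int = 3
    neighbor_space: str = "samples"  # samples | features

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.neighbor_space not in ("samples", "features"):
            raise ValueError(f"unknown neighbor space {self.neighbor_space!r}")


def _scaled_distances(target: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Distance from one column vector to each column of ``others``:
    sqrt(mean of squared differences over co-observed coordinates).
    Pairs with no co-observed coordinate get distance +inf."""
    diff = others - target[:, None]
    co = ~np.isnan(diff)
    n_co = co.sum(axis=0)
    sq = np.where(co, diff, 0.0) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(sq.sum(axis=0) / n_co)
    d[n_co == 0] = np.inf
    return d


def _impute_columns(values: np.ndarray, ids: list[str], fill_cols: np.ndarray,
                    k: int) -> np.ndarray:
    """Fill missing cells of the columns flagged in ``fill_cols`` using kNN
    over all columns of ``values``. Returns a copy; only flagged columns'
    missing cells change."""
    out = values.copy()
    n_feat, n_samp = values.shape
    order = np.argsort(np.array(ids, dtype=object))  # lexicographic tie-break
    for s in np.flatnonzero(fill_cols):
        missing_feats = np.flatnonzero(np.isnan(values[:, s]))
        if missing_feats.size == 0:
            continue
        d = _scaled_distances(values[:, s], values)
        d[s] = np.inf  # never one's own neighbour
        for f in missing_feats:
            eligible = np.flatnonzero(~np.isnan(values[f, :]) & np.isfinite(d))
            if eligible.size == 0:
                raise ValueError(
                    f"feature {f} has no eligible donor for sample {ids[s]!r}"
                )
            if eligible.size < k:
                warnings.warn(
                    f"only {eligible.size} eligible neighbours (< k={k}) for "
                    f"sample {ids[s]!r}; using all of them",
                    stacklevel=2,
                )
            # sort by (distance, lexicographic sample id) for determinism
            rank = {c: r for r, c in enumerate(order)}
            chosen = sorted(eligible, key=lambda c: (d[c], rank[c]))[:k]
            out[f, s] = float(np.mean(values[f, chosen]))
    return out


def knn_impute_train(matrix: OmicsMatrix, cfg: ImputeConfig | None = None) -> OmicsMatrix:
    """Impute all missing entries of a training matrix in place of the mask.

    Observed entries are returned unchanged. Every feature must be observed
    in at least one sample and every sample in at least one feature.
    """
    cfg = cfg or ImputeConfig()
    if matrix.is_complete:
        return matrix
    mask = matrix.missing_mask
    feat_missing = mask.all(axis=1)
    if feat_missing.any():
        bad = [matrix.feature_ids[i] for i in np.flatnonzero(feat_missing)[:5]]
        raise ValueError(f"feature(s) observed nowhere: {bad}")
    samp_missing = mask.all(axis=0)
    if samp_missing.any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(samp_missing)[:5]]
        raise ValueError(f"sample(s) with no observed feature: {bad}")

    values = matrix.values if cfg.neighbor_space == "samples" else matrix.values.T
    ids = matrix.sample_ids if cfg.neighbor_space == "samples" else matrix.feature_ids
    filled = _impute_columns(values, ids, np.ones(values.shape[1], dtype=bool), cfg.k)
    if cfg.neighbor_space == "features":
        filled = filled.T
    return OmicsMatrix(list(matrix.feature_ids), list(matrix.sample_ids), filled,
                       platform=matrix.platform, scale=matrix.scale)


def knn_impute_test(train_imputed: OmicsMatrix, test: OmicsMatrix,
                    cfg: ImputeConfig | None = None) -> OmicsMatrix:
    """Impute a test matrix against a completed training matrix.

    The test matrix is stacked next to the training matrix and only the test
    columns are filled, drawing neighbours from the combined pool. Training
    cells are never modified.
    """
    cfg = cfg or ImputeConfig()
    if train_imputed.feature_ids != test.feature_ids:
        raise ValueError("train and test matrices must share the same feature space")
    if not train_imputed.is_complete:
        raise ValueError("training matrix must be fully imputed first")
    if test.is_complete:
        return test
    combined = np.hstack([train_imputed.values, test.values])
    ids = list(train_imputed.sample_ids) + list(test.sample_ids)
    fill = np.zeros(combined.shape[1], dtype=bool)
    fill[train_imputed.n_samples:] = True
    filled = _impute_columns(combined, ids, fill, cfg.k)
    test_values = filled[:, train_imputed.n_samples:]
    return OmicsMatrix(list(test.feature_ids), list(test.sample_ids), test_values,
                       platform=test.platform, scale=test.scale)
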