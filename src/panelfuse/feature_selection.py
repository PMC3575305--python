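"""Feature pre-filtering, univariate ranking, and multivariate ranking.

The selection funnel runs in three stages. Pre-filters remove features that
carry little information regardless of class: the empirical central mass
range (ECMR) filter drops low-variation features, the detection filter drops
sparsely observed features, and the absolute-count filter drops features
rarely expressed above a threshold. Univariate ranking scores each surviving
feature with an empirical-Bayes moderated t-statistic, Benjamini-Hochberg
FDR and fold change, then applies cutoffs with panel-size constraints.
Multivariate ranking reorders a panel by model-based importance (e.g.
squared linear-SVM weights or random-forest importance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data_model import FeaturePanel, LabelSet, OmicsMatrix, Scale

__all__ = [
    "ecmr",
    "ecmr_prefilter",
    "detection_filter",
    "absolute_count_filter",
    "UnivariateStats",
    "SelectionConfig",
    "moderated_t",
    "bh_adjust",
    "fold_change",
    "univariate_select",
    "multivariate_rank",
    "svm_squared_weights",
    "random_forest_importance",
]


def _quantile(x: np.ndarray, p: float) -> float:
    # Linear interpolation of order statistics, h = (n-1)p + 1. This is the
    # common statistical-environment default and keeps the ECMR reproducible
    # bit-for-bit.
    return float(np.quantile(x, p, method="linear"))


def ecmr(x: Sequence[float], f1: float) -> float:
    """Empirical central mass range of a vector.

    ECMR(x) = quantile(x, 1 - f1/2) - quantile(x, f1/2), where ``f1`` is the
    fraction of the smaller class. For balanced classes (f1 = 0.5) the ECMR
    equals the inter-quartile range; for unbalanced classes the wider
    quantile range lets variation in the smaller class enter the measure.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("ecmr requires a 1-d vector with at least 2 values")
    if np.isnan(arr).any() or np.isinf(arr).any():
        raise ValueError("ecmr input must be finite with no missing values")
    if not (0.0 < f1 <= 0.5):
        raise ValueError(f"f1 must lie in (0, 0.5], got {f1}")
    return _quantile(arr, 1.0 - f1 / 2.0) - _quantile(arr, f1 / 2.0)


def _ecmr_rows(values: np.ndarray, f1: float) -> np.ndarray:
    hi = np.quantile(values, 1.0 - f1 / 2.0, axis=1, method="linear")
    lo = np.quantile(values, f1 / 2.0, axis=1, method="linear")
    return hi - lo


def ecmr_prefilter(matrix: OmicsMatrix, labels: LabelSet, q: float = 0.5) -> FeaturePanel:
    """Keep features whose ECMR lies strictly above the q-quantile of all
    feature ECMRs (q = 0.5 removes the lower half).

    The strictly-above rule makes the behaviour at the cut value exact: on n
    features with pairwise-distinct ECMRs it retains n/2 features for even n
    and ceil(n/2) - 1 for odd n.
    """
    if not matrix.is_complete:
        raise ValueError("ecmr_prefilter requires a complete matrix (impute first)")
    labels.require_both_classes()
    if not (0.0 < q < 1.0):
        raise ValueError(f"prefilter quantile must lie in (0,1), got {q}")
    f1 = labels.subset([s for s in matrix.sample_ids if s in labels.assignment]).f1
    scores = _ecmr_rows(matrix.values, f1)
    cut = _quantile(scores, q)
    keep = scores > cut
    if not keep.any():
        raise ValueError("ECMR prefilter retained no features")
    order = np.argsort(-scores[keep], kind="stable")
    kept_ids = [matrix.feature_ids[i] for i in np.flatnonzero(keep)]
    kept_scores = scores[keep]
    ids = [kept_ids[i] for i in order]
    return FeaturePanel(
        ids,
        {fid: float(kept_scores[i]) for fid, i in zip(ids, order)},
        stage="ecmr_prefilter",
        provenance={"q": q, "f1": f1, "cut": cut, "n_input": matrix.n_features},
    )


def detection_filter(matrix: OmicsMatrix, min_rate: float = 0.75) -> FeaturePanel:
    """Keep features observed (non-missing) in at least ``min_rate`` of samples."""
    observed = (~matrix.missing_mask).mean(axis=1)
    keep = observed >= min_rate
    if not keep.any():
        raise ValueError("detection filter retained no features")
    order = np.argsort(-observed[keep], kind="stable")
    kept_ids = [matrix.feature_ids[i] for i in np.flatnonzero(keep)]
    kept_scores = observed[keep]
    ids = [kept_ids[i] for i in order]
    return FeaturePanel(
        ids,
        {fid: float(kept_scores[i]) for fid, i in zip(ids, order)},
        stage="detection_filter",
        provenance={"min_rate": min_rate, "n_input": matrix.n_features},
    )


def absolute_count_filter(matrix: OmicsMatrix, expr_threshold: float, k: int) -> FeaturePanel:
    """Keep features expressed strictly above ``expr_threshold`` in at least
    ``k`` samples."""
    if not matrix.is_complete:
        raise ValueError("absolute_count_filter requires a complete matrix")
    if k > matrix.n_samples:
        raise ValueError(f"k = {k} exceeds the number of samples ({matrix.n_samples})")
    counts = (matrix.values > expr_threshold).sum(axis=1)
    keep = counts >= k
    if not keep.any():
        raise ValueError("absolute-count filter retained no features")
    order = np.argsort(-counts[keep], kind="stable")
    kept_ids = [matrix.feature_ids[i] for i in np.flatnonzero(keep)]
    kept_counts = counts[keep]
    ids = [kept_ids[i] for i in order]
    return FeaturePanel(
        ids,
        {fid: float(kept_counts[i]) for fid, i in zip(ids, order)},
        stage="absolute_count_filter",
        provenance={"expr_threshold": expr_threshold, "k": k, "n_input": matrix.n_features},
    )


# ---------------------------------------------------------------------------
# Univariate ranking: moderated t, BH-FDR, fold change
# ---------------------------------------------------------------------------

@dataclass
class UnivariateStats:
    """Per-feature moderated-t statistics plus the global variance prior."""

    feature_ids: list[str]
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    s2: np.ndarray          # pooled within-class variance
    df_residual: float      # n1 + n2 - 2, common to all features
    s2_tilde: np.ndarray    # posterior (moderated) variance
    t: np.ndarray           # moderated t-statistic
    p: np.ndarray           # two-sided p-value, df = d0 + d
    fdr: np.ndarray         # BH-adjusted p
    fold_change: np.ndarray
    d0: float               # prior degrees of freedom (may be inf)
    s0_2: float             # prior variance


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to the
    marginal distribution of the observed variances.

    Matching is done on log variances: with s^2 | sigma^2 ~ sigma^2 chi^2_d / d
    the residuals e_g = log s_g^2 - digamma(d/2) + log(d/2) have a known mean
    and variance under the prior, which identifies d0 through the trigamma
    function and s0^2 through the mean. When the observed variances are more
    homogeneous than sampling noise alone allows, d0 diverges and the
    posterior variance collapses to the common value s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all features have zero variance; cannot fit variance prior")
    # guard against exact zeros from constant features
    z = np.log(np.where(s2 > 0, s2, np.min(positive)))
    e = z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(arr, method="fdr_bh")[1]


def fold_change(matrix: OmicsMatrix, labels: LabelSet) -> np.ndarray:
    """Per-feature fold change between classes, always >= 1.

    On the log2 scale FC = 2^|mean_pos - mean_neg|; on the ratio scale FC is
    the larger of the two ratios of class means.
    """
    labels.require_both_classes()
    y = labels.y(matrix.sample_ids)
    mpos = matrix.values[:, y == 1].mean(axis=1)
    mneg = matrix.values[:, y == 0].mean(axis=1)
    if matrix.scale == Scale.LOG2_INTENSITY:
        # extreme mean differences legitimately saturate to inf
        with np.errstate(over="ignore"):
            return 2.0 ** np.abs(mpos - mneg)
    if (mpos <= 0).any() or (mneg <= 0).any():
        raise ValueError("ratio-scale class mean <= 0; fold change undefined")
    return np.maximum(mpos / mneg, mneg / mpos)


def moderated_t(matrix: OmicsMatrix, labels: LabelSet, d0: float | None = None,
                s0_2: float | None = None) -> UnivariateStats:
    """Two-sample moderated t-test with empirical-Bayes variance shrinkage.

    For each feature the pooled variance s_g^2 is shrunk toward a prior
    variance s0^2 with prior weight d0 residual degrees of freedom:

        s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d),
        t_g = (mean_pos - mean_neg) / (s~_g sqrt(1/n1 + 1/n2)),

    with two-sided p-values from a t-distribution on d0 + d degrees of
    freedom. (d0, s0^2) are estimated from the marginal distribution of the
    observed variances unless supplied; passing ``d0=0`` recovers the
    ordinary pooled-variance t-test.
    """
    labels.require_both_classes()
    if not matrix.is_complete:
        raise ValueError("moderated_t requires a complete matrix (impute first)")
    y = labels.y(matrix.sample_ids)
    n1 = int((y == 1).sum())
    n2 = int((y == 0).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs at least 2 samples")
    xpos = matrix.values[:, y == 1]
    xneg = matrix.values[:, y == 0]
    mpos = xpos.mean(axis=1)
    mneg = xneg.mean(axis=1)
    df = float(n1 + n2 - 2)
    ss = ((xpos - mpos[:, None]) ** 2).sum(axis=1) + ((xneg - mneg[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    if d0 is None:
        d0_hat, s0_hat = _fit_variance_prior(s2, df)
    else:
        d0_hat = float(d0)
        if d0_hat > 0 and s0_2 is None:
            raise ValueError("s0_2 must be given when d0 is fixed and positive")
        s0_hat = float(s0_2) if s0_2 is not None else float(np.median(s2))

    if np.isinf(d0_hat):
        s2_tilde = np.full_like(s2, s0_hat)
        df_total = np.inf
    elif d0_hat == 0:
        s2_tilde = s2.copy()
        df_total = df
    else:
        s2_tilde = (d0_hat * s0_hat + df * s2) / (d0_hat + df)
        df_total = d0_hat + df

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mpos - mneg) / se, 0.0)
        # zero-variance, zero-difference features get t = 0 (p = 1)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    fc = fold_change(matrix, labels)
    return UnivariateStats(
        feature_ids=list(matrix.feature_ids),
        mean_pos=mpos, mean_neg=mneg, s2=s2, df_residual=df,
        s2_tilde=s2_tilde, t=t, p=p, fdr=bh_adjust(p), fold_change=fc,
        d0=d0_hat, s0_2=s0_hat,
    )


@dataclass
class SelectionConfig:
    """Cutoffs and panel-size constraints for univariate selection."""

    fdr_cut: float = 0.05
    fc_cut: float = 1.0
    min_panel: int = 1
    max_panel: int | None = None
    top_k: int | None = None  # when set, rank-only mode ignoring cutoffs

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_cut <= 1.0):
            raise ValueError(f"fdr_cut must lie in (0,1], got {self.fdr_cut}")
        if self.fc_cut < 1.0:
            raise ValueError(f"fc_cut must be >= 1, got {self.fc_cut}")
        if self.max_panel is not None and self.min_panel > self.max_panel:
            raise ValueError("min_panel must not exceed max_panel")


def _univariate_order(stats_: UnivariateStats) -> list[int]:
    # (FDR asc, |t| desc, feature_id asc) -- deterministic tie-breaking
    return sorted(
        range(len(stats_.feature_ids)),
        key=lambda i: (stats_.fdr[i], -abs(stats_.t[i]), stats_.feature_ids[i]),
    )


def univariate_select(stats_: UnivariateStats, cfg: SelectionConfig) -> FeaturePanel:
    """Apply FDR and fold-change cutoffs with panel-size constraints.

    Candidates pass FDR < fdr_cut and FC >= fc_cut and are ordered by
    (FDR asc, |t| desc, id asc). If fewer than ``min_panel`` pass, the list
    is extended with the next-best features by the same ordering; if more
    than ``max_panel`` pass, it is truncated. ``top_k`` mode returns the k
    best-ranked features regardless of cutoffs.
    """
    order = _univariate_order(stats_)
    m = len(order)
    if cfg.top_k is not None:
        if cfg.top_k > m:
            raise ValueError(f"top_k = {cfg.top_k} exceeds available features ({m})")
        chosen = order[: cfg.top_k]
    else:
        if cfg.min_panel > m:
            raise ValueError(f"min_panel = {cfg.min_panel} exceeds available features ({m})")
        passing = [i for i in order
                   if stats_.fdr[i] < cfg.fdr_cut and stats_.fold_change[i] >= cfg.fc_cut]
        chosen = passing
        if len(chosen) < cfg.min_panel:
            extra = [i for i in order if i not in set(chosen)]
            chosen = chosen + extra[: cfg.min_panel - len(chosen)]
        if cfg.max_panel is not None and len(chosen) > cfg.max_panel:
            chosen = chosen[: cfg.max_panel]
    ids = [stats_.feature_ids[i] for i in chosen]
    return FeaturePanel(
        ids,
        {stats_.feature_ids[i]: float(stats_.fdr[i]) for i in chosen},
        stage="univariate",
        provenance={
            "fdr_cut": cfg.fdr_cut, "fc_cut": cfg.fc_cut,
            "min_panel": cfg.min_panel, "max_panel": cfg.max_panel,
            "top_k": cfg.top_k, "d0": stats_.d0, "s0_2": stats_.s0_2,
        },
    )


# ---------------------------------------------------------------------------
# Multivariate ranking
# ---------------------------------------------------------------------------

def svm_squared_weights(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared weights of a linear SVM fit on (samples x features) data."""
    from sklearn.svm import SVC

    clf = SVC(kernel="linear", C=1.0)
    clf.fit(values, y)
    return np.asarray(clf.coef_).ravel() ** 2


def random_forest_importance(values: np.ndarray, y: np.ndarray, seed: int = 0,
                             n_estimators: int = 500) -> np.ndarray:
    """Gini importance from a seeded random forest."""
    from sklearn.ensemble import RandomForestClassifier

    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(values, y)
    return clf.feature_importances_


ImportanceFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


def multivariate_rank(matrix: OmicsMatrix, labels: LabelSet, panel: FeaturePanel,
                      importance_fn: ImportanceFn, top_m: int) -> FeaturePanel:
    """Reorder a panel by model-based importance and keep the top ``top_m``.

    ``importance_fn`` maps (samples x features array, 0/1 response) to
    non-negative per-feature scores. Ties keep the prior univariate order.
    """
    if top_m > len(panel):
        raise ValueError(f"top_m = {top_m} exceeds panel size {len(panel)}")
    sub = matrix.subset_features(panel.feature_ids)
    y = labels.y(sub.sample_ids)
    scores = np.asarray(importance_fn(sub.values.T, y), dtype=float)
    if scores.shape != (len(panel),):
        raise ValueError("importance_fn must return one score per panel feature")
    order = sorted(range(len(panel)), key=lambda i: (-scores[i], i))  # ties: prior order
    chosen = order[:top_m]
    ids = [panel.feature_ids[i] for i in chosen]
    return FeaturePanel(
        ids,
        {panel.feature_ids[i]: float(scores[i]) for i in chosen},
        stage="multivariate",
        provenance={"top_m": top_m, "parent_stage": panel.stage},
    )
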