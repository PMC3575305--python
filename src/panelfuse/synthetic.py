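"""Seeded two-platform synthetic data with known class structure.

The generator emulates the statistical shape of a paired transcriptomic /
proteomic study of a binary condition: a large complete matrix of log2
intensities and a small ratio-scale matrix with missing-at-random entries.
A configurable subset of features in each platform carries a mean shift
between classes; the remaining features are exchangeable noise. A
``signal_overlap`` dial controls on how many positive samples the two
platforms' signals agree: at 1.0 both platforms express the class signal in
every positive sample, while lower values make each platform detect the
condition in only part of the positives (disjoint parts at 0.0), producing
the classifier diversity that late-fusion ensembles exploit.

Within-platform correlation is induced in equicorrelated feature blocks via
a shared per-sample factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import LabelSet, OmicsMatrix, Scale, write_labels, write_matrix

__all__ = ["PlatformConfig", "SyntheticConfig", "SyntheticDataset", "generate", "inject_missing"]


@dataclass
class PlatformConfig:
    """Shape and signal of one simulated platform."""

    name: str = "genomic"
    scale: Scale = Scale.LOG2_INTENSITY
    n_features: int = 2000
    n_informative: int = 50
    effect_size: float = 2.0   # class mean shift in within-class SD units
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    block_size: int = 1        # equicorrelated block width (1 = independent)
    block_rho: float = 0.0
    missing_rate: float = 0.0  # MCAR cell-masking probability

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if not (0.0 <= self.missing_rate <= 0.9):
            raise ValueError("missing_rate must lie in [0, 0.9]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must lie in [0, 1)")


@dataclass
class SyntheticConfig:
    """Study design: class sizes, two platforms, and the diversity dial."""

    n_pos: int = 11
    n_neg: int = 21
    genomic: PlatformConfig = field(default_factory=lambda: PlatformConfig(
        name="genomic", scale=Scale.LOG2_INTENSITY, n_features=2000,
        n_informative=50, effect_size=2.0, missing_rate=0.0))
    proteomic: PlatformConfig = field(default_factory=lambda: PlatformConfig(
        name="proteomic", scale=Scale.RATIO, n_features=150,
        n_informative=20, effect_size=2.0, baseline_mean=0.0,
        baseline_sd=0.5, missing_rate=0.15))
    signal_overlap: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one sample")
        if not (0.0 <= self.signal_overlap <= 1.0):
            raise ValueError("signal_overlap must lie in [0,1]")


@dataclass
class SyntheticDataset:
    """Generated matrices plus labels and the ground-truth informative features."""

    genomic: OmicsMatrix
    proteomic: OmicsMatrix
    labels: LabelSet
    informative: dict[str, list[str]]  # platform name -> true signal feature ids
    config: SyntheticConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(self.genomic, out / "genomic.tsv")
        write_matrix(self.proteomic, out / "proteomic.tsv")
        write_labels(self.labels, out / "labels.tsv")
        with (out / "truth.tsv").open("w") as fh:
            fh.write("platform\tfeature_id\n")
            for platform, feats in self.informative.items():
                for f in feats:
                    fh.write(f"{platform}\t{f}\n")


def _signal_carriers(rng: np.random.Generator, n_pos: int, overlap: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-positive-sample indicators of whether each platform expresses the
    class signal. A fraction ``overlap`` of positives express it on both
    platforms; the rest alternate between platform-exclusive expression."""
    both = rng.random(n_pos) < overlap
    a = both.copy()
    b = both.copy()
    exclusive = np.flatnonzero(~both)
    half = rng.permutation(exclusive)
    a[half[: len(half) // 2 + len(half) % 2]] = True
    b[half[len(half) // 2 + len(half) % 2:]] = True
    return a, b


def _platform_matrix(rng: np.random.Generator, cfg: PlatformConfig,
                     sample_ids: list[str], y: np.ndarray,
                     carries: np.ndarray) -> tuple[OmicsMatrix, list[str]]:
    n = len(sample_ids)
    p = cfg.n_features
    x = rng.normal(0.0, 1.0, size=(p, n))
    if cfg.block_rho > 0 and cfg.block_size > 1:
        # equicorrelation within blocks via a shared per-sample factor
        lam = np.sqrt(cfg.block_rho)
        for start in range(0, p, cfg.block_size):
            stop = min(start + cfg.block_size, p)
            factor = rng.normal(0.0, 1.0, size=n)
            x[start:stop] = lam * factor + np.sqrt(1 - cfg.block_rho) * x[start:stop]
    x = cfg.baseline_mean + cfg.baseline_sd * x
    informative_idx = np.arange(cfg.n_informative)
    shift_cols = (y == 1) & carries
    x[np.ix_(informative_idx, np.flatnonzero(shift_cols))] += cfg.effect_size * cfg.baseline_sd

    feature_ids = [f"{cfg.name}_f{i:05d}" for i in range(p)]
    if cfg.scale == Scale.RATIO:
        x = 2.0 ** x  # ratio scale: exponentiate the latent log values
    matrix = OmicsMatrix(feature_ids, sample_ids, x, platform=cfg.name, scale=cfg.scale)
    if cfg.missing_rate > 0:
        matrix = inject_missing(matrix, cfg.missing_rate,
                                seed=int(rng.integers(0, 2**31 - 1)))
    truth = [feature_ids[i] for i in informative_idx]
    return matrix, truth


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a reproducible two-platform dataset with known signal."""
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    sample_ids = [f"s{i:03d}" for i in range(n)]
    y = np.array([1] * config.n_pos + [0] * config.n_neg)
    labels = LabelSet({s: ("positive" if yi == 1 else "negative")
                       for s, yi in zip(sample_ids, y)})
    carry_g = np.zeros(n, dtype=bool)
    carry_p = np.zeros(n, dtype=bool)
    a, b = _signal_carriers(rng, config.n_pos, config.signal_overlap)
    carry_g[: config.n_pos] = a
    carry_p[: config.n_pos] = b
    genomic, truth_g = _platform_matrix(rng, config.genomic, sample_ids, y, carry_g)
    proteomic, truth_p = _platform_matrix(rng, config.proteomic, sample_ids, y, carry_p)
    return SyntheticDataset(
        genomic=genomic, proteomic=proteomic, labels=labels,
        informative={config.genomic.name: truth_g, config.proteomic.name: truth_p},
        config=config,
    )


def inject_missing(matrix: OmicsMatrix, rate: float, seed: int = 0) -> OmicsMatrix:
    """Mask cells independently with probability ``rate`` (MCAR), resampling
    any feature that would end up with no observed value."""
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"missing rate must lie in [0,1), got {rate}")
    if rate == 0.0:
        return matrix
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    n_feat, n_samp = values.shape
    mask = rng.random((n_feat, n_samp)) < rate
    for _ in range(100):
        empty = mask.all(axis=1)
        if not empty.any():
            break
        mask[empty] = rng.random((int(empty.sum()), n_samp)) < rate
    else:
        raise ValueError("missing rate too high: cannot keep every feature observed")
    values[mask] = np.nan
    return OmicsMatrix(list(matrix.feature_ids), list(matrix.sample_ids), values,
                       platform=matrix.platform, scale=matrix.scale)
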