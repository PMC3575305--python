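import numpy as np
import pytest

from panelfuse.data_model import LabelSet, OmicsMatrix, Scale
from panelfuse.synthetic import PlatformConfig, SyntheticConfig, generate


@pytest.fixture
def small_matrix() -> OmicsMatrix:
    """3 features x 4 samples, complete, log2 scale."""
    values = np.array([
        [8.0, 9.0, 7.5, 8.5],
        [5.0, 5.2, 4.9, 5.1],
        [10.0, 12.0, 9.5, 11.0],
    ])
    return OmicsMatrix(["f1", "f2", "f3"], ["s1", "s2", "s3", "s4"], values)


@pytest.fixture
def small_labels() -> LabelSet:
    return LabelSet({"s1": "positive", "s2": "positive",
                     "s3": "negative", "s4": "negative"})


@pytest.fixture(scope="session")
def signal_dataset():
    """Two-platform dataset with a clear class effect (seeded)."""
    cfg = SyntheticConfig(
        n_pos=11, n_neg=21, seed=11,
        genomic=PlatformConfig(name="genomic", n_features=300,
                               n_informative=40, effect_size=2.0),
        proteomic=PlatformConfig(name="proteomic", scale=Scale.RATIO,
                                 n_features=100, n_informative=20,
                                 effect_size=2.0, baseline_mean=0.0,
                                 baseline_sd=0.5, missing_rate=0.15),
    )
    return generate(cfg)


def make_two_class_matrix(seed: int = 0, n_features: int = 30, n_pos: int = 6,
                          n_neg: int = 8, shift: float = 1.5, n_shifted: int = 5):
    """Small complete matrix with a mean shift on the first features."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    sd = rng.uniform(0.5, 2.0, size=(n_features, 1))
    values = rng.normal(0.0, sd, size=(n_features, n))
    values[:n_shifted, :n_pos] += shift
    fids = [f"f{i:03d}" for i in range(n_features)]
    sids = [f"s{i:02d}" for i in range(n)]
    matrix = OmicsMatrix(fids, sids, values)
    labels = LabelSet({s: ("positive" if i < n_pos else "negative")
                       for i, s in enumerate(sids)})
    return matrix, labels
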