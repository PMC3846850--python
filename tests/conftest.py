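import numpy as np
import pytest

from mrmrsvm import ExpressionMatrix, LabeledDataset, SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 features x 4 samples, raw intensities, one missing cell."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [0.05, 0.2, 0.4, 0.8],
            [10.0, np.nan, 30.0, 40.0],
        ]
    )
    return ExpressionMatrix(
        feature_ids=["F1", "F2", "F3"],
        sample_ids=["S1", "S2", "S3", "S4"],
        values=values,
        annotated=np.array([True, True, False]),
        stage="raw",
    )


@pytest.fixture
def zscored_dataset(rng):
    """Small z-score-stage dataset: one strong feature, two noise features."""
    n = 60
    y = np.arange(n) % 2 == 0
    strong = np.where(y, 1.0, -1.0) + rng.normal(0, 0.4, n)
    noise1 = rng.normal(size=n)
    noise2 = rng.normal(size=n)
    X = np.vstack([strong, noise1, noise2])
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    m = ExpressionMatrix(
        feature_ids=["STRONG", "N1", "N2"],
        sample_ids=[f"s{i}" for i in range(n)],
        values=X,
        stage="zscore",
    )
    return LabeledDataset(matrix=m, y=y)


@pytest.fixture
def tiny_cohort():
    """Small synthetic cohort (fast): 2 informative among ~60 features."""
    cfg = SyntheticConfig(
        n_samples=80,
        n_informative=2,
        n_redundant_per_informative=1,
        n_noise=55,
        effect_size=2.5,
        presence_rate=1.0,
        seed=7,
    )
    return generate_cohort(cfg)
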