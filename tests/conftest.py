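import numpy as np
import pytest

from refined import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """A 6x4 feature table with known values."""
    values = np.array(
        [
            [0.1, 0.9, 0.2, 0.5],
            [0.2, 0.8, 0.3, 0.4],
            [0.3, 0.7, 0.1, 0.6],
            [0.4, 0.6, 0.9, 0.2],
            [0.5, 0.5, 0.8, 0.3],
            [0.6, 0.4, 0.7, 0.1],
        ]
    )
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(6)],
        feature_names=["fa", "fb", "fc", "fd"],
        values=values,
    )


@pytest.fixture
def random_table(rng):
    """A 30x16 random feature table in [0, 1]."""
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(30)],
        feature_names=[f"f{j:02d}" for j in range(16)],
        values=rng.uniform(size=(30, 16)),
    )
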