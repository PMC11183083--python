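import numpy as np
import pytest

from batcheval import BatchLabels, FeatureMatrix, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


@pytest.fixture
def toy_matrix():
    """4x3 positive matrix whose vegdist distances are frozen as oracles."""
    values = np.array(
        [
            [0.5, 1.2, 2.0],
            [1.5, 0.3, 0.7],
            [2.2, 1.1, 0.4],
            [0.9, 2.5, 1.8],
        ]
    )
    return FeatureMatrix(values, ["s1", "s2", "s3", "s4"], ["f1", "f2", "f3"])


@pytest.fixture
def two_group_labels():
    return BatchLabels(["a", "a", "b", "b"])


def make_dataset(n=100, add_batch=True, seed=0, **kwargs):
    cfg = SimConfig(n_samples=n, add_batch=add_batch, seed=seed, **kwargs)
    return simulate_dataset(cfg)


@pytest.fixture
def batch_dataset():
    return make_dataset(n=100, add_batch=True, seed=11)


@pytest.fixture
def null_dataset():
    return make_dataset(n=100, add_batch=False, seed=12)
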