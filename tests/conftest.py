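import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_blobs(n_per_class=10, n_features=12, separation=10.0, seed=0):
    """Two spherical Gaussian blobs separated along the first axis.

    With separation 10 sigma the classes are linearly separable for any
    reasonable n, a sanity floor for every classifier test.
    """
    g = np.random.default_rng(seed)
    shift = np.zeros(n_features)
    shift[0] = separation
    X_pos = g.normal(size=(n_per_class, n_features)) + shift
    X_neg = g.normal(size=(n_per_class, n_features))
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(n_per_class), -np.ones(n_per_class)])
    return X, y


@pytest.fixture
def separable_toy():
    return make_blobs()
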