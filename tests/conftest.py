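import numpy as np
import pytest

from tmixnet.data import ExpressionMatrix, standardize
from tmixnet.simulate import generate_setup, sample_mvt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def blobs():
    """Two well-separated Gaussian-ish blobs, 40 x 6, standardized."""
    r = np.random.default_rng(7)
    a = r.normal(0.0, 1.0, size=(20, 6))
    b = r.normal(0.0, 1.0, size=(20, 6))
    b[:, :3] += 4.0
    X = standardize(ExpressionMatrix(np.vstack([a, b])))
    labels = np.repeat([0, 1], 20)
    return X, labels


@pytest.fixture(scope="session")
def setup1_small():
    """One set-up-1 draw (nu=20), reused across tests."""
    return generate_setup(1, nu=20.0, seed=11)


@pytest.fixture(scope="session")
def random_pd():
    def make(p, seed=0, strength=1.0):
        r = np.random.default_rng(seed)
        A = r.standard_normal((p, 2 * p))
        S = A @ A.T / (2 * p)
        return S + strength * np.eye(p)
    return make


@pytest.fixture(scope="session")
def t_blob():
    """Heavy-tailed single cluster for moment tests."""
    return sample_mvt(2000, np.zeros(4), np.eye(4), 6.0, seed=3)
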