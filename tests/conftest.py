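import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_logistic_instance(rng, n=30, p=4, sparse=True):
    """Small random binomial instance with a planted signal."""
    X = rng.normal(size=(n, p))
    beta = rng.normal(scale=1.0, size=p)
    if sparse and p > 2:
        beta[2:] = 0.0
    eta = X @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    # guard against degenerate draws
    if y.sum() < 2 or y.sum() > n - 2:
        y[:2] = [0.0, 1.0]
        y[-2:] = [1.0, 0.0]
    return X, y


@pytest.fixture
def support_recovery_fixture():
    """N=300, J=10 super-learner design: columns 0-1 are noisy copies of the
    true success probability, the rest are pure noise on a comparable scale."""
    rng = np.random.default_rng(7)
    n, J = 300, 10
    eta = rng.normal(size=n)
    prob = 1.0 / (1.0 + np.exp(-eta))
    Z = 0.5 + 0.2 * rng.normal(scale=0.5, size=(n, J))
    Z[:, 0] = prob + rng.normal(scale=0.05, size=n)
    Z[:, 1] = prob + rng.normal(scale=0.05, size=n)
    y = (rng.random(n) < prob).astype(float)
    return Z, y
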