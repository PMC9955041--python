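import numpy as np
import pytest

from isingmpf.core import IsingParameters, n_pairs


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_params(rng, n, sigma=0.5):
    return IsingParameters(
        couplings=rng.normal(0, sigma, n_pairs(n)),
        fields=rng.normal(0, sigma, n),
    )


def random_configs(rng, m, n):
    return (2 * rng.integers(0, 2, (m, n)) - 1).astype(float)


def fd_gradient(f, theta, eps=1e-5):
    """Central finite differences of a scalar function of theta."""
    g = np.zeros_like(theta)
    for k in range(len(theta)):
        tp = theta.copy()
        tp[k] += eps
        tm = theta.copy()
        tm[k] -= eps
        g[k] = (f(tp) - f(tm)) / (2 * eps)
    return g
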