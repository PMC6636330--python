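import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cost(rng, n):
    """Random symmetric zero-diagonal cost with max entry 1."""
    C = rng.random((n, n))
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 0.0)
    return C / C.max()


def random_balanced_pair(rng, n):
    """Two strictly positive measures with equal unit mass."""
    a = rng.random(n) + 0.05
    b = rng.random(n) + 0.05
    return a / a.sum(), b / b.sum()
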