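import numpy as np
import pytest

from scedan import make_series


@pytest.fixture
def slc_fixture():
    """Baseline trend 2, slope change −2, level change 4 — hand-checked."""
    return make_series([0, 2, 4], [10, 10, 10], aim="decrease")


@pytest.fixture
def flat_series():
    """Identical flat phases: the global no-change fixture."""
    return make_series([5.0] * 5, [5.0] * 5, aim="decrease")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_series(rng, min_len=2, max_len=12, ties=False, aim="decrease"):
    """A random small AB series; with ``ties`` scores are drawn from a
    small integer grid so exact equalities occur."""
    n_pre = int(rng.integers(min_len, max_len + 1))
    n_post = int(rng.integers(min_len, max_len + 1))
    if ties:
        y = rng.integers(0, 6, size=n_pre + n_post).astype(float)
    else:
        y = rng.normal(0, 1, size=n_pre + n_post)
    return make_series(y[:n_pre], y[n_pre:], aim=aim)
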