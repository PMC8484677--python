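import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_timeseries(rng):
    """A small generic T x K matrix with no special structure."""
    return rng.standard_normal((20, 4))


@pytest.fixture
def random_symmetric():
    def make(K, seed=0):
        r = np.random.default_rng(seed)
        A = r.standard_normal((K, K))
        return 0.5 * (A + A.T)

    return make
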