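import numpy as np
import pytest

from xlintegrate.synthetic_data import gen_chain, gen_ensemble


@pytest.fixture(scope="session")
def small_chain():
    """60-bead self-avoiding chain shared across structure tests."""
    return gen_chain(60, seed=12345)


@pytest.fixture(scope="session")
def small_ensemble(small_chain):
    """20-model jittered ensemble over the shared chain."""
    return gen_ensemble(small_chain, n_models=20, jitter=1.5, seed=54321)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
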