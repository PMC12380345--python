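import numpy as np
import pytest

from graip import make_uncertain_er, sample_statistics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def er_target():
    """Uncertain ER graph: 50 nodes, backbone mean degree 4, uniform
    (0,1] probabilities — the small workhorse target."""
    return make_uncertain_er(50, 4, rng_seed=7)


@pytest.fixture(scope="session")
def er_stats(er_target):
    """Envelope of the workhorse target (S=500 worlds, order <= 4)."""
    return sample_statistics(er_target, 500, 4, np.random.default_rng(99))
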