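import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, p, cond_scale=1.0):
    """A well-conditioned random SPD matrix of size p."""
    a = rng.standard_normal((p, p))
    return a @ a.T + cond_scale * p * np.eye(p)


@pytest.fixture
def spd_factory(rng):
    return lambda p=10: random_spd(rng, p)
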