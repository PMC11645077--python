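import numpy as np
import pytest

from statescape import MEMParameters


def random_params(n_rois: int, rng, h_scale: float = 0.5, j_scale: float = 0.4) -> MEMParameters:
    """A random MEM parameter set with symmetric zero-diagonal couplings."""
    h = rng.normal(0, h_scale, n_rois)
    upper = np.triu(rng.normal(0, j_scale, (n_rois, n_rois)), 1)
    return MEMParameters(h=h, J=upper + upper.T)


@pytest.fixture
def rng():
    return np.random.default_rng(20240742)


@pytest.fixture
def params3(rng):
    return random_params(3, rng)
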