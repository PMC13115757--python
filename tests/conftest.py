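import numpy as np
import pytest
from hypothesis import settings

from dclkit import synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def noiseless_titration():
    """Exact 1:1 titration (K=200, r_free=0.005, r_inf=0.047, 12 points)."""
    t, truth = synth.make_titration(K=200.0, sigma_r=0.0, n_points=12,
                                    host_max=14e-3)
    return t, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
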