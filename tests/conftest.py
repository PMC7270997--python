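import numpy as np
import pytest

from nexdist import Weibull, new_weibull


@pytest.fixture
def exp_theta1():
    """NE-W reduced case theta=1 with unit-exponential parent: G = F^2."""
    return new_weibull(1.0, 1.0, 1.0)


@pytest.fixture
def theta2_model():
    return new_weibull(2.0, 1.0, 1.0)


@pytest.fixture
def unit_weibull():
    return Weibull(1.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
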