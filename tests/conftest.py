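import numpy as np
import pytest

from smclab import AgentParams, World


@pytest.fixture
def narrow_world():
    """Single narrow shape (w=1, h=1) centered at the origin of a 40-ring."""
    return World.single(width=1.0, height=1.0, L=40.0, center=0.0)


@pytest.fixture
def wide_world():
    return World.single(width=3.0, height=1.0, L=40.0, center=0.0)


@pytest.fixture
def bistable_params():
    """Hand-picked bistable controller: w11=6, theta1=-3 puts the folds
    symmetrically about zero input, with opposite-sign attractor velocities."""
    return AgentParams(w11=6.0, w21=4.0, theta1=-3.0, theta2=-2.0,
                       tau1=1.0, tau2=1.0, g_s=10.0)


@pytest.fixture
def monostable_params():
    return AgentParams(w11=3.0, w21=2.0, theta1=0.0, theta2=0.0,
                       tau1=1.0, tau2=1.0, g_s=5.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
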