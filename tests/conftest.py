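import numpy as np
import pytest

from lungesim.fencer_sim import FencerBehavior
from lungesim.geometry import FencerProfile


@pytest.fixture
def profile() -> FencerProfile:
    return FencerProfile(id="F01", height=1.78, mass=75.0, handedness="right")


@pytest.fixture
def left_profile() -> FencerProfile:
    return FencerProfile(id="F02", height=1.70, mass=68.0, handedness="left")


@pytest.fixture
def behavior() -> FencerBehavior:
    return FencerBehavior()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
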