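import numpy as np
import pytest

from taxisim import ControllerFilter, DesignedPathway, SimulationConfig


@pytest.fixture
def positive_pathway():
    return DesignedPathway(variant="positive")


@pytest.fixture
def pseudo_pathway():
    return DesignedPathway(variant="pseudo")


@pytest.fixture
def bandpass_filter():
    return ControllerFilter(kind="band_pass", A=16.0, omega1=0.02, omega2=5.0)


@pytest.fixture
def lowpass_filter():
    return ControllerFilter(kind="low_pass", A=64.0, omega0=5.0)


@pytest.fixture
def small_sim():
    """A quick 100 s / 50-agent configuration for structural checks."""
    return SimulationConfig(controller=ControllerFilter(A=16.0),
                            n_bacteria=50, duration=100.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
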