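import numpy as np
import pytest

from calrecruit import CalciumTransientModel, SimulationConfig, Trace


@pytest.fixture
def transient():
    return CalciumTransientModel()  # 1% dF/F amplitude, 3 s decay


@pytest.fixture
def small_config():
    """A small culture at the study conditions (cheap enough for unit tests)."""
    return SimulationConfig(n_neurons=10, duration_s=120.0, seed=7)


def make_normalized(values, frame_rate_hz=20.0, roi_id=0):
    return Trace(np.asarray(values, dtype=float), frame_rate_hz, "normalized", roi_id)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
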