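import numpy as np
import pytest

from cardiokin.synthgen import BeatWaveformParams, ConditionParams
from cardiokin.tracking import place_marker_grid
from cardiokin.trajectories import TimeBase


@pytest.fixture
def clean_pulse_params():
    """Noise-free, jitter-free 1 Hz beat with the closed-form example shape."""
    return BeatWaveformParams(A0=10.0, f_beat=1.0, tau_c=0.2, tau_r=0.3,
                              jitter_cv=0.0, noise_sigma=0.0)


@pytest.fixture
def ctrl_condition():
    return ConditionParams("CTRL", between_cv=0.0)


@pytest.fixture
def grid_640x480():
    return place_marker_grid(640, 480, rows=5, cols=6, margin=60)


@pytest.fixture
def tb_100hz():
    return TimeBase(100.0, 2000)


@pytest.fixture
def tb_25hz():
    return TimeBase(25.0, 500)


@pytest.fixture
def frame_center():
    return (319.5, 239.5)


def farthest_marker(grid, center):
    d = np.hypot(grid.positions[:, 0] - center[0],
                 grid.positions[:, 1] - center[1])
    return int(np.argmax(d))
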