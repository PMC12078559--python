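import numpy as np
import pytest

from azoswim.model import ModelParams, Phase, SwitchingSchedule
from azoswim.msd import Trajectory


@pytest.fixture
def params():
    """Shipped default model parameters."""
    return ModelParams()


@pytest.fixture
def short_schedule():
    return SwitchingSchedule(interval_length=2.0, n_intervals=4,
                             start_phase=Phase.UV_TO_VIS)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_trajectory(positions, frame_interval=0.2, track_id="t0"):
    positions = np.asarray(positions, dtype=float)
    times = np.arange(len(positions)) * frame_interval
    return Trajectory(track_id=track_id, times=times, positions=positions,
                      frame_interval=frame_interval)


@pytest.fixture
def drift_trajectory():
    """Pure drift x = 2t um/s along x, 100 frames at 1 s."""
    t = np.arange(100, dtype=float)
    pos = np.stack([2.0 * t, np.zeros_like(t)], axis=1)
    return Trajectory(track_id="drift", times=t, positions=pos,
                      frame_interval=1.0)
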