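import numpy as np
import pytest

from flyaim import ArenaCalibration, Trajectory


@pytest.fixture
def calibration():
    return ArenaCalibration(pixels_per_mm=1.0, frame_rate=30.06)


@pytest.fixture
def make_trajectory(calibration):
    """Factory for random-walk trajectories with seeded noise."""

    def _make(n_frames=200, seed=0, step_mm=0.3, cal=None):
        rng = np.random.default_rng(seed)
        heading = np.cumsum(rng.normal(0, 20, n_frames))
        steps = rng.exponential(step_mm, n_frames - 1)
        dx = steps * np.cos(np.radians(heading[:-1]))
        dy = steps * np.sin(np.radians(heading[:-1]))
        return Trajectory(
            frame_index=np.arange(n_frames),
            x_mm=np.concatenate([[0.0], np.cumsum(dx)]),
            y_mm=np.concatenate([[0.0], np.cumsum(dy)]),
            orientation_deg=heading,
            calibration=cal or calibration,
        )

    return _make
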