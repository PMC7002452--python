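import numpy as np
import pytest

from phimage import SensorGeometry
from phimage import synth


@pytest.fixture
def small_geometry():
    """A reduced pixel grid that keeps the movie sizes test-friendly."""
    return SensorGeometry(n_rows=16, n_cols=8, pixel_pitch_um=23.55, frame_rate_hz=25.0)


@pytest.fixture
def tiny_protocol():
    """2 angles x 2 trials, short phases: 4 trials, 28 s total."""
    return synth.generate_protocol(
        pre_phase_s=4.0,
        stim_s=2.0,
        interval_s=4.0,
        n_trials_per_angle=2,
        angles_deg=(0.0, 90.0),
        seed=7,
    )


@pytest.fixture
def single_pixel_truth(small_geometry):
    """One responsive (alkaline) pixel at (3, 2) for angle 0, noise-free."""
    field = np.zeros(small_geometry.shape + (2,))
    field[3, 2, 0] = 0.02
    return synth.make_ground_truth(
        small_geometry, response_field=field, angles_deg=(0.0, 90.0)
    )
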