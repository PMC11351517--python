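import numpy as np
import pytest

from mgst.paradigm import ScreenGeometry, ParadigmSpec, build_trial_schedule, degree_to_pixel
from mgst.preprocess import GazeRecording
from mgst.synthgaze import SubjectProfile


@pytest.fixture(scope="session")
def geom():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def spec():
    return ParadigmSpec()


@pytest.fixture(scope="session")
def schedule(spec):
    return build_trial_schedule(spec, seed=7)


@pytest.fixture(scope="session")
def quiet_profile():
    """Noise-free, blink-free, all-correct profile for exact recovery."""
    return SubjectProfile(
        fixation_noise_sd=0.0, blink_rate_per_trial=0.0, interocular_offset_deg=0.0,
        early_error_prob=0.0, late_error_prob=0.0, omission_prob=0.0,
        mgs_gain_sd=0.0,
    )


def recording_from_degrees(x_deg, y_deg=None, valid=None, geom=None, schedule=None,
                           dt_ms=4.0):
    """Build a binocular recording whose cyclopean trace equals the given
    degree-space trajectory (both eyes identical)."""
    geom = geom or ScreenGeometry()
    x_deg = np.asarray(x_deg, dtype=float)
    n = len(x_deg)
    y_deg = np.zeros(n) if y_deg is None else np.asarray(y_deg, dtype=float)
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    cx, cy = geom.center_px
    x_px = cx + degree_to_pixel(x_deg, geom)
    y_px = cy + degree_to_pixel(y_deg, geom)
    if schedule is None:
        schedule = build_trial_schedule(ParadigmSpec(), seed=0)
    return GazeRecording(
        t_us=np.arange(n, dtype=np.int64) * int(dt_ms * 1000),
        left_x_px=x_px.copy(), left_y_px=y_px.copy(),
        right_x_px=x_px.copy(), right_y_px=y_px.copy(),
        left_valid=valid.copy(), right_valid=valid.copy(),
        geometry=geom, schedule=schedule,
    )
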