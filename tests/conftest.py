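import logging

import numpy as np
import pytest

from gaitagree.synthetic import (
    CameraModel,
    CohortConfig,
    ErrorModel,
    mean_subject,
)

# the anthropometry sampler logs a warning for every rejected height draw;
# that is expected behaviour, not test noise
logging.getLogger("gaitagree.synthetic").setLevel(logging.ERROR)


@pytest.fixture
def subject():
    return mean_subject()


@pytest.fixture
def ortho_cam():
    return CameraModel(projection_mode="orthographic")


@pytest.fixture
def default_cam():
    return CameraModel()


@pytest.fixture
def noise_free_err():
    """Zero measurement error but real between-subject variation."""
    return ErrorModel(sd_session_m=0.0, sd_observer_frame=0.0, sd_digitize_px=0.0,
                      system_bias_deg=0.0, sd_residual_deg=0.0, sd_reference_deg=0.0,
                      sd_force_n=0.0)


@pytest.fixture
def small_config():
    return CohortConfig(n_subjects=8, rng_seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
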