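import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import toadhop as th

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_rig():
    return th.default_rig(pixel_noise_sd=0.0)


@pytest.fixture(scope="session")
def calibrated(noiseless_rig):
    """Noiseless rig plus cameras resected from 12 clean board views."""
    views = th.generate_checkerboard_views(noiseless_rig, 12, seed=101)
    left, right, reports = th.calibrate_rig(views)
    return noiseless_rig, left, right, views, reports


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
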