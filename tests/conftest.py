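import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import jointkin as jk
from jointkin.protocols import calibration_motion, measurement_motion, standard_rig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rig():
    return standard_rig()


@pytest.fixture(scope="session")
def cal_ds(rig):
    """Noise-free rich-motion (wobble + flexion) calibration dataset."""
    return jk.simulate_hinge(rig, calibration_motion())


@pytest.fixture(scope="session")
def meas_ds(rig):
    """Noise-free stationary-base 0-60 degree flexion measurement dataset."""
    return jk.simulate_hinge(rig, measurement_motion())


def axis_error_deg(j_est, j_truth):
    """Angle between axes, sign-agnostic (the constraint is even in j)."""
    return float(np.degrees(np.arccos(min(1.0, abs(float(np.dot(j_est, j_truth)))))))


def aligned_rmse_deg(est, truth):
    """RMSE after resolving the estimator's arbitrary flexion-sign convention."""
    est = np.asarray(est, float)
    truth = np.asarray(truth, float)
    r1 = np.sqrt(np.mean((est - truth) ** 2))
    r2 = np.sqrt(np.mean((-est - truth) ** 2))
    return float(np.degrees(min(r1, r2)))
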