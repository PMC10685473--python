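import numpy as np
import pytest

from footkin.kinematics import joint_angle_pipeline
from footkin.synthetic import generate_trial, healthy_default_spec
from footkin.trial_io import TrialConfig


@pytest.fixture(scope="session")
def healthy_trial():
    """Noise-free healthy walking trial: (spec, markers, force plate, truth)."""
    spec = healthy_default_spec(seed=7)
    traj, fp, gt = generate_trial(spec)
    return spec, traj, fp, gt


@pytest.fixture(scope="session")
def healthy_result(healthy_trial):
    """The kinematic pipeline run on the noise-free healthy trial, unfiltered."""
    spec, traj, fp, gt = healthy_trial
    config = TrialConfig(body_mass=spec.body_mass, side=spec.side, filter_cutoff=None)
    return joint_angle_pipeline(traj, fp, config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniformly random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
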