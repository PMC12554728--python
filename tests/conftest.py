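"""Shared fixtures: one synthetic subject with noise-free and noisy trials,
and calibrated models for all four protocols.  Session-scoped, since trial
generation and model calibration are reused by many tests."""

import numpy as np
import pytest

import kneests as ks
from kneests.pose import SegmentPoseSeries

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def subject():
    return ks.generate_subject(rng_seed=1)


@pytest.fixture(scope="session")
def static_trial(subject):
    return ks.generate_static_trial(subject, artifact=ks.NOISE_FREE)


@pytest.fixture(scope="session")
def clean_trial(subject):
    """Noise-free STS repetition with ground truth."""
    return ks.generate_sts_trial(subject, artifact=ks.NOISE_FREE)


@pytest.fixture(scope="session")
def noisy_trial(subject):
    return ks.generate_sts_trial(subject,
                                 artifact=ks.ArtifactConfig(rng_seed=3))


@pytest.fixture(scope="session")
def models(subject, static_trial):
    out = {}
    for protocol in ks.PROTOCOLS:
        marker_set, joint = protocol.split("_")
        out[protocol] = ks.build_subject_model(
            static_trial, marker_set, "ik" if joint == "IK" else "6dof",
            body_mass=subject.body_mass, stature=subject.stature)
    return out


@pytest.fixture(scope="session")
def poses_6dof_clean(clean_trial, models):
    trial, _ = clean_trial
    return ks.solve_6dof_trajectory(trial, models["IOR_6DoF"])


@pytest.fixture(scope="session")
def poses_ik_clean(clean_trial, models):
    trial, _ = clean_trial
    return ks.solve_ik_trajectory(trial, models["IOR_IK"])


@pytest.fixture(scope="session")
def true_pose_series(clean_trial):
    """Generator ground-truth poses wrapped as a SegmentPoseSeries."""
    trial, truth = clean_trial
    names = list(truth.segment_poses)
    n = trial.n_frames
    return SegmentPoseSeries(
        rotations={k: truth.segment_poses[k][0] for k in names},
        origins={k: truth.segment_poses[k][1] for k in names},
        residuals={k: np.zeros(n) for k in names},
        valid={k: np.ones(n, dtype=bool) for k in names},
        rate=trial.marker_rate)
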