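"""Tracking solvers and joint angles against generator ground truth."""

import numpy as np
import pytest

import kneests as ks
from kneests.errors import InvalidParameterError


def _kfa_rms_error(poses, truth, model, side="right"):
    angles = ks.joint_angle_series(poses, "knee", side, model).angles
    err = angles - truth.joint_angle_curves[("knee", side)]
    return np.sqrt(np.nanmean(err**2, axis=0))


class TestSixDof:
    def test_noise_free_matches_truth(self, clean_trial, poses_6dof_clean,
                                      models):
        _, truth = clean_trial
        for side in ("right", "left"):
            rms = _kfa_rms_error(poses_6dof_clean, truth,
                                 models["IOR_6DoF"], side)
            assert rms.max() < 0.1

    def test_global_translation_invariance(self, clean_trial, models):
        import dataclasses
        trial, _ = clean_trial
        shifted = dataclasses.replace(
            trial,
            marker_positions=trial.marker_positions + np.array([500.0,
                                                                -200.0,
                                                                50.0]))
        a = ks.solve_6dof_trajectory(trial, models["CAST_6DoF"])
        b = ks.solve_6dof_trajectory(shifted, models["CAST_6DoF"])
        ka = ks.joint_angle_series(a, "knee", "right",
                                   models["CAST_6DoF"]).angles
        kb = ks.joint_angle_series(b, "knee", "right",
                                   models["CAST_6DoF"]).angles
        np.testing.assert_allclose(ka, kb, atol=1e-9)

    def test_wrong_joint_model_rejected(self, clean_trial, models):
        trial, _ = clean_trial
        with pytest.raises(InvalidParameterError):
            ks.solve_6dof_trajectory(trial, models["IOR_IK"])

    def test_tibial_drawer_detected_as_knee_translation(self, subject,
                                                        static_trial):
        cfg = ks.SyntheticProtocolConfig(tibial_drawer_mm=8.0)
        trial, _ = ks.generate_sts_trial(subject, cfg, ks.NOISE_FREE)
        model = ks.build_subject_model(static_trial, "CAST", "6dof",
                                       body_mass=subject.body_mass)
        poses = ks.solve_6dof_trajectory(trial, model)
        trans = ks.knee_translation(poses, model, "right")
        assert np.abs(trans[:, 1]).mean() == pytest.approx(8.0, rel=0.02)


class TestChainIk:
    def test_noise_free_matches_6dof_and_truth(self, clean_trial,
                                               poses_6dof_clean,
                                               poses_ik_clean, models):
        _, truth = clean_trial
        assert _kfa_rms_error(poses_ik_clean, truth,
                              models["IOR_IK"]).max() < 0.05
        a = ks.joint_angle_series(poses_ik_clean, "knee", "right",
                                  models["IOR_IK"]).angles
        b = ks.joint_angle_series(poses_6dof_clean, "knee", "right",
                                  models["IOR_6DoF"]).angles
        assert np.sqrt(np.nanmean((a - b) ** 2)) < 0.05

    def test_knee_translation_identically_zero(self, poses_ik_clean, models):
        trans = ks.knee_translation(poses_ik_clean, models["IOR_IK"], "right")
        assert np.abs(trans).max() < 1e-9

    def test_residual_near_zero_noise_free(self, poses_ik_clean):
        assert np.nanmax(poses_ik_clean.residuals["pelvis"]) < 1e-6

    def test_rigid_cluster_offset_ik_vs_6dof(self, subject, static_trial,
                                             models):
        """A pure lateral offset of the thigh cluster moves the 6DoF knee
        translation but cannot move the IK knee centre."""
        import dataclasses
        trial, _ = ks.generate_sts_trial(subject, artifact=ks.NOISE_FREE)
        pos = trial.marker_positions.copy()
        for lab in ("RTH1", "RTH2", "RTH3", "RTH4"):
            pos[:, trial.index(lab), 1] -= 10.0  # 10 mm lateral (right)
        shifted = dataclasses.replace(trial, marker_positions=pos)
        p6 = ks.solve_6dof_trajectory(shifted, models["CAST_6DoF"])
        pik = ks.solve_ik_trajectory(shifted, models["CAST_IK"])
        t6 = ks.knee_translation(p6, models["CAST_6DoF"], "right")
        tik = ks.knee_translation(pik, models["CAST_IK"], "right")
        assert np.abs(t6).max() > 1.0
        assert np.abs(tik).max() < 1e-9

    def test_objective_monotone_within_frames(self, noisy_trial, models):
        trial, _ = noisy_trial
        poses = ks.solve_ik_trajectory(trial, models["CAST_IK"],
                                       record_diagnostics=True)
        for hist in poses.diagnostics["cost_histories"][:100]:
            assert np.all(np.diff(hist) <= 1e-12)

    def test_wrong_joint_model_rejected(self, clean_trial, models):
        trial, _ = clean_trial
        with pytest.raises(InvalidParameterError):
            ks.solve_ik_trajectory(trial, models["IOR_6DoF"])


class TestJointAngles:
    def test_static_pose_angles_zero(self, subject, static_trial, models):
        poses = ks.solve_6dof_trajectory(static_trial, models["IOR_6DoF"])
        for joint in ("knee", "hip", "ankle"):
            for side in ("right", "left"):
                angles = ks.joint_angle_series(poses, joint, side,
                                               models["IOR_6DoF"]).angles
                assert np.abs(angles).max() < 1e-7

    def test_left_right_symmetric_motion_same_signed_angles(self,
                                                            clean_trial):
        _, truth = clean_trial
        r = truth.joint_angle_curves[("knee", "right")]
        lft = truth.joint_angle_curves[("knee", "left")]
        # generator motion is bilaterally symmetric: identical signed curves
        np.testing.assert_allclose(r, lft, atol=1e-9)

    def test_flexion_ramp_recovered(self, clean_trial, poses_6dof_clean,
                                    models):
        trial, truth = clean_trial
        kfa = ks.joint_angle_series(poses_6dof_clean, "knee", "right",
                                    models["IOR_6DoF"]).flexion
        np.testing.assert_allclose(
            kfa, truth.aux["knee_flexion_deg"], atol=0.1)


class TestAngularVelocity:
    def test_constant_angle_zero(self):
        series = ks.JointAngleSeries(angles=np.full((50, 3), 30.0),
                                     joint="knee", side="right", rate=100.0)
        np.testing.assert_allclose(ks.angular_velocity(series), 0.0,
                                   atol=1e-12)

    def test_linear_ramp_constant_velocity(self):
        t = np.arange(100) / 100.0
        angles = np.zeros((100, 3))
        angles[:, 0] = 40.0 * t
        series = ks.JointAngleSeries(angles=angles, joint="knee",
                                     side="right", rate=100.0)
        np.testing.assert_allclose(ks.angular_velocity(series), 40.0,
                                   atol=1e-9)

    def test_sinusoid_amplitude(self):
        rate, freq, amp = 100.0, 1.0, 20.0
        t = np.arange(500) / rate
        angles = np.zeros((500, 3))
        angles[:, 0] = amp * np.sin(2 * np.pi * freq * t)
        series = ks.JointAngleSeries(angles=angles, joint="knee",
                                     side="right", rate=rate)
        vel = ks.angular_velocity(series)
        expected = 2 * np.pi * freq * amp
        assert np.max(np.abs(vel[10:-10])) == pytest.approx(expected,
                                                            rel=1e-3)

    def test_short_series_rejected(self):
        series = ks.JointAngleSeries(angles=np.zeros((3, 3)), joint="knee",
                                     side="right", rate=100.0)
        with pytest.raises(InvalidParameterError):
            ks.angular_velocity(series)
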