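"""Newton-Euler chain against closed-form statics and generator physics."""

import numpy as np
import pytest

import kneests as ks
from kneests.errors import InvalidParameterError
from kneests.geometry import (angular_velocity_from_rotations,
                              central_difference)
from kneests.io import GRAVITY
from kneests.pose import SegmentPoseSeries


@pytest.fixture(scope="module")
def static_poses(subject):
    n = 60
    names = list(subject.true_frames)
    return SegmentPoseSeries(
        rotations={k: np.tile(subject.true_frames[k][0], (n, 1, 1))
                   for k in names},
        origins={k: np.tile(subject.true_frames[k][1], (n, 1))
                 for k in names},
        residuals={k: np.zeros(n) for k in names},
        valid={k: np.ones(n, dtype=bool) for k in names},
        rate=100.0)


class TestSegmentKinematics:
    def test_stationary_pose_zero_derivatives(self, static_poses, models):
        kin = ks.segment_kinematics(static_poses, models["IOR_6DoF"],
                                    ["shank_right"])
        k = kin["shank_right"]
        assert np.abs(k.com_acc).max() < 1e-9
        assert np.abs(k.omega).max() < 1e-9

    def test_generator_com_acceleration_recovered(self, clean_trial,
                                                  true_pose_series, models):
        _, truth = clean_trial
        kin = ks.segment_kinematics(true_pose_series, models["IOR_6DoF"],
                                    ["thigh_right"])
        # oracle: differentiate the same segment COM independently
        model = models["IOR_6DoF"]
        rot, org = truth.segment_poses["thigh_right"]
        com = (org + np.einsum("fij,j->fi", rot,
                               model.segments["thigh_right"].com_local)) \
            / 1000.0
        acc = np.stack([central_difference(com[:, i], 100.0, order=2)
                        for i in range(3)], axis=1)
        np.testing.assert_allclose(kin["thigh_right"].com_acc, acc,
                                   atol=1e-9)

    def test_gap_frames_rejected(self, static_poses, models):
        static_poses.valid["shank_right"][10] = False
        try:
            with pytest.raises(InvalidParameterError, match="shank_right"):
                ks.segment_kinematics(static_poses, models["IOR_6DoF"],
                                      ["shank_right"])
        finally:
            static_poses.valid["shank_right"][10] = True


class TestNewtonEulerChain:
    def test_static_knee_moment_closed_form(self, static_poses, models):
        """Vertical force at a COP a lever arm anterior of the knee: the
        external knee moment equals the hand-computed statics."""
        model = models["IOR_6DoF"]
        n = static_poses.n_frames
        knee = model.joint_centers_lab0["knee_right"] / 1000.0
        lever = 0.12  # m anterior
        fz = 400.0
        cop = np.tile([(knee[0] + lever) * 1000.0, knee[1] * 1000.0, 0.0],
                      (n, 1))
        force = np.tile([0.0, 0.0, fz], (n, 1))
        chain = ks.newton_euler_chain(static_poses, model, force, cop,
                                      np.zeros(n), "right")
        external = -chain["knee"]["moment"][5]
        # closed form: GRF lever minus gravity terms of foot + shank
        g_vec = np.array([0.0, 0.0, -GRAVITY])
        expected = np.cross([lever, 0.0, 0.0], [0.0, 0.0, fz])
        for seg in ("foot_right", "shank_right"):
            mass = model.inertia[seg.split("_")[0]].mass
            com = (static_poses.origins[seg][0]
                   + static_poses.rotations[seg][0]
                   @ model.segments[seg].com_local) / 1000.0
            expected = expected + np.cross(com - knee, mass * g_vec)
        np.testing.assert_allclose(external, expected,
                                   rtol=0.005, atol=1e-9)

    def test_zero_grf_massless_equilibrium(self, static_poses, models):
        import copy
        model = copy.deepcopy(models["IOR_6DoF"])
        for seg in ("foot", "shank"):
            model.inertia[seg].mass = 0.0
        n = static_poses.n_frames
        chain = ks.newton_euler_chain(static_poses, model, np.zeros((n, 3)),
                                      np.zeros((n, 3)), np.zeros(n), "right")
        assert np.abs(chain["knee"]["moment"]).max() < 1e-12
        assert np.abs(chain["knee"]["force"]).max() < 1e-12

    def test_static_joint_force_supports_weight_below(self, static_poses,
                                                      models):
        model = models["IOR_6DoF"]
        n = static_poses.n_frames
        weight_distal = (model.inertia["foot"].mass
                         + model.inertia["shank"].mass) * GRAVITY
        chain = ks.newton_euler_chain(static_poses, model, np.zeros((n, 3)),
                                      np.zeros((n, 3)), np.zeros(n), "right")
        assert chain["knee"]["force"][5, 2] == pytest.approx(weight_distal,
                                                             abs=0.1)

    def test_generator_consistency_pelvis_residual(self, subject,
                                                   clean_trial,
                                                   true_pose_series, models):
        """Inverse dynamics applied to generator kinematics with
        generator-consistent plate signals closes the whole-body balance:
        the residual wrench at the pelvis root (HAT dynamics vs hip loads
        + seat wrench) vanishes within numerical-differentiation error."""
        _, truth = clean_trial
        model = models["IOR_6DoF"]
        ev = truth.event_frames
        lo, hi = ev["seat_off"] + 25, ev["seat_on"] - 25
        hip = {s: ks.newton_euler_chain(
            true_pose_series, model, truth.aux["feet_force"][s],
            truth.aux["cops"][s], truth.aux["free_mz"][s], s, (lo, hi))["hip"]
            for s in ("right", "left")}
        g_vec = np.array([0.0, 0.0, -GRAVITY])
        rot_p, org_p = truth.segment_poses["pelvis"]
        hat_com = (org_p + np.einsum("fij,j->fi", rot_p,
                                     subject.hat_com_in_pelvis)) / 1000.0
        hat_m = subject.inertia["hat"].mass
        acc = np.stack([central_difference(hat_com[:, k], 100.0, order=2)
                        for k in range(3)], axis=1)
        res_f = (hat_m * (acc[lo:hi] - g_vec)
                 - (-hip["right"]["force"]) - (-hip["left"]["force"])
                 - truth.aux["seat_force"][lo:hi])
        assert np.abs(res_f[5:-5]).max() < 1e-6

        i_hat = subject.inertia["hat"].inertia_tensor
        omega = angular_velocity_from_rotations(rot_p, 100.0)
        i_lab = np.einsum("fij,jk,flk->fil", rot_p, i_hat, rot_p)
        ang_mom = np.einsum("fij,fj->fi", i_lab, omega)
        d_l = np.stack([central_difference(ang_mom[:, k], 100.0)
                        for k in range(3)], axis=1)
        moment = 0.0
        for s in ("right", "left"):
            arm = hip[s]["point"] - hat_com[lo:hi]
            moment = moment + (-hip[s]["moment"]) \
                + np.cross(arm, -hip[s]["force"])
        n_frames = rot_p.shape[0]
        seat_point = np.column_stack([
            org_p[:, 0] / 1000.0 - 0.06, org_p[:, 1] / 1000.0,
            np.full(n_frames, 0.43)])
        seat_m = truth.aux["seat_moment"][lo:hi] + np.cross(
            seat_point[lo:hi] - hat_com[lo:hi],
            truth.aux["seat_force"][lo:hi])
        res_m = d_l[lo:hi] - moment - seat_m
        assert np.abs(res_m[5:-5]).max() < 1e-3


class TestNormalizeAndResolve:
    def test_unit_conversion(self):
        moment = np.tile([-70.0, 0.0, 0.0], (10, 1))  # internal, lab frame
        series = ks.normalize_and_resolve(moment, 70.0, None, "knee",
                                          "right", 100.0,
                                          resolution_frame="lab")
        # external = +70 about X; knee flexion sign flips the X component
        assert series.moments[0, 0] == pytest.approx(-1.0)

    def test_mass_normalization_linearity(self):
        rng = np.random.default_rng(0)
        moment = rng.normal(size=(20, 3))
        a = ks.normalize_and_resolve(moment, 60.0, None, "knee", "right",
                                     100.0, resolution_frame="lab")
        b = ks.normalize_and_resolve(moment, 120.0, None, "knee", "right",
                                     100.0, resolution_frame="lab")
        np.testing.assert_allclose(a.moments, 2.0 * b.moments, atol=1e-12)

    def test_resolution_frame_preserves_norm(self, static_poses, models):
        rng = np.random.default_rng(1)
        n = static_poses.n_frames
        moment = rng.normal(size=(n, 3))
        lab = ks.normalize_and_resolve(moment, 70.0, None, "knee", "right",
                                       100.0, resolution_frame="lab")
        prox = ks.normalize_and_resolve(moment, 70.0, static_poses, "knee",
                                        "right", 100.0,
                                        resolution_frame="proximal")
        np.testing.assert_allclose(np.linalg.norm(lab.moments, axis=1),
                                   np.linalg.norm(prox.moments, axis=1),
                                   atol=1e-12)

    def test_invalid_mass_rejected(self):
        with pytest.raises(InvalidParameterError):
            ks.normalize_and_resolve(np.zeros((5, 3)), 0.0, None, "knee",
                                     "right", 100.0)
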