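"""Marker sets, joint-centre regressions, frames, inertia, model building."""

import dataclasses

import numpy as np
import pytest

import kneests as ks
from kneests.calibration import (StaticCalibration, bell_hip_joint_center,
                                 build_segment_frames,
                                 load_anthropometric_table)
from kneests.errors import (DegenerateGeometryError, InvalidParameterError,
                            MissingMarkerError)
from kneests.markersets import load_marker_set


class TestMarkerSets:
    def test_marker_counts_match_protocol_definitions(self):
        ior = load_marker_set("IOR")
        cast = load_marker_set("CAST")
        assert len(ior.static_labels) == 26
        assert len(ior.dynamic_labels) == 20
        assert len(cast.static_labels) == 36
        assert len(cast.dynamic_labels) == 28

    def test_combined_set_is_union_without_duplicates(self):
        from kneests.markersets import combined_static_labels
        union = combined_static_labels()
        assert len(union) == len(set(union))
        ior = set(load_marker_set("IOR").static_labels)
        cast = set(load_marker_set("CAST").static_labels)
        assert set(union) == ior | cast

    def test_every_segment_has_three_tracking_targets_after_augmentation(self):
        for name in ("IOR", "CAST"):
            spec = load_marker_set(name)
            for seg in spec.segments.values():
                n = len(seg.tracking) + (1 if seg.augment_hip_center else 0)
                assert n >= 3, f"{name}:{seg.segment}"

    def test_unknown_set_rejected(self):
        with pytest.raises(InvalidParameterError):
            load_marker_set("VICON")


class TestBellRegression:
    def test_reference_geometry(self):
        # inter-ASIS distance 240 mm -> offsets (+-86.4, -45.6, -72.0) mm
        # in (lateral, anterior, vertical) pelvis axes
        rasis = np.array([0.0, -120.0, 900.0])
        lasis = np.array([0.0, +120.0, 900.0])
        hjc = bell_hip_joint_center(lasis, rasis, None, None)
        np.testing.assert_allclose(hjc["right"], [86.4, -45.6, -72.0])
        np.testing.assert_allclose(hjc["left"], [-86.4, -45.6, -72.0])

    def test_left_right_mirror_symmetry(self):
        rasis, lasis = np.array([3.0, -115.0, 0.0]), np.array([3.0, 118.0, 0.0])
        hjc = bell_hip_joint_center(lasis, rasis, None, None)
        np.testing.assert_allclose(hjc["right"] * [-1, 1, 1], hjc["left"])

    def test_linearity_in_inter_asis_distance(self):
        rasis, lasis = np.array([0.0, -120.0, 0.0]), np.array([0.0, 120.0, 0.0])
        one = bell_hip_joint_center(lasis, rasis, None, None)
        two = bell_hip_joint_center(2 * lasis, 2 * rasis, None, None)
        np.testing.assert_allclose(2 * one["right"], two["right"])

    def test_zero_distance_rejected(self):
        p = np.zeros(3)
        with pytest.raises(DegenerateGeometryError):
            bell_hip_joint_center(p, p, None, None)


class TestStaticPose:
    def test_constant_positions_recovered(self, static_trial):
        calib = ks.compute_static_pose(static_trial)
        assert calib.n_frames_used == static_trial.n_frames
        for label in static_trial.marker_labels:
            assert calib.residual_sd[label] == pytest.approx(0.0, abs=1e-9)

    def test_noise_sd_estimated(self, subject):
        trial = ks.generate_static_trial(
            subject, artifact=ks.ArtifactConfig(measurement_noise_sd=1.0,
                                                rng_seed=5))
        calib = ks.compute_static_pose(trial)
        sds = np.array(list(calib.residual_sd.values()))
        assert np.mean(sds) == pytest.approx(1.0, rel=0.05)

    def test_missing_label_named_in_error(self, static_trial):
        with pytest.raises(MissingMarkerError, match="RXXX"):
            ks.compute_static_pose(static_trial, required_labels=["RXXX"])

    def test_too_few_frames_rejected(self, subject):
        trial = ks.generate_static_trial(subject, artifact=ks.NOISE_FREE)
        short = dataclasses.replace(
            trial, marker_positions=trial.marker_positions[:5])
        with pytest.raises(InvalidParameterError):
            ks.compute_static_pose(short)


class TestFramesAndClusters:
    def test_noise_free_frames_recover_truth(self, subject, static_trial):
        calib = ks.compute_static_pose(static_trial)
        skel = build_segment_frames(calib)
        for name, (rot_true, org_true) in subject.true_frames.items():
            rot, org = skel.frames[name]
            assert np.abs(rot - rot_true).max() < 1e-9
            assert np.abs(org - org_true).max() < 1e-6

    def test_frames_orthonormal(self, static_trial):
        calib = ks.compute_static_pose(static_trial)
        skel = build_segment_frames(calib)
        for rot, _ in skel.frames.values():
            assert np.abs(rot.T @ rot - np.eye(3)).max() < 1e-12

    def test_cluster_calibration_round_trip(self, static_trial):
        calib = ks.compute_static_pose(static_trial)
        cluster = ["RTH1", "RTH2", "RTH3", "RTH4"]
        locals_ = ks.calibrate_cluster(calib, cluster, ["RLE", "RME"])
        # reconstruct in the same static pose
        from kneests.geometry import orthonormal_frame
        pts = np.stack([calib[lab] for lab in cluster])
        centroid = pts.mean(axis=0)
        rot = orthonormal_frame(pts[0] - centroid, pts[1] - centroid,
                                order=("x", "y"))
        for lab in ("RLE", "RME"):
            rec = centroid + rot @ locals_[lab]
            assert np.abs(rec - calib[lab]).max() < 1e-9

    def test_cluster_locals_invariant_to_rigid_displacement(self,
                                                           static_trial):
        calib = ks.compute_static_pose(static_trial)
        moved = StaticCalibration(
            mean_positions={
                k: ks.cardan_xyz_compose(10.0, -5.0, 30.0) @ v
                + np.array([100.0, -50.0, 20.0])
                for k, v in calib.mean_positions.items()},
            residual_sd=calib.residual_sd,
            n_frames_used=calib.n_frames_used)
        a = ks.calibrate_cluster(calib, ["RSK1", "RSK2", "RSK3", "RSK4"],
                                 ["RLM"])
        b = ks.calibrate_cluster(moved, ["RSK1", "RSK2", "RSK3", "RSK4"],
                                 ["RLM"])
        np.testing.assert_allclose(a["RLM"], b["RLM"], atol=1e-9)

    def test_collinear_cluster_rejected(self, static_trial):
        calib = ks.compute_static_pose(static_trial)
        bad = StaticCalibration(
            mean_positions={**calib.mean_positions,
                            "X1": np.array([0.0, 0, 0]),
                            "X2": np.array([1.0, 0, 0]),
                            "X3": np.array([2.0, 0, 0])},
            residual_sd={}, n_frames_used=10)
        with pytest.raises(DegenerateGeometryError):
            ks.calibrate_cluster(bad, ["X1", "X2", "X3"], ["RLM"])


class TestInertia:
    def test_reference_thigh_mass(self):
        params = ks.compute_inertial_parameters(
            70.0, {"thigh": 400.0, "shank": 400.0, "foot": 250.0})
        assert params["thigh"].mass == pytest.approx(7.00)

    def test_masses_scale_linearly(self):
        lengths = {"thigh": 400.0, "shank": 400.0, "foot": 250.0}
        a = ks.compute_inertial_parameters(60.0, lengths)
        b = ks.compute_inertial_parameters(120.0, lengths)
        for seg in a:
            assert b[seg].mass == pytest.approx(2 * a[seg].mass)

    def test_table_fractions_in_unit_interval(self):
        table = load_anthropometric_table()
        for row in table.values():
            assert 0 < row["mass_fraction"] < 1
            assert 0 < row["com_fraction"] < 1

    def test_modeled_mass_fractions_sum_to_one(self):
        table = load_anthropometric_table()
        total = (2 * (table["thigh"]["mass_fraction"]
                      + table["shank"]["mass_fraction"]
                      + table["foot"]["mass_fraction"])
                 + table["hat"]["mass_fraction"])
        assert total == pytest.approx(1.0, abs=1e-3)


class TestSubjectModel:
    def test_ior_and_cast_share_joint_centers_noise_free(self, models):
        for joint in ("hip_right", "knee_left", "ankle_right"):
            np.testing.assert_allclose(
                models["IOR_6DoF"].joint_centers_lab0[joint],
                models["CAST_6DoF"].joint_centers_lab0[joint], atol=1e-9)

    def test_model_json_round_trip(self, models, tmp_path):
        model = models["CAST_IK"]
        model.save_json(tmp_path / "model.json")
        back = ks.SubjectModel.load_json(tmp_path / "model.json")
        assert back.protocol == model.protocol
        np.testing.assert_allclose(
            back.segments["thigh_right"].tracking_locals,
            model.segments["thigh_right"].tracking_locals, atol=1e-12)
        assert back.inertia["thigh"].mass == pytest.approx(
            model.inertia["thigh"].mass)

    def test_model_recovers_generator_truth(self, subject, models):
        model = models["IOR_6DoF"]
        for key, true_local in subject.true_joint_centers.items():
            np.testing.assert_allclose(model.joint_centers_local[key],
                                       true_local, atol=1e-6)
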