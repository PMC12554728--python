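"""Generator invariants: determinism, physics consistency, rigidity."""

import numpy as np
import pytest

import kneests as ks
from kneests.errors import InvalidParameterError
from kneests.geometry import central_difference
from kneests.io import GRAVITY
from kneests.markersets import SIDE_PREFIX


class TestSubjectGeneration:
    def test_combined_marker_set_resolvable(self, subject):
        from kneests.markersets import load_marker_set
        for name in ("IOR", "CAST"):
            for label in load_marker_set(name).static_labels:
                assert label in subject.tpose_positions

    def test_determinism_under_fixed_seed(self):
        a = ks.generate_subject(rng_seed=42)
        b = ks.generate_subject(rng_seed=42)
        assert a.body_mass == b.body_mass
        for lab in a.tpose_positions:
            np.testing.assert_array_equal(a.tpose_positions[lab],
                                          b.tpose_positions[lab])

    def test_different_seeds_give_different_jitter(self):
        a = ks.generate_subject(rng_seed=1)
        b = ks.generate_subject(rng_seed=2)
        assert not np.allclose(a.true_marker_locals["RLE"],
                               b.true_marker_locals["RLE"])

    def test_invalid_anthropometry_rejected(self):
        with pytest.raises(InvalidParameterError):
            ks.generate_subject(ks.AnthropometryParams(stature_mean=-1.0))

    def test_cluster_markers_coplanar_within_tenth_mm(self, subject):
        for p in SIDE_PREFIX.values():
            for grp in ("TH", "SK"):
                pts = np.stack([subject.tpose_positions[f"{p}{grp}{i}"]
                                for i in range(1, 5)])
                centered = pts - pts.mean(axis=0)
                sv = np.linalg.svd(centered, compute_uv=False)
                assert sv[2] < 0.1  # out-of-plane extent
                # fits inside the 131 x 80 mm plate
                assert sv[0] <= 131.0 and sv[1] <= 80.0


class TestStaticTrial:
    def test_zero_noise_markers_exact(self, subject, static_trial):
        for m, lab in enumerate(static_trial.marker_labels):
            err = static_trial.marker_positions[:, m] \
                - subject.tpose_positions[lab]
            assert np.abs(err).max() < 1e-12

    def test_vertical_grf_equals_body_weight(self, subject, static_trial):
        total = static_trial.plate_forces[:, :, 2].sum(axis=0)
        np.testing.assert_allclose(total, subject.body_mass * GRAVITY,
                                   atol=1e-6)

    def test_noise_sd_realized(self, subject):
        trial = ks.generate_static_trial(
            subject, artifact=ks.ArtifactConfig(measurement_noise_sd=1.0))
        sd = trial.marker_positions.std(axis=0).mean()
        assert sd == pytest.approx(1.0, rel=0.03)

    def test_too_short_rejected(self, subject):
        with pytest.raises(InvalidParameterError):
            ks.generate_static_trial(subject, duration_s=0.5)


class TestStsTrial:
    def test_initial_knee_flexion_is_90_degrees(self, clean_trial):
        _, truth = clean_trial
        assert truth.joint_angle_curves[("knee", "right")][0, 0] \
            == pytest.approx(90.0, abs=1e-9)
        assert truth.joint_angle_curves[("knee", "left")][0, 0] \
            == pytest.approx(90.0, abs=1e-9)

    def test_rigidity_in_noise_free_limit(self, clean_trial):
        trial, _ = clean_trial
        # inter-marker distances within a segment constant over time
        for a, b in (("RTH1", "RTH3"), ("RLE", "RGT"), ("RCA", "RSM")):
            d = np.linalg.norm(trial.marker(a) - trial.marker(b), axis=1)
            assert d.max() - d.min() < 1e-9

    def test_event_frames_strictly_increasing(self, clean_trial):
        _, truth = clean_trial
        seq = [truth.event_frames[k] for k in
               ("onset", "seat_off", "stand_start", "stand_end", "seat_on",
                "end")]
        assert all(b > a for a, b in zip(seq, seq[1:]))

    def test_vertical_force_balance_with_seat(self, subject, clean_trial):
        # sum of plate + seat vertical force = m (g + a_com,z), checked by
        # differentiating the generated COM trajectory
        _, truth = clean_trial
        com_z = truth.aux["com_total_mm"][:, 2] / 1000.0
        acc_z = central_difference(com_z, truth.marker_rate, order=2)
        total_up = (truth.aux["feet_force"]["right"][:, 2]
                    + truth.aux["feet_force"]["left"][:, 2]
                    + truth.aux["seat_force"][:, 2])
        mass = truth.aux["total_mass"]
        required = mass * (GRAVITY + acc_z)
        np.testing.assert_allclose(total_up[2:-2], required[2:-2], atol=1e-3)

    def test_seated_feet_load_below_threshold(self, clean_trial):
        trial, truth = clean_trial
        onset = truth.event_frames["onset"]
        seated = (truth.aux["feet_force"]["right"][:onset, 2]
                  + truth.aux["feet_force"]["left"][:onset, 2])
        np.testing.assert_allclose(seated, 10.0, atol=1e-6)

    def test_seat_above_standing_hip_rejected(self, subject):
        with pytest.raises(InvalidParameterError):
            ks.generate_sts_trial(
                subject, ks.SyntheticProtocolConfig(seat_height=2000.0))

    def test_determinism(self, subject):
        art = ks.ArtifactConfig(rng_seed=9)
        t1, _ = ks.generate_sts_trial(subject, artifact=art)
        t2, _ = ks.generate_sts_trial(subject, artifact=art)
        np.testing.assert_array_equal(t1.marker_positions,
                                      t2.marker_positions)
        np.testing.assert_array_equal(t1.plate_forces, t2.plate_forces)

    def test_tibial_drawer_shifts_shank(self, subject):
        cfg = ks.SyntheticProtocolConfig(tibial_drawer_mm=10.0)
        _, truth = ks.generate_sts_trial(subject, cfg, ks.NOISE_FREE)
        _, base = ks.generate_sts_trial(subject, artifact=ks.NOISE_FREE)
        shift = (truth.segment_poses["shank_right"][1]
                 - base.segment_poses["shank_right"][1])
        assert np.linalg.norm(shift, axis=1).mean() == pytest.approx(10.0,
                                                                     rel=0.01)


class TestCohort:
    def test_design_counts(self):
        cohort = ks.generate_cohort(3, seed=7)
        assert len(cohort) == 3
        assert all(len(e["trials"]) == 3 for e in cohort)

    def test_minimum_cohort_size(self):
        with pytest.raises(InvalidParameterError):
            ks.generate_cohort(1)

    def test_two_subjects_is_smallest_legal(self):
        cohort = ks.generate_cohort(
            2, ks.SyntheticProtocolConfig(n_repetitions=1), seed=3)
        assert len(cohort) == 2

    def test_seeds_change_placement_jitter(self):
        a = ks.generate_cohort(2, ks.SyntheticProtocolConfig(n_repetitions=1),
                               seed=1)
        b = ks.generate_cohort(2, ks.SyntheticProtocolConfig(n_repetitions=1),
                               seed=2)
        la = a[0]["subject"].true_marker_locals["RLE"]
        lb = b[0]["subject"].true_marker_locals["RLE"]
        assert not np.allclose(la, lb)
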