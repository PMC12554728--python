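"""One-dimensional SPM: t curves, smoothness, RFT thresholds, clusters."""

import numpy as np
import pytest
from scipy import stats

import kneests as ks
from kneests.errors import InvalidParameterError
from kneests.spm import (SPMConfig, expected_euler_characteristic,
                         smooth_gaussian_curves, spm_paired_test)


@pytest.fixture(scope="module")
def smooth_pair():
    rng = np.random.default_rng(123)
    a = smooth_gaussian_curves(24, 101, 15.0, rng)
    b = smooth_gaussian_curves(24, 101, 15.0, rng)
    return a, b


class TestPairedTCurve:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 101))
        t, _ = ks.paired_t_curve(a, a.copy())
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_unit_mean_unit_sd_difference_gives_sqrt_n(self):
        # per-subject differences with sample mean 1 and sample SD exactly 1
        # must give t = sqrt(n) ~ 4.899 for n = 24 at every node
        n = 24
        z = np.arange(n, dtype=float)
        z = (z - z.mean()) / z.std(ddof=1)
        diff = 1.0 + z
        rng = np.random.default_rng(1)
        b = rng.normal(size=(n, 101))
        a = b + diff[:, None]
        t, _ = ks.paired_t_curve(a, b)
        np.testing.assert_allclose(t, np.sqrt(n), atol=1e-9)

    def test_agrees_with_scalar_t_test_per_node(self, smooth_pair):
        a, b = smooth_pair
        t, _ = ks.paired_t_curve(a, b)
        for q in (0, 17, 50, 100):
            scalar = stats.ttest_rel(a[:, q], b[:, q]).statistic
            assert t[q] == pytest.approx(scalar, abs=1e-10)

    def test_zero_variance_node_flagged_infinite(self):
        a = np.random.default_rng(2).normal(size=(8, 10))
        b = a.copy()
        b[:, 3] -= 1.0  # exact constant difference: zero variance
        t, _ = ks.paired_t_curve(a, b)
        assert np.isinf(t[3]) and t[3] > 0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InvalidParameterError):
            ks.paired_t_curve(np.zeros((2, 10)), np.zeros((2, 10)))


class TestFwhmEstimation:
    def test_calibration_against_known_smoothness(self):
        rng = np.random.default_rng(5)
        for w in (10.0, 15.0, 20.0):
            estimates = [ks.estimate_fwhm(
                smooth_gaussian_curves(24, 101, w, rng)) for _ in range(40)]
            assert np.mean(estimates) == pytest.approx(w, rel=0.15)

    def test_smoothing_increases_estimate(self):
        rng = np.random.default_rng(6)
        rough = smooth_gaussian_curves(24, 101, 4.0, rng)
        smooth = smooth_gaussian_curves(24, 101, 20.0, rng)
        assert ks.estimate_fwhm(smooth) > ks.estimate_fwhm(rough)

    def test_scale_invariance(self, smooth_pair):
        a, _ = smooth_pair
        residuals = a - a.mean(axis=0)
        assert ks.estimate_fwhm(residuals) == pytest.approx(
            ks.estimate_fwhm(17.3 * residuals), rel=1e-12)

    def test_constant_residuals_infinitely_smooth(self):
        assert np.isinf(ks.estimate_fwhm(np.zeros((5, 101))))


class TestRftThreshold:
    def test_exceeds_pointwise_critical_value(self):
        for fwhm in (5.0, 10.0, 25.0):
            t_star = ks.rft_critical_threshold(23, fwhm, 101, 0.05, True)
            pointwise = stats.t.isf(0.025, 23)
            assert t_star > pointwise

    def test_limit_of_very_smooth_field_is_pointwise(self):
        t_star = ks.rft_critical_threshold(23, 1e6, 101, 0.05, True)
        pointwise = stats.t.isf(0.025, 23)
        assert t_star == pytest.approx(pointwise, rel=0.02)

    def test_threshold_solves_expected_ec(self):
        t_star = ks.rft_critical_threshold(23, 12.0, 101, 0.05, True)
        ec = expected_euler_characteristic(t_star, 23, 100 / 12.0)
        assert ec == pytest.approx(0.025, abs=1e-7)

    def test_matches_permutation_threshold(self, smooth_pair):
        a, b = smooth_pair
        t, residuals = ks.paired_t_curve(a, b)
        fwhm = ks.estimate_fwhm(residuals)
        t_rft = ks.rft_critical_threshold(23, fwhm, 101, 0.05, True)
        t_perm = ks.permutation_threshold(
            a, b, SPMConfig(n_permutations=10000, rng_seed=4))
        assert t_rft == pytest.approx(t_perm, rel=0.05)

    def test_alpha_monotonicity(self, smooth_pair):
        a, b = smooth_pair
        t10 = ks.permutation_threshold(
            a, b, SPMConfig(alpha=0.10, n_permutations=2000))
        t05 = ks.permutation_threshold(
            a, b, SPMConfig(alpha=0.05, n_permutations=2000))
        assert t10 < t05

    def test_too_few_permutations_rejected(self, smooth_pair):
        a, b = smooth_pair
        with pytest.raises(InvalidParameterError):
            ks.permutation_threshold(a, b, SPMConfig(n_permutations=10))


class TestClusters:
    def test_no_excursion_empty(self):
        assert ks.suprathreshold_clusters(np.zeros(101), 3.0) == []

    def test_single_boxcar(self):
        t = np.zeros(101)
        t[40:61] = 5.0
        clusters = ks.suprathreshold_clusters(t, 3.0)
        assert len(clusters) == 1
        assert 39.0 <= clusters[0].start <= 40.0
        assert 60.0 <= clusters[0].end <= 61.0
        assert clusters[0].max_abs_t == pytest.approx(5.0)

    def test_two_excursions_match_brute_force(self):
        rng = np.random.default_rng(9)
        t = rng.normal(size=101)
        t[10:20] += 6.0
        t[70:80] -= 6.0
        t_star = 4.0
        clusters = ks.suprathreshold_clusters(t, t_star)
        over = np.abs(t) > t_star
        brute = []
        i = 0
        while i < 101:
            if over[i]:
                j = i
                while j + 1 < 101 and over[j + 1]:
                    j += 1
                brute.append((i, j))
                i = j + 1
            else:
                i += 1
        assert len(clusters) == len(brute)
        for cl, (i, j) in zip(clusters, brute):
            assert i - 1 <= cl.start <= i
            assert j <= cl.end <= j + 1
        assert clusters[0].sign == 1 and clusters[-1].sign == -1


class TestFullTest:
    def test_null_rarely_significant(self, smooth_pair):
        a, b = smooth_pair
        res = spm_paired_test(a, b)
        assert res.df == 23
        assert res.critical_threshold > 3.0

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(10)
        a = smooth_gaussian_curves(20, 101, 12.0, rng)
        b = smooth_gaussian_curves(20, 101, 12.0, rng)
        bump = np.exp(-0.5 * ((np.arange(101) - 50) / 8.0) ** 2)
        res = spm_paired_test(a + 3.0 * bump, b)
        assert res.significant
        assert any(c.start < 50 < c.end for c in res.clusters)
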