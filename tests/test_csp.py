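import numpy as np
import pytest
import scipy.optimize

from mibci.csp import (
    CovarianceEstimate,
    class_covariance,
    fit_csp,
    fit_fbcsp,
    logvar_features,
    project,
    project_trialset,
    FeatureSeries,
)
from mibci.data import Trial, TrialSet
from mibci.filterbank import default_filter_bank


def random_psd(rng, n=4):
    a = rng.normal(size=(n, n))
    return a @ a.T + 1e-3 * np.eye(n)


def rayleigh(w, c1, c2):
    return float(w @ c1 @ w) / float(w @ c2 @ w)


def brute_force_max_rayleigh(c1, c2, rng, restarts=10):
    """Independent oracle: multi-restart Nelder-Mead over unit vectors."""
    best = -np.inf
    n = c1.shape[0]
    for _ in range(restarts):
        w0 = rng.normal(size=n)
        res = scipy.optimize.minimize(
            lambda w: -rayleigh(w, c1, c2), w0, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
        )
        best = max(best, -res.fun)
    return best


class TestClassCovariance:
    def test_white_noise_tends_to_scaled_identity(self, rng):
        trials = [Trial(rng.standard_normal((4, 20000)), label=1) for _ in range(5)]
        c = class_covariance(trials, 1).matrix
        assert np.allclose(np.diag(c), 0.25, atol=0.02)
        off = c - np.diag(np.diag(c))
        assert np.max(np.abs(off)) < 0.02

    def test_hand_computed_single_trial(self):
        trial = Trial(np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, 1.0, 1.0]]), label=1)
        c = class_covariance([trial], 1).matrix
        np.testing.assert_allclose(c, np.diag([1.0, 0.0]), atol=1e-12)

    def test_symmetric_psd_for_random_input(self, rng):
        trials = [Trial(rng.normal(size=(5, 50)), label=1) for _ in range(3)]
        c = class_covariance(trials, 1).matrix
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        assert np.linalg.eigvalsh(c).min() >= -1e-10

    def test_empty_class_rejected(self):
        trial = Trial(np.ones((2, 4)), label=1)
        with pytest.raises(ValueError):
            class_covariance([trial], 2)


class TestFitCSP:
    def test_axis_aligned_diagonal_example(self):
        c1 = CovarianceEstimate(np.diag([4.0, 1.0]) / 5.0)
        c2 = CovarianceEstimate(np.diag([1.0, 4.0]) / 5.0)
        fs = fit_csp(c1, c2, m=1)
        np.testing.assert_allclose(fs.eigenvalues, [0.8, 0.2], atol=1e-5)
        for row, axis in zip(fs.projection, np.eye(2)):
            cos = abs(row @ axis) / np.linalg.norm(row)
            assert cos > 0.999

    def test_identical_classes_give_half_eigenvalues(self, rng):
        c = random_psd(rng)
        fs = fit_csp(CovarianceEstimate(c), CovarianceEstimate(c.copy()), m=2)
        np.testing.assert_allclose(fs.eigenvalues, 0.5, atol=1e-10)

    def test_eigenvalue_pairing_between_class_views(self, rng):
        c1, c2 = random_psd(rng), random_psd(rng)
        lam_a = fit_csp(CovarianceEstimate(c1), CovarianceEstimate(c2), 1).eigenvalues
        lam_b = fit_csp(CovarianceEstimate(c2), CovarianceEstimate(c1), 1).eigenvalues
        np.testing.assert_allclose(lam_a, 1.0 - lam_b[::-1], atol=1e-10)

    def test_composite_normalization_of_filters(self, rng):
        c1, c2 = random_psd(rng), random_psd(rng)
        fs = fit_csp(CovarianceEstimate(c1), CovarianceEstimate(c2), 2)
        for w in fs.projection:
            assert w @ (c1 + c2) @ w == pytest.approx(1.0, rel=1e-4)

    def test_too_many_filters_rejected(self, rng):
        c = random_psd(rng, 2)
        with pytest.raises(ValueError):
            fit_csp(CovarianceEstimate(c), CovarianceEstimate(c), m=2)

    def test_rayleigh_ratio_matches_brute_force(self, rng):
        # eigendecomposition vs independent numerical maximization
        for _ in range(10):
            c1, c2 = random_psd(rng), random_psd(rng)
            fs = fit_csp(CovarianceEstimate(c1), CovarianceEstimate(c2), 1)
            ours = rayleigh(fs.projection[0], c1, c2)
            oracle = brute_force_max_rayleigh(c1, c2, rng)
            assert abs(ours - oracle) / oracle < 1e-6


@pytest.fixture(scope="module")
def four_class_trialset():
    rng = np.random.default_rng(5)
    trials = [
        Trial(rng.normal(size=(6, 400)), label=1 + i % 4) for i in range(24)
    ]
    return TrialSet(trials, class_set=[1, 2, 3, 4], sample_rate_hz=250.0)


class TestFitFBCSP:
    def test_binary_gives_one_set_per_band(self, small_epoched_trialset):
        bank = default_filter_bank(250.0)
        sets = fit_fbcsp(small_epoched_trialset, bank, m=1)
        assert len(sets) == 10
        assert [s.band_index for s in sets] == list(range(10))
        assert all(s.ovr_class is None for s in sets)
        assert all(s.n_filters == 2 for s in sets)  # m=1 -> M=2

    def test_four_class_ovr_gives_band_times_class(self, four_class_trialset):
        bank = default_filter_bank(250.0)
        sets = fit_fbcsp(four_class_trialset, bank, m=2)
        assert len(sets) == 40
        # band-major then class order
        assert [(s.band_index, s.ovr_class) for s in sets[:4]] == [
            (0, 1), (0, 2), (0, 3), (0, 4)]
        assert all(s.n_filters == 4 for s in sets)  # m=2 -> M=4


class TestProject:
    def test_identity_projection_returns_channels(self, rng):
        x = rng.normal(size=(3, 100))
        x -= x.mean(axis=1, keepdims=True)
        trial = Trial(x, label=1)
        from mibci.csp import CSPFilterSet

        fs = CSPFilterSet(projection=np.eye(3), eigenvalues=np.ones(3), m=1,
                          band_index=0)
        z = project([trial], [fs])
        np.testing.assert_allclose(z.values, x, atol=1e-12)
        assert z.label == 1

    def test_feature_row_counts_match_layout_rule(self, small_epoched_trialset,
                                                  four_class_trialset):
        bank = default_filter_bank(250.0)
        # 2-class, 3 channels, m=1, 10 bands -> D = 20
        sets2 = fit_fbcsp(small_epoched_trialset, bank, m=1)
        z2 = project_trialset(small_epoched_trialset.subset([0]), bank, sets2)[0]
        assert z2.n_rows == 20
        assert len(z2.layout) == 20
        assert z2.n_samples == small_epoched_trialset.n_samples
        # 4-class OVR, m=2, 10 bands -> D = 160
        sets4 = fit_fbcsp(four_class_trialset, bank, m=2)
        z4 = project_trialset(four_class_trialset.subset([0]), bank, sets4)[0]
        assert z4.n_rows == 160

    def test_zero_input_zero_output(self):
        from mibci.csp import CSPFilterSet

        fs = CSPFilterSet(projection=np.eye(2), eigenvalues=np.ones(2), m=1,
                          band_index=0)
        z = project([Trial(np.zeros((2, 50)), label=1)], [fs])
        np.testing.assert_array_equal(z.values, 0.0)

    def test_dimension_mismatch_rejected(self):
        from mibci.csp import CSPFilterSet

        fs = CSPFilterSet(projection=np.eye(3), eigenvalues=np.ones(3), m=1,
                          band_index=0)
        with pytest.raises(ValueError):
            project([Trial(np.zeros((2, 50)), label=1)], [fs])


class TestLogvarFeatures:
    def test_sinusoid_variance_closed_form(self):
        t = np.arange(1000) / 250.0
        row = np.sin(2 * np.pi * 10 * t)  # whole periods: variance = 1/2
        z = FeatureSeries(values=row[None, :], label=1,
                          layout=[(0, None, 0)])
        feats = logvar_features(z, normalize=False)
        assert feats[0] == pytest.approx(np.log(0.5), abs=1e-3)

    def test_within_set_scale_invariance(self, rng):
        vals = rng.normal(size=(4, 200))
        layout = [(0, None, i) for i in range(2)] + [(1, None, i) for i in range(2)]
        z1 = FeatureSeries(vals, label=1, layout=layout)
        z2 = FeatureSeries(vals * np.array([3.0, 3.0, 7.0, 7.0])[:, None],
                           label=1, layout=layout)
        np.testing.assert_allclose(logvar_features(z1), logvar_features(z2),
                                   atol=1e-12)

    def test_zero_row_floored_finite(self):
        z = FeatureSeries(np.zeros((2, 50)), label=1,
                          layout=[(0, None, 0), (0, None, 1)])
        feats = logvar_features(z)
        assert np.all(np.isfinite(feats))
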