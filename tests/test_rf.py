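import numpy as np
import pytest

from t5rf import rf, stimuli
from t5rf.preprocess import NormalizedTrace, TrialTensor
from t5rf.rf import (
    DoGFit,
    FitRejection,
    GaussianFit,
    TuningCurve,
    align_by_crosscorr,
    apply_shift,
    bar_tuning_curve,
    cartesian_rf_map,
    fit_difference_of_gaussians,
    fit_gaussian,
    fourier_amplitude,
    freq_tuning_map,
    fwhm_from_w,
    strf_reverse_correlation,
)


def gaussian(x, A, x0, w):
    return A * np.exp(-((x - x0) ** 2) / w**2)


def dog(x, A_c, A_s, x0, w_c, w_s):
    return gaussian(x, A_c, x0, w_c) - gaussian(x, A_s, x0, w_s)


class TestBarTuningCurve:
    def test_signed_extrema_kept(self):
        data = np.zeros((2, 3, 10))
        data[0, :, 4] = 0.5
        data[1, :, 2] = -0.2
        data[1, :, 7] = 0.1
        tens = TrialTensor(data, np.arange(10) / 10, [2.5, 4.5], "bar_off")
        curve = bar_tuning_curve(tens)
        np.testing.assert_allclose(curve.amplitudes, [0.5, -0.2])

    def test_all_zero_tensor(self):
        tens = TrialTensor(np.zeros((3, 2, 8)), np.arange(8) / 10,
                           [0.0, 2.0, 4.0], "bar_on")
        np.testing.assert_array_equal(bar_tuning_curve(tens).amplitudes, 0.0)

    def test_epoch_mean_mode(self):
        data = np.ones((1, 2, 10)) * 0.3
        tens = TrialTensor(data, np.arange(10) / 10, [0.0], "bar_off")
        assert bar_tuning_curve(tens, "epoch_mean").amplitudes[0] == pytest.approx(0.3)


class TestGaussianFit:
    def test_noiseless_recovery(self):
        x = np.arange(0.0, 60.0, 2.0)
        curve = TuningCurve(x, gaussian(x, 2.0, 10.0, 5.0))
        fit = fit_gaussian(curve)
        assert isinstance(fit, GaussianFit)
        assert fit.A == pytest.approx(2.0, abs=1e-4)
        assert fit.x0 == pytest.approx(10.0, abs=1e-4)
        assert fit.w == pytest.approx(5.0, abs=1e-4)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_negative_amplitude_curve(self):
        x = np.arange(0.0, 60.0, 2.0)
        fit = fit_gaussian(TuningCurve(x, gaussian(x, -1.5, 30.0, 8.0)))
        assert isinstance(fit, GaussianFit)
        assert fit.A == pytest.approx(-1.5, abs=1e-4)

    def test_fwhm_formula_value(self):
        assert fwhm_from_w(5.0) == pytest.approx(2 * 5 * np.sqrt(np.log(2)))
        assert fwhm_from_w(5.0) == pytest.approx(8.3255, abs=1e-3)

    def test_fwhm_matches_measured_half_width(self):
        # formula-vs-measurement oracle: width at half the fitted peak on a
        # dense grid equals 2 w sqrt(log 2)
        x = np.arange(0.0, 60.0, 2.0)
        fit = fit_gaussian(TuningCurve(x, gaussian(x, 1.0, 30.0, 6.5)))
        dense = np.linspace(0, 60, 200001)
        above = dense[np.abs(fit(dense)) >= abs(fit.A) / 2]
        measured = above.max() - above.min()
        assert measured == pytest.approx(fit.fwhm, abs=1e-3)

    def test_flat_curve_rejected(self):
        x = np.arange(0.0, 30.0, 2.0)
        fit = fit_gaussian(TuningCurve(x, np.full(len(x), 0.7)))
        assert isinstance(fit, FitRejection)

    def test_r2_threshold_rejection(self):
        rng = np.random.default_rng(1)
        x = np.arange(0.0, 60.0, 2.0)
        fit = fit_gaussian(TuningCurve(x, rng.normal(size=len(x))), r2_min=0.9)
        assert isinstance(fit, FitRejection)

    def test_shift_equivariance(self):
        x = np.arange(0.0, 60.0, 2.0)
        y = gaussian(x, 1.2, 20.0, 6.0)
        f0 = fit_gaussian(TuningCurve(x, y))
        f1 = fit_gaussian(TuningCurve(x + 15.0, y))
        assert f1.x0 == pytest.approx(f0.x0 + 15.0, abs=1e-6)
        assert f1.w == pytest.approx(f0.w, abs=1e-6)


class TestDoGFit:
    def test_noiseless_recovery(self):
        x = np.arange(0.0, 60.0, 1.0)
        curve = TuningCurve(x, dog(x, 1.0, 0.3, 30.0, 4.0, 12.0))
        fit = fit_difference_of_gaussians(curve)
        assert isinstance(fit, DoGFit)
        assert fit.A_c == pytest.approx(1.0, abs=1e-3)
        assert fit.A_s == pytest.approx(0.3, abs=1e-3)
        assert fit.x0 == pytest.approx(30.0, abs=1e-3)
        assert fit.w_c == pytest.approx(4.0, abs=1e-3)
        assert fit.w_s == pytest.approx(12.0, abs=1e-3)

    def test_pure_gaussian_degenerates(self):
        x = np.arange(0.0, 60.0, 1.0)
        fit = fit_difference_of_gaussians(TuningCurve(x, gaussian(x, 1.0, 30.0, 5.0)))
        assert isinstance(fit, DoGFit)
        assert fit.A_s < 0.05 * fit.A_c

    def test_amplitude_cap(self):
        rng = np.random.default_rng(2)
        x = np.arange(0.0, 60.0, 1.0)
        y = dog(x, 1.0, 0.2, 30.0, 3.0, 9.0) * 0.5 + 0.02 * rng.normal(size=len(x))
        fit = fit_difference_of_gaussians(TuningCurve(x, y), r2_min=0.0)
        rng_amp = y.max() - y.min()
        assert isinstance(fit, DoGFit)
        assert fit.A_c <= 2 * rng_amp + 1e-9
        assert fit.A_c > fit.A_s >= 0

    def test_negative_curve_sign(self):
        x = np.arange(0.0, 60.0, 1.0)
        fit = fit_difference_of_gaussians(TuningCurve(x, -dog(x, 1.0, 0.3, 30.0, 4.0, 12.0)))
        assert isinstance(fit, DoGFit)
        assert fit.sign == -1.0
        assert fit.A_c == pytest.approx(1.0, abs=1e-3)


class TestStrf:
    def make_noise(self, geometry, seed=0, duration=120.0):
        return stimuli.build_ternary_noise(geometry, duration_s=duration, seed=seed)

    def test_delayed_copy_peaks_at_lag(self, geometry):
        noise = self.make_noise(geometry, seed=4)
        t = np.arange(0.0, noise.duration, 0.1)
        s = noise.sample(t)
        x_star = 6
        delay = 3  # samples of 0.1 s
        r = np.roll(s[:, x_star], delay)
        r[:delay] = 0.0
        strf = strf_reverse_correlation(
            NormalizedTrace(t, r, 1, 1, "plain"), noise, fit_spatial=False)
        lag_i, pos_i = strf.peak_index
        assert pos_i == x_star
        assert strf.lags[lag_i] == pytest.approx(0.3)
        assert np.linalg.norm(strf.k) == pytest.approx(1.0)

    def test_independent_response_noise_floor(self, geometry):
        noise = self.make_noise(geometry, seed=5, duration=300.0)
        rng = np.random.default_rng(6)
        t = np.arange(0.0, noise.duration, 0.1)
        r = rng.normal(size=len(t))
        strf = strf_reverse_correlation(
            NormalizedTrace(t, r, 1, 1, "plain"), noise,
            fit_spatial=False, normalize=False)
        # each raw entry is a mean of ~T*rate independent products of a unit
        # normal with a ternary value (variance 2/3): CLT noise floor
        assert np.abs(strf.k).max() < 3.0 / np.sqrt(len(t))

    def test_max_lag_validation(self, geometry):
        noise = self.make_noise(geometry, seed=0, duration=10.0)
        t = np.arange(0.0, 1.0, 0.1)
        with pytest.raises(stimuli.InvalidConfigError):
            strf_reverse_correlation(
                NormalizedTrace(t, np.zeros(10), 1, 1, "plain"), noise, max_lag_s=2.0)


class TestFreqTuning:
    def test_sinusoid_amplitude_convention(self):
        t = np.arange(0, 4.0, 0.1)
        assert fourier_amplitude(0.7 * np.sin(2 * np.pi * 1.25 * t), 10.0, 1.25) == \
            pytest.approx(0.7, abs=1e-9)

    def test_dc_offset_invariance(self):
        t = np.arange(0, 4.0, 0.1)
        x = 0.5 * np.sin(2 * np.pi * 0.5 * t)
        a = fourier_amplitude(x, 10.0, 0.5)
        b = fourier_amplitude(x + 3.0, 10.0, 0.5)
        assert a == pytest.approx(b, abs=1e-12)

    def test_harmonic_orthogonality(self):
        t = np.arange(0, 4.0, 0.1)
        x = np.sin(2 * np.pi * 2.5 * t)  # energy at 2f only
        assert fourier_amplitude(x, 10.0, 1.25) == pytest.approx(0.0, abs=1e-9)

    def test_map_from_tensor(self):
        lams, fs = [6.0, 10.0], [0.5, 1.25]
        conds = [(l, f) for l in lams for f in fs]
        t = np.arange(0, 4.0, 0.1)
        data = np.stack([
            np.vstack([0.3 * np.sin(2 * np.pi * f * t)] * 2) for (_, f) in conds
        ])
        tens = TrialTensor(data, t, conds, "grating")
        m = freq_tuning_map(tens)
        np.testing.assert_allclose(m.amplitudes, 0.3, atol=1e-9)
        scaled = m.scale_by_max()
        assert np.nanmax(scaled.amplitudes) == pytest.approx(1.0)

    def test_unresolvable_condition_flagged(self):
        conds = [(6.0, 8.0)]  # above the 5 Hz Nyquist of the 10 Hz grid
        t = np.arange(0, 4.0, 0.1)
        data = np.ones((1, 2, len(t)))
        m = freq_tuning_map(TrialTensor(data, t, conds, "grating"))
        assert np.isnan(m.amplitudes).all()


class TestCartesianMap:
    def test_positive_profiles(self):
        x = np.arange(0.0, 30.0, 2.0)
        h = gaussian(x, 1.0, 10.0, 4.0)
        v = gaussian(x, 0.5, 20.0, 4.0)
        m = cartesian_rf_map(h, v, x, x)
        assert np.all(m.category == "both_positive")
        i, j = np.unravel_index(np.argmax(m.values), m.values.shape)
        assert x[i] == pytest.approx(10.0)
        assert x[j] == pytest.approx(20.0)

    def test_mixed_sign_and_magnitude(self):
        h = np.array([1.0, 2.0])
        v = np.array([-3.0, -1.0])
        m = cartesian_rf_map(h, v)
        assert np.all(m.category == "mixed_sign")
        np.testing.assert_allclose(m.magnitude, np.abs(np.outer(h, v)))


class TestAlignment:
    def test_known_shift_recovered(self):
        x = np.arange(60)
        base = gaussian(x.astype(float), 1.0, 30.0, 5.0)
        shifted = apply_shift(base, 3)  # content moved 3 samples right
        shifts = align_by_crosscorr([base, shifted])
        assert shifts == [0, -3]
        np.testing.assert_allclose(apply_shift(shifted, -3)[5:-5], base[5:-5])

    def test_identical_curves_zero_shift(self):
        base = gaussian(np.arange(40.0), 1.0, 20.0, 4.0)
        assert align_by_crosscorr([base, base, base]) == [0, 0, 0]

    def test_noise_pair_matches_brute_force(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=50), rng.normal(size=50)

        def brute(template, curve):
            best, best_s = -np.inf, 0
            for s in range(-49, 50):
                v = np.dot(template, apply_shift(curve, s))
                if v > best:
                    best, best_s = v, s
            return best_s

        assert align_by_crosscorr([a, b])[1] == brute(a, b)

    def test_all_zero_curve_warns(self):
        base = gaussian(np.arange(40.0), 1.0, 20.0, 4.0)
        with pytest.warns(UserWarning):
            shifts = align_by_crosscorr([base, np.zeros(40)])
        assert shifts[1] == 0
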