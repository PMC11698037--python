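"""Damped-oscillation statistics: peaks, log decrement, FFT, cross-correlation."""

import math

import numpy as np
import pytest

from glidekin import (InsufficientPeaksError, ValidationError,
                      cross_correlation, damping_ratio_logdec, find_pitch_peaks,
                      natural_frequency_fft, undamped_frequency)
from glidekin.oscillation import characterize_oscillation, swing_amplitudes
from glidekin.simulate import pitch_step_response

ZETAS = (0.05, 0.1, 0.23, 0.4)


def analytic_cycle_amplitudes(zeta, n=5, a0=10.0):
    delta = 2 * math.pi * zeta / math.sqrt(1 - zeta ** 2)
    return a0 * np.exp(-delta * np.arange(n))


class TestFindPitchPeaks:
    def test_damped_sinusoid_peaks_at_analytic_times(self):
        t = np.arange(0, 1.5, 0.02)
        f_d = 4.0
        beta = pitch_step_response(t, zeta=0.11, f_d_hz=f_d, amplitude_deg=20)
        times, devs, base = find_pitch_peaks(t, beta, prominence_deg=1.0,
                                             smooth_cutoff_hz=None)
        # extrema of the ring-down sit at half-period intervals
        expected = (np.arange(1, len(times) + 1)) * 0.5 / f_d
        assert np.allclose(times, expected[:len(times)], atol=0.021)
        assert np.all(np.sign(devs[:-1]) != np.sign(devs[1:]))

    def test_constant_pitch_has_no_peaks(self):
        t = np.arange(0, 1.0, 0.02)
        with pytest.raises(InsufficientPeaksError):
            find_pitch_peaks(t, np.full(t.size, 5.0))

    def test_noise_wiggles_rejected(self):
        t = np.arange(0, 1.5, 0.02)
        clean = pitch_step_response(t, zeta=0.23, f_n_hz=4.7, amplitude_deg=20)
        noisy = pitch_step_response(t, zeta=0.23, f_n_hz=4.7, amplitude_deg=20,
                                    noise_sigma_deg=0.5, seed=8)
        tc, _, _ = find_pitch_peaks(t, clean, prominence_deg=1.0)
        tn, devs, _ = find_pitch_peaks(t, noisy, prominence_deg=1.0)
        # the retained swing sequence is dominated by the true oscillation:
        # every kept swing above the noise floor matches a clean one in time
        big = np.abs(devs) > 1.5
        for time in tn[big]:
            assert np.min(np.abs(tc - time)) < 0.05

    def test_nonpositive_prominence_rejected(self):
        t = np.arange(0, 1.0, 0.02)
        with pytest.raises(ValidationError):
            find_pitch_peaks(t, np.sin(20 * t), prominence_deg=0.0)


class TestLogDecrement:
    def test_halving_amplitudes_give_ln2(self):
        delta, zeta = damping_ratio_logdec([10.0, 5.0])
        assert delta == pytest.approx(math.log(2), rel=1e-12)
        assert zeta == pytest.approx(0.1097, abs=2e-4)

    def test_equal_amplitudes_undamped(self):
        delta, zeta = damping_ratio_logdec([4.0, 4.0, 4.0])
        assert delta == 0.0 and zeta == 0.0

    @pytest.mark.parametrize("zeta_true", ZETAS)
    def test_exact_on_analytic_cycle_amplitudes(self, zeta_true):
        amps = analytic_cycle_amplitudes(zeta_true)
        _, zeta = damping_ratio_logdec(amps, "full-cycle")
        assert abs(zeta - zeta_true) < 1e-9

    @pytest.mark.parametrize("zeta_true", [0.05, 0.1, 0.23])
    def test_pipeline_recovery_from_sampled_response(self, zeta_true):
        t = np.arange(0, 1.5, 0.02)
        beta = pitch_step_response(t, zeta=zeta_true, f_n_hz=4.7, amplitude_deg=20)
        est = characterize_oscillation(t, beta)
        assert est.damping_ratio == pytest.approx(zeta_true, abs=0.02)

    def test_growing_oscillation_gives_negative_zeta(self):
        # negatively damped pitch (growing peaks) is reported, not clamped
        delta, zeta = damping_ratio_logdec([2.0, 3.0, 4.5], "full-cycle")
        assert delta < 0 and zeta < 0

    def test_zeta_consistent_with_stored_delta(self):
        delta, zeta = damping_ratio_logdec([10.0, 4.0, 1.6])
        assert zeta == delta / math.sqrt(4 * math.pi ** 2 + delta ** 2)

    def test_nonpositive_amplitudes_rejected(self):
        with pytest.raises(ValidationError):
            damping_ratio_logdec([5.0, 0.0])

    def test_swing_floor_drops_noise_tail(self):
        devs = [-10.0, 5.0, -2.5, 1.25, -0.2, 0.15, -0.18]
        swings = swing_amplitudes(devs, floor_frac=0.1)
        # swings: 7.5, 3.75, 1.875, then 0.725, 0.175, 0.165 — the tail
        # falls below 10% of the max swing (0.75) and is excluded
        assert np.allclose(swings, [7.5, 3.75, 1.875])


class TestNaturalFrequency:
    def test_pure_damped_sinusoid_within_one_padded_bin(self):
        t = np.arange(0, 2.0, 0.02)
        beta = pitch_step_response(t, zeta=0.23, f_d_hz=4.7, amplitude_deg=20)
        f = natural_frequency_fft(t, beta)
        bin_width = 50.0 / (4 * t.size)
        assert abs(f - 4.7) <= bin_width + 1e-12

    def test_strongest_tone_wins(self):
        t = np.arange(0, 2.0, 0.02)
        y = 1.0 * np.sin(2 * np.pi * 2.0 * t) + 4.0 * np.sin(2 * np.pi * 5.0 * t)
        f = natural_frequency_fft(t, y)
        assert f == pytest.approx(5.0, abs=0.13)

    def test_dc_only_input_yields_null_with_warning(self):
        t = np.arange(0, 2.0, 0.02)
        with pytest.warns(UserWarning, match="no spectral peak"):
            assert natural_frequency_fft(t, np.full(t.size, 3.0)) is None

    def test_too_short_window_rejected(self):
        t = np.arange(0, 0.2, 0.02)
        with pytest.raises(ValidationError, match="bin width"):
            natural_frequency_fft(t, np.sin(40 * t))

    def test_undamped_correction(self):
        assert undamped_frequency(4.574, 0.23) == pytest.approx(4.70, abs=0.01)


class TestCrossCorrelation:
    def test_identity_correlates_at_zero_lag(self, rng):
        x = rng.normal(0, 1, 200)
        res = cross_correlation(x, x, dt=0.02, max_lag_s=0.5)
        assert res.best_lag_s == 0.0
        assert res.coefficient_at_best_lag == pytest.approx(1.0, abs=1e-12)

    def test_constructed_delay_recovered(self, rng):
        x = np.sin(np.linspace(0, 20, 400)) + 0.05 * rng.normal(size=400)
        k = 5  # 0.1 s at 50 Hz
        y = np.roll(x, k)
        res = cross_correlation(x, y, dt=0.02, max_lag_s=0.5)
        assert res.best_lag_s == pytest.approx(0.1, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        n, dt, max_lag = 120, 0.02, 0.3
        x = rng.normal(0, 1, n)
        y = -x + 0.1 * rng.normal(0, 1, n)
        res = cross_correlation(x, y, dt=dt, max_lag_s=max_lag)
        max_k = int(round(max_lag / dt))
        # O(n^2) double-loop Pearson oracle
        oracle = {}
        for k in range(-max_k, max_k + 1):
            pairs = [(x[i], y[i + k]) for i in range(n) if 0 <= i + k < n]
            xa = np.array([p[0] for p in pairs])
            ya = np.array([p[1] for p in pairs])
            oracle[k] = np.mean((xa - xa.mean()) * (ya - ya.mean())) / (xa.std() * ya.std())
        for k, coef in zip(np.round(res.lags_s / dt).astype(int), res.coefficients):
            assert coef == pytest.approx(oracle[k], abs=1e-10)
        assert res.coefficient_at_best_lag == pytest.approx(-1.0, abs=0.05)
        assert res.best_lag_s == 0.0

    def test_coefficients_bounded(self, rng):
        x = rng.normal(0, 1, 60)
        y = rng.normal(0, 1, 60)
        res = cross_correlation(x, y, dt=0.02, max_lag_s=0.25)
        assert np.nanmax(np.abs(res.coefficients)) <= 1.0 + 1e-12

    def test_zero_variance_yields_null(self):
        x = np.zeros(50)
        y = np.arange(50.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cross_correlation(x, y, dt=0.02, max_lag_s=0.2)
        assert res.coefficient_at_best_lag is None

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValidationError, match="half"):
            cross_correlation(np.ones(20), np.ones(20), dt=0.02, max_lag_s=0.5)


class TestOnSimulatedTransition:
    def test_pitch_classified_underdamped(self, std_analysis):
        est = std_analysis.oscillation
        assert est is not None
        assert 0.0 < est.damping_ratio < 1.0

    def test_theta_beta_correlation_negative(self, std_analysis):
        res = std_analysis.xcorr[("theta", "beta")]
        assert res.coefficient_at_best_lag < 0
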