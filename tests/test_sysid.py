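"""Cross-correlation estimator, double-exponential fit, and odor-modulation
comparison, checked against convolution and linearity oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorgaze.synthetic_data import (
    PlantParams,
    gen_white_noise_stimulus,
    simulate_steering_plant,
)
from odorgaze.sysid import (
    DoubleExpFit,
    ImpulseKernel,
    VelocityStimulus,
    WingbeatTrace,
    compare_odor_modulation,
    double_exp_kernel,
    double_exp_peak_time,
    estimate_impulse_response,
    fit_double_exponential,
)


def nrmse(estimate, reference):
    """RMS error normalised by the reference peak magnitude."""
    return np.sqrt(np.mean((estimate - reference) ** 2)) / np.max(np.abs(reference))


def make_pair(x, y):
    t = np.arange(len(x)) * 0.01
    return VelocityStimulus(t, x), WingbeatTrace(t, y)


class TestEstimator:
    def test_zero_response_gives_zero_kernel(self):
        x = gen_white_noise_stimulus(5.0, 0.01, seed=0)
        y = WingbeatTrace(x.time, np.zeros_like(x.time))
        k = estimate_impulse_response(x, y, max_lag=0.5)
        np.testing.assert_array_equal(k.g, 0.0)

    def test_shifted_copy_is_unit_at_shift_lag(self):
        x_arr = np.zeros(500)
        x_arr[10] = 1.0
        shift = 25
        y_arr = np.roll(x_arr, shift)
        x, y = make_pair(x_arr, y_arr)
        k = estimate_impulse_response(x, y, max_lag=1.0)
        expected = np.zeros_like(k.g)
        expected[shift] = 1.0
        np.testing.assert_allclose(k.g, expected, atol=1e-12)
        assert k.lag[shift] == pytest.approx(shift * 0.01)

    def test_recovers_kernel_on_noiseless_lti_data(self):
        plant = PlantParams(noise_sd=0.0)
        x = gen_white_noise_stimulus(120.0, 0.01, seed=0)
        y = simulate_steering_plant(x, plant)
        k = estimate_impulse_response(x, y, max_lag=1.0)
        g_true = double_exp_kernel(k.lag, plant.amp, plant.tau_rise, plant.tau_decay)
        assert nrmse(k.g, g_true) < 0.05

    def test_accuracy_improves_with_record_length(self):
        plant = PlantParams(noise_sd=0.0)
        errs = []
        for dur in (30.0, 480.0):
            x = gen_white_noise_stimulus(dur, 0.01, seed=3)
            y = simulate_steering_plant(x, plant)
            k = estimate_impulse_response(x, y, max_lag=1.0)
            g_true = double_exp_kernel(k.lag, plant.amp, plant.tau_rise, plant.tau_decay)
            errs.append(nrmse(k.g, g_true))
        assert errs[1] < errs[0]

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.floats(-3, 3, allow_nan=False),
        b=st.floats(-3, 3, allow_nan=False),
        seed=st.integers(0, 100),
    )
    def test_linearity_in_response(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x_arr = rng.choice([-3.75, 0.0, 3.75], size=400)
        if not np.any(x_arr):
            x_arr[0] = 3.75
        y1 = rng.normal(size=400)
        y2 = rng.normal(size=400)
        x, _ = make_pair(x_arr, y1)
        k1 = estimate_impulse_response(x, make_pair(x_arr, y1)[1], 0.5).g
        k2 = estimate_impulse_response(x, make_pair(x_arr, y2)[1], 0.5).g
        k12 = estimate_impulse_response(x, make_pair(x_arr, a * y1 + b * y2)[1], 0.5).g
        np.testing.assert_allclose(k12, a * k1 + b * k2, atol=1e-9)

    def test_zero_stimulus_rejected(self):
        x, y = make_pair(np.zeros(100), np.ones(100))
        with pytest.raises(ValueError, match="zero variance"):
            estimate_impulse_response(x, y, 0.5)

    def test_grid_mismatch_rejected(self):
        x = VelocityStimulus(np.arange(100) * 0.01, np.ones(100))
        y = WingbeatTrace(np.arange(100) * 0.02, np.ones(100))
        with pytest.raises(ValueError, match="time grid"):
            estimate_impulse_response(x, y, 0.5)


class TestDoubleExpFit:
    def test_exact_curve_recovered_within_one_percent(self, exact_kernel):
        fit = fit_double_exponential(exact_kernel)
        assert fit.converged
        assert fit.amp == pytest.approx(1.0, rel=0.01)
        assert fit.tau_rise == pytest.approx(0.02, rel=0.01)
        assert fit.tau_decay == pytest.approx(0.15, rel=0.01)
        t_star = double_exp_peak_time(0.02, 0.15)
        assert fit.peak_time == pytest.approx(t_star, abs=0.005)

    def test_peak_scales_linearly_with_kernel(self, exact_kernel):
        fit1 = fit_double_exponential(exact_kernel)
        scaled = ImpulseKernel(exact_kernel.lag, 1.4 * exact_kernel.g)
        fit2 = fit_double_exponential(scaled)
        assert fit2.peak_amplitude == pytest.approx(1.4 * fit1.peak_amplitude, rel=1e-6)
        assert fit2.tau_rise == pytest.approx(fit1.tau_rise, rel=1e-6)
        assert fit2.tau_decay == pytest.approx(fit1.tau_decay, rel=1e-6)

    def test_peak_invariant_to_lag_resolution(self):
        peaks = []
        for dt in (0.01, 0.02):
            lag = np.arange(0, 1.0 + 1e-9, dt)
            kernel = ImpulseKernel(lag, double_exp_kernel(lag, 1.0, 0.02, 0.15))
            peaks.append(fit_double_exponential(kernel).peak_amplitude)
        assert abs(peaks[1] - peaks[0]) / peaks[0] < 0.02

    def test_median_peak_error_at_fixture_snr(self):
        """100 noisy replicates at the default SNR: median |peak error| < 10%."""
        plant = PlantParams()
        true_peak = double_exp_kernel(
            double_exp_peak_time(plant.tau_rise, plant.tau_decay),
            plant.amp, plant.tau_rise, plant.tau_decay,
        )
        errors = []
        for seed in range(100):
            x = gen_white_noise_stimulus(60.0, 0.01, seed=seed)
            y = simulate_steering_plant(x, plant, seed=10_000 + seed)
            fit = fit_double_exponential(estimate_impulse_response(x, y, 1.0))
            errors.append(abs(fit.peak_amplitude - true_peak) / true_peak)
        assert np.median(errors) < 0.10

    def test_short_kernel_rejected(self):
        lag = np.arange(5) * 0.01
        with pytest.raises(ValueError, match="10 lags"):
            fit_double_exponential(ImpulseKernel(lag, np.ones(5)))


class TestOdorModulation:
    @staticmethod
    def _fits(peaks):
        return [DoubleExpFit(1.0, 0.02, 0.15, p, 0.05, 0.0) for p in peaks]

    def test_exact_gain_gives_exact_percent_change(self):
        water = self._fits([1.0, 2.0, 3.0, 4.0, 5.0])
        odor = self._fits([1.4, 2.8, 4.2, 5.6, 7.0])
        res = compare_odor_modulation(water, odor)
        assert res.percent_change == pytest.approx(40.0)
        assert res.p_value < 0.05

    def test_identical_conditions_flagged_null(self):
        fits = self._fits([1.0, 2.0, 3.0])
        res = compare_odor_modulation(fits, self._fits([1.0, 2.0, 3.0]))
        assert res.percent_change == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_single_fly_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_odor_modulation(self._fits([1.0]), self._fits([1.4]))

    def test_percent_change_bias_small_at_default_snr(self):
        """Per-fly percent-change estimates are unbiased to < 5 points."""
        plant = PlantParams()
        changes = []
        for seed in range(100):
            xw = gen_white_noise_stimulus(60.0, 0.01, seed=2 * seed)
            xo = gen_white_noise_stimulus(60.0, 0.01, seed=2 * seed + 1)
            yw = simulate_steering_plant(xw, plant, odor_on=False, seed=50_000 + 2 * seed)
            yo = simulate_steering_plant(xo, plant, odor_on=True, seed=50_000 + 2 * seed + 1)
            pw = fit_double_exponential(estimate_impulse_response(xw, yw, 1.0)).peak_amplitude
            po = fit_double_exponential(estimate_impulse_response(xo, yo, 1.0)).peak_amplitude
            changes.append(100.0 * (po - pw) / pw)
        assert abs(np.mean(changes) - 40.0) < 5.0
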