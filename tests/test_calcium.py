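"""ΔF/F, epoch segmentation, rank-sum epoch statistics, odor-on/off paired
comparison, and QC exclusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorgaze.calcium import (
    DffTrace,
    EpochDesign,
    EpochResponse,
    RoiTrace,
    compute_dff,
    epoch_peaks,
    epoch_peaks_from_windows,
    odor_modulation_test,
    odor_on_off_test,
    qc_filter,
    rank_sum_test,
    trace_from_tiff,
)
from odorgaze.synthetic_data import CELL_MODELS, simulate_imaging_cohort


def flat_trace(n=1100, f0=100.0, rate=10.0, **kw):
    return RoiTrace(np.arange(n) / rate, np.full(n, f0), **kw)


def brute_force_u(a, b):
    """Rank-sum (Mann-Whitney U of sample a) by direct pair counting."""
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


class TestDff:
    def test_constant_trace_gives_zero(self):
        dff = compute_dff(flat_trace())
        np.testing.assert_allclose(dff.dff, 0.0, atol=1e-12)
        assert dff.f0 == pytest.approx(100.0)

    def test_doubling_gives_unity(self):
        tr = flat_trace()
        tr.F[600:700] = 200.0
        dff = compute_dff(tr, baseline_window=(0.0, 5.0))
        np.testing.assert_allclose(dff.dff[600:700], 1.0)

    def test_baseline_default_is_final_rest_seconds(self, default_design):
        tr = flat_trace()
        tr.F[:50] = 500.0  # early rest, outside the final-5-s baseline window
        dff = compute_dff(tr, design=default_design)
        assert dff.f0 == pytest.approx(100.0)

    def test_too_few_baseline_frames_rejected(self):
        tr = flat_trace(n=100)
        with pytest.raises(ValueError, match="3 frames"):
            compute_dff(tr, baseline_window=(0.0, 0.15))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(gain=st.floats(0.1, 50.0), seed=st.integers(0, 20))
    def test_invariant_to_multiplicative_gain(self, gain, seed):
        rng = np.random.default_rng(seed)
        F = 100.0 + rng.uniform(0, 50, 200)
        t = np.arange(200) / 10.0
        d1 = compute_dff(RoiTrace(t, F), baseline_window=(0, 5))
        d2 = compute_dff(RoiTrace(t, gain * F), baseline_window=(0, 5))
        np.testing.assert_allclose(d1.dff, d2.dff, atol=1e-9)


class TestEpochPeaks:
    def test_zero_dff_gives_zero_peaks(self, default_design):
        dff = compute_dff(flat_trace(), design=default_design)
        np.testing.assert_array_equal(epoch_peaks(dff, default_design).peaks, 0.0)

    def test_single_spike_lands_in_its_epoch(self, default_design):
        tr = flat_trace()
        onset3 = default_design.motion_onset(3)
        idx = int(onset3 * 10) + 20
        tr.F[idx] = 180.0
        peaks = epoch_peaks(compute_dff(tr, design=default_design), default_design).peaks
        np.testing.assert_allclose(peaks, [0, 0, 0.8, 0, 0], atol=1e-12)

    def test_permutation_equivariance(self, default_design):
        rng = np.random.default_rng(3)
        tr = flat_trace()
        tr.F += rng.uniform(0, 30, tr.F.size)
        dff = compute_dff(tr, design=default_design)
        windows = default_design.motion_windows()
        base = epoch_peaks_from_windows(dff, windows)
        order = [3, 0, 4, 1, 2]
        shuffled = epoch_peaks_from_windows(dff, [windows[i] for i in order])
        np.testing.assert_array_equal(shuffled, base[order])

    def test_lag_pad_captures_delayed_peak(self, default_design):
        tr = flat_trace()
        t1 = default_design.motion_onset(1) + default_design.motion_duration
        idx = int((t1 + 1.0) * 10)  # 1 s after motion offset, inside the pad
        tr.F[idx] = 150.0
        peaks = epoch_peaks(compute_dff(tr, design=default_design), default_design,
                            lag_pad=2.0).peaks
        assert peaks[0] == pytest.approx(0.5)


class TestRankSumStatistics:
    def test_fully_separated_13v13_equals_enumerated_extreme(self):
        rng = np.random.default_rng(0)
        e1 = rng.uniform(0.5, 1.0, 13)
        e2 = rng.uniform(1.5, 2.0, 13)  # strictly greater, every pair
        u, p = rank_sum_test(e1, e2)
        assert u == brute_force_u(e1, e2) == 0.0
        assert p < 0.001
        u_rev, _ = rank_sum_test(e2, e1)
        assert u_rev == brute_force_u(e2, e1) == 169.0

    def test_identical_epochs_give_p_one(self):
        responses = [EpochResponse(np.ones(5), fly_id=f"f{i}") for i in range(6)]
        df = odor_modulation_test(responses)
        assert (df["p_ranksum"] == 1.0).all()
        assert (df["p_signed_rank"] == 1.0).all()

    def test_hx_cohort_epoch2_significant_only(self, default_design):
        traces = simulate_imaging_cohort(CELL_MODELS["Hx"], n_flies=13, seed=3)
        responses = [
            epoch_peaks(compute_dff(t, design=default_design), default_design,
                        fly_id=t.roi_id)
            for t in traces
        ]
        assert all(r.peaks[1] > r.peaks[0] for r in responses)
        df = odor_modulation_test(responses).set_index("epoch")
        assert df.loc[2, "p_ranksum"] < 0.05
        assert df.loc[2, "mean_delta"] > 0


class TestOdorOnOff:
    @staticmethod
    def _dff(values, rate=10.0):
        values = np.asarray(values, dtype=float)
        return DffTrace(np.arange(values.size) / rate, values, f0=100.0)

    def test_identical_windows_null(self):
        d = self._dff(np.tile([0.1, 0.2], 50))
        res = odor_on_off_test([d, d], on_window=(0, 5), off_window=(5, 10))
        assert res["p_value"] == 1.0 and res["degenerate"]

    def test_tdc2_on_exceeds_off_in_every_fly(self, default_design):
        from odorgaze.synthetic_data import VisualStimulus

        traces = simulate_imaging_cohort(
            CELL_MODELS["Tdc2"], n_flies=6, stimulus=VisualStimulus(kind="none"), seed=4
        )
        dffs = [compute_dff(t, design=default_design) for t in traces]
        on = default_design.odor_window()
        off = (on[0] - 10.0, on[0])
        res = odor_on_off_test(dffs, on_window=on, off_window=off)
        assert np.all(res["on"] > res["off"])
        assert res["p_value"] < 0.005

    def test_misplaced_off_window_kills_the_effect(self, default_design):
        from odorgaze.synthetic_data import VisualStimulus

        traces = simulate_imaging_cohort(
            CELL_MODELS["Tdc2"], n_flies=6, stimulus=VisualStimulus(kind="none"), seed=4
        )
        dffs = [compute_dff(t, design=default_design) for t in traces]
        on0, on1 = default_design.odor_window()
        # "off" window mistakenly placed inside the pulse: difference ~ 0
        res = odor_on_off_test(dffs, on_window=(on0 + 2, on1), off_window=(on0 + 2, on1))
        assert abs(np.mean(res["on"] - res["off"])) < 1e-9
        assert res["p_value"] > 0.05


class TestQcFilter:
    def test_clean_fixture_included(self, default_design):
        traces = simulate_imaging_cohort(CELL_MODELS["Hx"], n_flies=3, seed=5)
        included, excluded = qc_filter(traces, default_design)
        assert len(included) == 3 and not excluded

    def test_linear_bleaching_excluded(self):
        design = EpochDesign(n_epochs=2)
        n = int(design.total_duration * 10)
        t = np.arange(n) / 10.0
        F = 100.0 * (1.0 - 0.5 * t / 60.0)  # 50% per minute decay
        tr = RoiTrace(t, F)
        _, excluded = qc_filter([tr], design)
        assert excluded and excluded[0][1] == "bleaching"

    def test_flat_noise_trace_excluded_for_responsiveness(self, default_design):
        rng = np.random.default_rng(6)
        n = int(default_design.total_duration * 10)
        tr = RoiTrace(np.arange(n) / 10.0, 100.0 + rng.normal(0, 3.0, n))
        _, excluded = qc_filter([tr], default_design)
        assert excluded and excluded[0][1] == "responsiveness"

    def test_movement_jumps_excluded(self, default_design):
        n = int(default_design.total_duration * 10)
        F = np.full(n, 100.0)
        F[::3] = 250.0  # a third of frames jump by >50%
        tr = RoiTrace(np.arange(n) / 10.0, F)
        _, excluded = qc_filter([tr], default_design)
        assert excluded and excluded[0][1] == "movement"


class TestTiffIngestion:
    def test_rectangular_roi_mean_trace(self, tmp_path):
        import tifffile

        rng = np.random.default_rng(7)
        stack = rng.uniform(50, 150, size=(20, 8, 8)).astype(np.float32)
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, stack)
        tr = trace_from_tiff(path, roi=(2, 5, 1, 4), frame_rate=10.0)
        expected = stack[:, 2:5, 1:4].mean(axis=(1, 2))
        np.testing.assert_allclose(tr.F, expected, rtol=1e-6)
        assert tr.time[1] - tr.time[0] == pytest.approx(0.1)
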