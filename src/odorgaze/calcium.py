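"""ΔF/F extraction, epoch segmentation, and odor-pairing statistics for
ROI calcium-imaging traces.

The pairing protocol presents repeated 10-s epochs of wide-field motion
separated by rest periods; one motion epoch (the second, by default) is
accompanied by an odor pulse.  Analysis proceeds from raw fluorescence to
ΔF/F against a pre-stimulus baseline, takes the peak ΔF/F within each
motion epoch (padded for indicator decay), and compares epoch 1 against
every later epoch with a rank-sum test across flies.  Odor-only
experiments (no motion) are analysed as a paired odor-off vs odor-on
window comparison.  A QC filter excludes preparations with excessive
movement artifact, photobleaching, or no repeatable response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RoiTrace",
    "DffTrace",
    "EpochDesign",
    "EpochResponse",
    "QcThresholds",
    "compute_dff",
    "epoch_peaks",
    "epoch_peaks_from_windows",
    "rank_sum_test",
    "odor_modulation_test",
    "odor_on_off_test",
    "qc_filter",
    "trace_from_tiff",
]


@dataclass
class RoiTrace:
    """Raw fluorescence of one ROI on the imaging frame clock (8-11 Hz)."""

    time: np.ndarray
    F: np.ndarray
    roi_id: str = "roi0"
    cell_type: str = "Hx"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != self.time.shape:
            raise ValueError("F and time must have matching shape")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.F <= 0):
            raise ValueError("fluorescence must be strictly positive")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass
class DffTrace:
    time: np.ndarray
    dff: np.ndarray
    f0: float
    roi_id: str = "roi0"
    cell_type: str = "Hx"


@dataclass(frozen=True)
class EpochDesign:
    """Epoch schedule: initial rest, then n_epochs x (motion + rest).

    The odor pulse coincides with the motion period of
    ``odor_epoch_index`` (1-based).
    """

    n_epochs: int = 5
    motion_duration: float = 10.0
    rest_duration: float = 10.0
    odor_epoch_index: int = 2
    odor_duration: float = 10.0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if min(self.motion_duration, self.rest_duration, self.odor_duration) <= 0:
            raise ValueError("durations must be positive")
        if not 1 <= self.odor_epoch_index <= self.n_epochs:
            raise ValueError("odor_epoch_index must lie in [1, n_epochs]")

    def motion_onset(self, k: int) -> float:
        """Start time of 1-based motion epoch ``k``."""
        return self.rest_duration + (k - 1) * (self.motion_duration + self.rest_duration)

    def motion_windows(self) -> list[tuple[float, float]]:
        return [
            (self.motion_onset(k), self.motion_onset(k) + self.motion_duration)
            for k in range(1, self.n_epochs + 1)
        ]

    def odor_window(self) -> tuple[float, float]:
        t0 = self.motion_onset(self.odor_epoch_index)
        return (t0, t0 + self.odor_duration)

    @property
    def total_duration(self) -> float:
        return self.rest_duration + self.n_epochs * (
            self.motion_duration + self.rest_duration
        )


@dataclass
class EpochResponse:
    """Per-epoch peak ΔF/F for one fly / ROI."""

    peaks: np.ndarray
    fly_id: str = "fly0"
    cell_type: str = "Hx"

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float)


def compute_dff(
    trace: RoiTrace,
    baseline_window: tuple[float, float] | None = None,
    design: EpochDesign | None = None,
    method: str = "window",
    percentile: float = 10.0,
    percentile_window: float = 30.0,
) -> DffTrace:
    """ΔF/F = (F - F0)/F0 against a pre-stimulus baseline.

    By default F0 is the mean fluorescence over the final 5 s of the
    initial rest period (from ``design``; or the explicit
    ``baseline_window``; or the first 5 s when neither is given).  A
    rolling-percentile baseline is available via ``method='percentile'``
    for drifting recordings; it divides by a time-varying F0 and reports
    its median as ``f0``.
    """
    if method == "percentile":
        half = percentile_window / 2.0
        f0_t = np.array(
            [
                np.percentile(
                    trace.F[(trace.time >= t - half) & (trace.time <= t + half)],
                    percentile,
                )
                for t in trace.time
            ]
        )
        if np.any(f0_t <= 0):
            raise ValueError("rolling baseline is non-positive")
        dff = (trace.F - f0_t) / f0_t
        return DffTrace(trace.time, dff, float(np.median(f0_t)), trace.roi_id, trace.cell_type)
    if method != "window":
        raise ValueError(f"unknown baseline method {method!r}")

    if baseline_window is None:
        if design is not None:
            t1 = design.rest_duration
            t0 = max(0.0, t1 - 5.0)
        else:
            t0, t1 = float(trace.time[0]), float(trace.time[0]) + 5.0
        baseline_window = (t0, t1)
    t0, t1 = baseline_window
    mask = (trace.time >= t0) & (trace.time < t1)
    if np.count_nonzero(mask) < 3:
        raise ValueError("baseline window must contain at least 3 frames")
    f0 = float(np.mean(trace.F[mask]))
    if f0 <= 0:
        raise ValueError("baseline F0 must be positive")
    return DffTrace(trace.time, (trace.F - f0) / f0, f0, trace.roi_id, trace.cell_type)


def epoch_peaks_from_windows(
    dff: DffTrace, windows: Sequence[tuple[float, float]], lag_pad: float = 2.0
) -> np.ndarray:
    """Max ΔF/F within each [start, end + lag_pad) window."""
    peaks = np.empty(len(windows))
    for i, (t0, t1) in enumerate(windows):
        mask = (dff.time >= t0) & (dff.time < t1 + lag_pad)
        peaks[i] = float(np.max(dff.dff[mask])) if mask.any() else float("nan")
    return peaks


def epoch_peaks(
    dff: DffTrace,
    design: EpochDesign,
    lag_pad: float = 2.0,
    fly_id: str | None = None,
) -> EpochResponse:
    """Peak ΔF/F in each motion epoch; lag_pad admits indicator-delayed peaks."""
    peaks = epoch_peaks_from_windows(dff, design.motion_windows(), lag_pad)
    return EpochResponse(peaks, fly_id or dff.roi_id, dff.cell_type)


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns the U statistic for sample ``a`` and the p-value (exact for
    small tie-free samples, normal approximation otherwise).  Fully tied
    data returns p = 1 rather than a divide-by-zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def odor_modulation_test(responses: Sequence[EpochResponse]) -> pd.DataFrame:
    """Epoch-1 vs epoch-k comparison of peak responses across flies.

    For every epoch k >= 2 the epoch-1 peaks of all flies are compared
    against the epoch-k peaks with a two-sided rank-sum test (as in the
    between-epoch cohort comparison) and, since the same flies contribute
    to both epochs, the paired Wilcoxon signed-rank p-value is reported
    alongside.  Per-fly deltas (epoch k minus epoch 1) are included for
    plotting.
    """
    if not responses:
        raise ValueError("need at least one response")
    peaks = np.vstack([r.peaks for r in responses])
    n_epochs = peaks.shape[1]
    rows = []
    for k in range(1, n_epochs):
        e1, ek = peaks[:, 0], peaks[:, k]
        u, p = rank_sum_test(e1, ek)
        deltas = ek - e1
        if np.allclose(deltas, 0.0):
            p_signed = 1.0
        else:
            try:
                p_signed = float(stats.wilcoxon(ek, e1).pvalue)
            except ValueError:
                p_signed = float("nan")
        rows.append(
            {
                "epoch": k + 1,
                "u_statistic": u,
                "p_ranksum": p,
                "p_signed_rank": p_signed,
                "mean_delta": float(np.mean(deltas)),
                "deltas": deltas,
            }
        )
    return pd.DataFrame(rows)


def odor_on_off_test(
    dffs: Sequence[DffTrace],
    on_window: tuple[float, float],
    off_window: tuple[float, float],
    statistic: str = "max",
) -> dict:
    """Paired odor-on vs odor-off comparison across flies.

    Each fly contributes one ``max`` (or ``mean``) ΔF/F per window; the
    two are compared with a two-tailed paired t-test.
    """
    fn = {"max": np.max, "mean": np.mean}[statistic]
    on_vals, off_vals = [], []
    for d in dffs:
        m_on = (d.time >= on_window[0]) & (d.time < on_window[1])
        m_off = (d.time >= off_window[0]) & (d.time < off_window[1])
        if not (m_on.any() and m_off.any()):
            raise ValueError("window contains no frames")
        on_vals.append(float(fn(d.dff[m_on])))
        off_vals.append(float(fn(d.dff[m_off])))
    on_vals = np.array(on_vals)
    off_vals = np.array(off_vals)
    diffs = on_vals - off_vals
    if np.allclose(diffs, diffs[0]) and np.isclose(diffs[0], 0.0):
        t, p, degenerate = 0.0, 1.0, True
    else:
        t, p = stats.ttest_rel(on_vals, off_vals)
        t, p, degenerate = float(t), float(p), False
    return {
        "on": on_vals,
        "off": off_vals,
        "t_statistic": t,
        "p_value": p,
        "n_flies": len(dffs),
        "degenerate": degenerate,
    }


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds.  These defaults are package conventions, not
    published values, and are echoed into every QC report."""

    jump_frac: float = 0.5          # frame-to-frame |dF|/F counted as a movement jump
    max_jump_frame_frac: float = 0.05  # tolerated fraction of jump frames
    max_bleach_pct_per_min: float = 20.0  # tolerated linear decay of F
    response_k: float = 2.0         # epoch peak must exceed k x baseline noise SD
    min_responsive_epochs: int = 2


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def qc_filter(
    traces: Sequence[RoiTrace],
    design: EpochDesign,
    thresholds: QcThresholds | None = None,
    lag_pad: float = 2.0,
) -> tuple[list[RoiTrace], list[tuple[RoiTrace, str]]]:
    """Partition traces into (included, excluded-with-reason).

    Three checks, applied in order; the first failure names the reason:

    - ``movement``: fraction of frames whose frame-to-frame fractional
      change exceeds ``jump_frac`` is above ``max_jump_frame_frac``.
    - ``bleaching``: a linear fit of F against time decays faster than
      ``max_bleach_pct_per_min`` (percent of the fitted initial level).
    - ``responsiveness``: fewer than ``min_responsive_epochs`` motion
      epochs whose peak of the 1-s-smoothed ΔF/F exceeds ``response_k``
      baseline-noise SDs (smoothing keeps single noise excursions from
      counting as responses).
    """
    thr = thresholds or QcThresholds()
    included: list[RoiTrace] = []
    excluded: list[tuple[RoiTrace, str]] = []
    for trace in traces:
        jumps = np.abs(np.diff(trace.F)) / trace.F[:-1]
        if np.mean(jumps > thr.jump_frac) > thr.max_jump_frame_frac:
            excluded.append((trace, "movement"))
            continue
        slope, intercept = np.polyfit(trace.time, trace.F, 1)
        if intercept > 0 and -slope * 60.0 / intercept * 100.0 > thr.max_bleach_pct_per_min:
            excluded.append((trace, "bleaching"))
            continue
        dff = compute_dff(trace, design=design)
        t1 = design.rest_duration
        base_mask = (dff.time >= max(0.0, t1 - 5.0)) & (dff.time < t1)
        noise_sd = float(np.std(dff.dff[base_mask], ddof=1))
        width = max(1, int(round(1.0 / trace.dt)))
        smooth = _smooth(dff.dff, width)
        smooth_dff = DffTrace(dff.time, smooth, dff.f0, dff.roi_id, dff.cell_type)
        peaks = epoch_peaks_from_windows(smooth_dff, design.motion_windows(), lag_pad)
        n_resp = int(np.sum(peaks > thr.response_k * max(noise_sd, 1e-12)))
        if n_resp < thr.min_responsive_epochs:
            excluded.append((trace, "responsiveness"))
            continue
        included.append(trace)
    return included, excluded


def trace_from_tiff(
    path,
    roi: tuple[int, int, int, int],
    frame_rate: float | None = None,
    frame_times: np.ndarray | None = None,
    roi_id: str = "roi0",
    cell_type: str = "Hx",
) -> RoiTrace:
    """Mean-ROI fluorescence trace from a multi-page TIFF stack.

    ``roi`` is (row0, row1, col0, col1), 0-based half-open.  Frame times
    come from ``frame_times`` (e.g. recorded sync pulses, one per
    completed frame) or a nominal ``frame_rate``.
    """
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    r0, r1, c0, c1 = roi
    F = stack[:, r0:r1, c0:c1].mean(axis=(1, 2)).astype(float)
    if frame_times is not None:
        time = np.asarray(frame_times, dtype=float)
    elif frame_rate is not None:
        time = np.arange(F.size) / frame_rate
    else:
        raise ValueError("provide frame_times or frame_rate")
    return RoiTrace(time=time, F=F, roi_id=roi_id, cell_type=cell_type)
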