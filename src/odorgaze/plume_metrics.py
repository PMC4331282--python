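"""Odor-plume tracking metrics from heading traces of magnetically tethered flies.

A fly free to rotate in yaw orients relative to a narrow odor plume at a
fixed azimuth.  Tracking behaviour is split into three phases: *detection*
(ever orienting within ±threshold of the plume for a minimum dwell),
*acquisition* (time spent in the plume during the first 10 s), and
*continuous tracking* (time in the plume during the final 10 s).  Group
comparisons use a chi-square test on detection proportions and
two-sample tests on the time metrics among detected flies only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "HeadingTrace",
    "PlumeMetrics",
    "GroupComparison",
    "angular_distance",
    "signed_angular_diff",
    "wrap_degrees",
    "detect_plume",
    "time_in_plume",
    "compute_plume_metrics",
    "summarize_plume_tracking",
]

DEFAULT_THRESHOLD_DEG = 10.0
DEFAULT_MIN_DWELL_S = 0.5
DEFAULT_WINDOW_S = 10.0


def wrap_degrees(angle):
    """Wrap angles into [0, 360)."""
    return np.asarray(angle, dtype=float) % 360.0


def signed_angular_diff(a, b):
    """Signed shortest rotation from ``b`` to ``a``, in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(d == -180.0, 180.0, d)


def angular_distance(a, b):
    """Shortest arc between two angles, in [0, 180]."""
    return np.abs(signed_angular_diff(a, b))


@dataclass
class HeadingTrace:
    """Wrapped heading trajectory of one fly, with its plume azimuth."""

    time: np.ndarray
    heading: np.ndarray
    plume_azimuth: float = 180.0
    fly_id: str = "fly0"
    group: str = "control"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.heading = wrap_degrees(self.heading)
        if self.heading.shape != self.time.shape:
            raise ValueError("heading and time must have matching shape")
        if self.time.size < 2:
            raise ValueError("need at least 2 samples")
        steps = np.diff(self.time)
        self.dt = float(steps[0])
        if self.dt <= 0 or not np.allclose(steps, self.dt, rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform and increasing")

    @property
    def duration(self) -> float:
        return float(self.time.size * self.dt)

    def in_plume(self, threshold: float = DEFAULT_THRESHOLD_DEG) -> np.ndarray:
        return angular_distance(self.heading, self.plume_azimuth) <= threshold


@dataclass
class PlumeMetrics:
    fly_id: str
    group: str
    detected: bool
    acquisition_time: float
    tracking_time: float
    total_time_in_plume: float


@dataclass
class GroupComparison:
    detection: dict
    chi2_statistic: float | None
    chi2_p: float | None
    time_metrics: dict
    pairwise: list = field(default_factory=list)


def detect_plume(
    trace: HeadingTrace,
    threshold: float = DEFAULT_THRESHOLD_DEG,
    min_dwell: float = DEFAULT_MIN_DWELL_S,
) -> bool:
    """True iff the fly dwells within ±threshold of the plume for >= min_dwell.

    The dwell is a contiguous run of in-plume samples anywhere in the
    trial; a single-sample fly-through at coarse sampling does not count.
    """
    inside = trace.in_plume(threshold)
    if not inside.any():
        return False
    # length of the longest run of True samples
    padded = np.concatenate([[0], inside.astype(int), [0]])
    edges = np.flatnonzero(np.diff(padded))
    run_lengths = edges[1::2] - edges[0::2]
    return bool(run_lengths.max() * trace.dt >= min_dwell)


def time_in_plume(
    trace: HeadingTrace,
    window: tuple[float, float],
    threshold: float = DEFAULT_THRESHOLD_DEG,
) -> float:
    """Time within ±threshold of the plume over the half-open window [t0, t1).

    Computed as dt times the count of in-plume samples in the window, so
    it is additive over disjoint windows and monotone in the threshold.
    """
    t0, t1 = window
    mask = (trace.time >= t0) & (trace.time < t1)
    inside = trace.in_plume(threshold)
    return float(np.count_nonzero(inside & mask) * trace.dt)


def compute_plume_metrics(
    trace: HeadingTrace,
    threshold: float = DEFAULT_THRESHOLD_DEG,
    min_dwell: float = DEFAULT_MIN_DWELL_S,
    window: float = DEFAULT_WINDOW_S,
) -> PlumeMetrics:
    """Detection plus acquisition (first window), tracking (final window),
    and whole-trial time-in-plume for a single fly."""
    T = trace.duration
    return PlumeMetrics(
        fly_id=trace.fly_id,
        group=trace.group,
        detected=detect_plume(trace, threshold, min_dwell),
        acquisition_time=time_in_plume(trace, (0.0, window), threshold),
        tracking_time=time_in_plume(trace, (T - window, T), threshold),
        total_time_in_plume=time_in_plume(trace, (0.0, T), threshold),
    )


def _mean_sem(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    n = values.size
    return {
        "mean": float(np.mean(values)) if n else float("nan"),
        "sem": float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "n": int(n),
    }


def summarize_plume_tracking(
    traces_by_group: Mapping[str, Sequence[HeadingTrace]],
    threshold: float = DEFAULT_THRESHOLD_DEG,
    min_dwell: float = DEFAULT_MIN_DWELL_S,
    window: float = DEFAULT_WINDOW_S,
    yates: bool = False,
) -> GroupComparison:
    """Group-level plume-tracking summary.

    Detection proportions are compared across groups by a chi-square test
    on the detected / not-detected counts (no continuity correction by
    default).  Acquisition, tracking, and total time metrics are computed
    among detected flies only — non-detecting flies are excluded before
    any time statistic — and compared pairwise between groups with
    unpaired two-tailed t-tests.  A single group yields no chi-square and
    no pairwise tests.
    """
    groups = list(traces_by_group)
    if not groups:
        raise ValueError("need at least one group")
    metrics: dict[str, list[PlumeMetrics]] = {}
    for name in groups:
        traces = list(traces_by_group[name])
        if not traces:
            raise ValueError(f"group {name!r} is empty")
        metrics[name] = [
            compute_plume_metrics(tr, threshold, min_dwell, window) for tr in traces
        ]

    detection = {}
    table = []
    for name in groups:
        ms = metrics[name]
        n_det = sum(m.detected for m in ms)
        detection[name] = {
            "n": len(ms),
            "n_detected": n_det,
            "proportion": n_det / len(ms),
        }
        table.append([n_det, len(ms) - n_det])

    chi2_stat = chi2_p = None
    if len(groups) > 1:
        tab = np.asarray(table)
        if np.any(tab.sum(axis=0) == 0):
            # every fly in every group has the same outcome: no difference
            chi2_stat, chi2_p = 0.0, 1.0
        else:
            res = stats.chi2_contingency(tab, correction=yates)
            chi2_stat, chi2_p = float(res.statistic), float(res.pvalue)

    fields = ("acquisition_time", "tracking_time", "total_time_in_plume")
    time_metrics: dict[str, dict] = {}
    detected_values: dict[str, dict[str, np.ndarray]] = {}
    for name in groups:
        det = [m for m in metrics[name] if m.detected]
        detected_values[name] = {
            f: np.array([getattr(m, f) for m in det]) for f in fields
        }
        time_metrics[name] = {f: _mean_sem(detected_values[name][f]) for f in fields}

    pairwise = []
    for a, b in itertools.combinations(groups, 2):
        for f in fields:
            va, vb = detected_values[a][f], detected_values[b][f]
            if va.size < 2 or vb.size < 2:
                continue
            t, p = stats.ttest_ind(va, vb)
            pairwise.append(
                {"metric": f, "group_a": a, "group_b": b,
                 "t_statistic": float(t), "p_value": float(p)}
            )

    return GroupComparison(
        detection=detection,
        chi2_statistic=chi2_stat,
        chi2_p=chi2_p,
        time_metrics=time_metrics,
        pairwise=pairwise,
    )
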