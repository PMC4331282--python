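"""White-noise system identification of the yaw optomotor steering plant.

A rigidly tethered fly steering in response to panoramic yaw motion is
treated as a causal linear time-invariant plant: the wingbeat-amplitude
difference ``y(t)`` (ΔWBA, proportional to yaw torque) is the convolution
of a spectrally broad displacement-impulse stimulus ``x(t)`` with an
impulse-response kernel ``g(t)``, plus noise.  Cross-correlating ``x``
with ``y`` and normalising by the stimulus power recovers ``g``; the
kernel is then summarised by a difference-of-exponentials fit

    g(t) = A * (exp(-t / tau_decay) - exp(-t / tau_rise)),   tau_decay > tau_rise,

whose peak amplitude is the per-fly measure of optomotor gain.  Pairing
an appetitive odor with the visual stimulus multiplies the gain; the
cohort-level comparison of fitted peak amplitudes (paired t-test and
percent change) quantifies that cross-modal modulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "VelocityStimulus",
    "WingbeatTrace",
    "ImpulseKernel",
    "DoubleExpFit",
    "OdorModulationResult",
    "double_exp_kernel",
    "double_exp_peak_time",
    "estimate_impulse_response",
    "fit_double_exponential",
    "compare_odor_modulation",
]

DEFAULT_PIXEL_STEP_DEG = 3.75  # one display pixel of panorama rotation


def _check_uniform(time: np.ndarray, name: str, min_samples: int = 1) -> float:
    time = np.asarray(time, dtype=float)
    if time.ndim != 1 or time.size < min_samples:
        raise ValueError(f"{name}: need a 1-D time grid with >= {min_samples} samples")
    if time.size == 1:
        return float("nan")  # single-sample record: step undefined until analysis
    steps = np.diff(time)
    dt = float(steps[0])
    if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise ValueError(f"{name}: time grid must be uniform and increasing")
    return dt


@dataclass
class VelocityStimulus:
    """Broadband sequence of signed panorama-displacement impulses.

    ``velocity_impulses`` holds the displacement (degrees) applied at each
    sample; a ternary sequence takes values in {-pixel_step, 0, +pixel_step}.
    """

    time: np.ndarray
    velocity_impulses: np.ndarray
    pixel_step: float = DEFAULT_PIXEL_STEP_DEG

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.velocity_impulses = np.asarray(self.velocity_impulses, dtype=float)
        if self.velocity_impulses.shape != self.time.shape:
            raise ValueError("stimulus and time grid must have matching shape")
        if not np.all(np.isfinite(self.velocity_impulses)):
            raise ValueError("stimulus contains non-finite values")
        self.dt = _check_uniform(self.time, "VelocityStimulus")
        if self.pixel_step <= 0:
            raise ValueError("pixel_step must be positive")


@dataclass
class WingbeatTrace:
    """ΔWBA steering trace paired with a stimulus, on the same clock."""

    time: np.ndarray
    dwba: np.ndarray
    condition: str = "water"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dwba = np.asarray(self.dwba, dtype=float)
        if self.dwba.shape != self.time.shape:
            raise ValueError("dwba and time grid must have matching shape")
        self.dt = _check_uniform(self.time, "WingbeatTrace")


@dataclass
class ImpulseKernel:
    """Estimated steering kernel ĝ(τ) on a uniform lag grid starting at 0.

    ``g`` is expressed per unit of stimulus displacement (ΔWBA a.u. per
    degree); multiply by ``pixel_step`` for the per-pixel convention.
    """

    lag: np.ndarray
    g: np.ndarray
    pixel_step: float = DEFAULT_PIXEL_STEP_DEG

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.g.shape != self.lag.shape:
            raise ValueError("kernel and lag grid must have matching shape")
        if abs(self.lag[0]) > 1e-12:
            raise ValueError("lag grid must start at 0")
        self.dt = _check_uniform(self.lag, "ImpulseKernel", min_samples=2)

    @property
    def g_per_pixel(self) -> np.ndarray:
        return self.g * self.pixel_step


@dataclass
class DoubleExpFit:
    """Difference-of-exponentials fit of an impulse-response kernel."""

    amp: float
    tau_rise: float
    tau_decay: float
    peak_amplitude: float
    peak_time: float
    rss: float
    converged: bool = True

    def curve(self, t: np.ndarray) -> np.ndarray:
        return double_exp_kernel(t, self.amp, self.tau_rise, self.tau_decay)


@dataclass
class OdorModulationResult:
    peaks_water: np.ndarray
    peaks_odor: np.ndarray
    percent_change: float
    t_statistic: float
    p_value: float
    n_flies: int
    degenerate: bool = False  # zero-variance paired differences

    def to_dict(self) -> dict:
        return {
            "n_flies": self.n_flies,
            "percent_change": self.percent_change,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "mean_peak_water": float(np.mean(self.peaks_water)),
            "mean_peak_odor": float(np.mean(self.peaks_odor)),
            "degenerate": self.degenerate,
        }


def double_exp_kernel(t, amp: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Causal biphasic kernel A*(exp(-t/tau_decay) - exp(-t/tau_rise)).

    Zero for t < 0.  ``tau_decay > tau_rise > 0`` makes the bracket
    non-negative, so the sign of ``amp`` is the sign of the response.
    """
    if not (tau_decay > tau_rise > 0):
        raise ValueError("require tau_decay > tau_rise > 0")
    t = np.asarray(t, dtype=float)
    out = amp * (np.exp(-t / tau_decay) - np.exp(-t / tau_rise))
    return np.where(t >= 0, out, 0.0)


def double_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form argmax of the difference-of-exponentials kernel."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def estimate_impulse_response(
    x: VelocityStimulus, y: WingbeatTrace, max_lag: float = 1.0
) -> ImpulseKernel:
    """Cross-correlation estimate ĝ(τ) = Σ_t x(t)·y(t+τ) / Σ_t x(t)².

    Only lags with full overlap contribute (no circular wrap); the
    normaliser is the stimulus power over the same overlap window, so a
    shifted copy of the stimulus yields exactly 1 at the shift lag.
    """
    if x.time.shape != y.time.shape or not np.allclose(x.time, y.time, atol=1e-9):
        raise ValueError("stimulus and response must share one time grid")
    xs = x.velocity_impulses
    ys = y.dwba
    n = xs.size
    dt = x.dt
    n_lags = int(round(max_lag / dt)) + 1
    if n_lags > n:
        raise ValueError("max_lag must be shorter than the record")
    if not np.any(xs != 0):
        raise ValueError("stimulus has zero variance; kernel is undefined")
    g = np.empty(n_lags)
    for k in range(n_lags):
        xk = xs[: n - k]
        den = float(xk @ xk)
        if den == 0.0:
            g[k] = 0.0
            continue
        g[k] = float(xk @ ys[k:]) / den
    return ImpulseKernel(lag=np.arange(n_lags) * dt, g=g, pixel_step=x.pixel_step)


def _profiled_residual(params: np.ndarray, t: np.ndarray, g: np.ndarray) -> np.ndarray:
    # params = (log tau_rise, log (tau_decay - tau_rise)); amplitude profiled out
    tau_r = np.exp(params[0])
    tau_d = tau_r + np.exp(params[1])
    basis = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    bb = float(basis @ basis)
    amp = float(basis @ g) / bb if bb > 0 else 0.0
    return amp * basis - g


def _profiled_amp(params: np.ndarray, t: np.ndarray, g: np.ndarray) -> float:
    tau_r = np.exp(params[0])
    tau_d = tau_r + np.exp(params[1])
    basis = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    bb = float(basis @ basis)
    return float(basis @ g) / bb if bb > 0 else 0.0


def fit_double_exponential(
    kernel: ImpulseKernel,
    init: tuple[float, float] | None = None,
    n_starts: int = 5,
) -> DoubleExpFit:
    """Least-squares double-exponential fit with deterministic multi-start.

    The amplitude enters the model linearly and is profiled out, so only
    the two time constants are optimised (as logs, which enforces
    ``tau_decay > tau_rise > 0`` by construction).  The fit is restarted
    from ``n_starts`` spread initial time constants (plus ``init`` when
    given) and the lowest-residual solution is kept.  ``peak_amplitude``
    and ``peak_time`` summarise the fitted curve, evaluated on a lag grid
    refined 4x relative to the kernel's.
    """
    t = kernel.lag
    g = kernel.g
    if t.size < 10:
        raise ValueError("kernel needs at least 10 lags for a stable fit")
    tmax = float(t[-1])
    starts = []
    if init is not None:
        tr0, td0 = init
        if td0 > tr0 > 0:
            starts.append((np.log(tr0), np.log(td0 - tr0)))
    rise_grid = np.geomspace(max(kernel.dt, 0.005), max(tmax / 5.0, 0.02), n_starts)
    for tr0 in rise_grid:
        starts.append((np.log(tr0), np.log(4.0 * tr0)))

    best = None
    for p0 in starts:
        try:
            sol = optimize.least_squares(
                _profiled_residual, np.asarray(p0), args=(t, g), method="trf", xtol=1e-12
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return DoubleExpFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)

    tau_r = float(np.exp(best.x[0]))
    tau_d = tau_r + float(np.exp(best.x[1]))
    amp = _profiled_amp(best.x, t, g)
    resid = _profiled_residual(best.x, t, g)
    rss = float(resid @ resid)
    fine = np.linspace(0.0, tmax, 4 * t.size)
    curve = double_exp_kernel(fine, amp, tau_r, tau_d)
    i = int(np.argmax(curve))
    return DoubleExpFit(
        amp=amp,
        tau_rise=tau_r,
        tau_decay=tau_d,
        peak_amplitude=float(curve[i]),
        peak_time=float(fine[i]),
        rss=rss,
        converged=True,
    )


def compare_odor_modulation(
    fits_water: Sequence[DoubleExpFit], fits_odor: Sequence[DoubleExpFit]
) -> OdorModulationResult:
    """Paired comparison of fitted kernel peak amplitudes across flies.

    Reports the percent change of the cohort mean odor peak relative to
    the mean water peak and a two-tailed paired t-test.  Matched order is
    assumed (element i of each list is the same fly).
    """
    if len(fits_water) != len(fits_odor):
        raise ValueError("water and odor fit lists must be matched by fly")
    n = len(fits_water)
    if n < 2:
        raise ValueError("need at least 2 flies for a paired comparison")
    pw = np.array([f.peak_amplitude for f in fits_water], dtype=float)
    po = np.array([f.peak_amplitude for f in fits_odor], dtype=float)
    mean_w = float(np.mean(pw))
    if mean_w == 0.0:
        raise ValueError("mean water peak is zero; percent change undefined")
    percent = 100.0 * (float(np.mean(po)) - mean_w) / mean_w
    diffs = po - pw
    if np.allclose(diffs, diffs[0]) and np.isclose(diffs[0], 0.0):
        return OdorModulationResult(pw, po, percent, 0.0, 1.0, n, degenerate=True)
    tstat, p = stats.ttest_rel(po, pw)
    return OdorModulationResult(pw, po, percent, float(tstat), float(p), n)
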