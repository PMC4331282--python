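"""Visual tuning analyses for wide-field motion-sensitive neurons.

Covers the four standard characterisations of a lobula-plate tangential
cell: the azimuthal receptive field (Gaussian fit to bar-sweep
responses, width reported as FWHM), the bar-width response curve
(monotonicity by Spearman rank correlation), direction tuning over the
eight arena directions (normalised to the largest response), and the
temporal-frequency optimum of grating responses (log-Gaussian fit in
log2-frequency, with an argmax fallback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TuningCurve",
    "RFFit",
    "TfFit",
    "curve_from_table",
    "fit_azimuthal_rf",
    "bar_width_curve",
    "direction_tuning",
    "temporal_frequency_optimum",
    "temporal_frequency",
    "gaussian_rf",
]

FOUR_LN2 = 4.0 * np.log(2.0)


def temporal_frequency(speed_deg_s: float, wavelength_deg: float) -> float:
    """Temporal frequency of a drifting grating: speed / wavelength (Hz)."""
    if wavelength_deg <= 0:
        raise ValueError("wavelength must be positive")
    return speed_deg_s / wavelength_deg


def gaussian_rf(az, center: float, fwhm: float, amplitude: float = 1.0, baseline: float = 0.0):
    """Gaussian receptive-field profile parameterised by its FWHM."""
    az = np.asarray(az, dtype=float)
    return baseline + amplitude * np.exp(-FOUR_LN2 * (az - center) ** 2 / fwhm**2)


@dataclass
class TuningCurve:
    """Mean ± SEM response per stimulus value across flies."""

    stimulus_values: np.ndarray
    mean_response: np.ndarray
    sem: np.ndarray
    n_flies: int
    kind: str = ""

    def __post_init__(self) -> None:
        self.stimulus_values = np.asarray(self.stimulus_values, dtype=float)
        self.mean_response = np.asarray(self.mean_response, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (
            self.stimulus_values.shape == self.mean_response.shape == self.sem.shape
        ):
            raise ValueError("curve fields must have matching shape")
        if np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")


@dataclass
class RFFit:
    center: float
    fwhm: float
    amplitude: float
    baseline: float
    rss: float
    converged: bool = True
    degenerate: bool = False


@dataclass
class TfFit:
    f_opt: float
    amplitude: float
    baseline: float
    logwidth_octaves: float
    rss: float
    converged: bool = True
    boundary: bool = False
    used_fallback: bool = False


def curve_from_table(df: pd.DataFrame, kind: str | None = None) -> TuningCurve:
    """Tidy table (fly_id, stimulus_kind, stimulus_value, peak_dff) -> curve."""
    if kind is not None:
        df = df[df["stimulus_kind"] == kind]
    if df.empty:
        raise ValueError("no rows for requested stimulus kind")
    grouped = df.groupby("stimulus_value")["peak_dff"]
    mean = grouped.mean()
    sem = grouped.sem().fillna(0.0)
    n_flies = int(df["fly_id"].nunique())
    return TuningCurve(
        stimulus_values=mean.index.to_numpy(dtype=float),
        mean_response=mean.to_numpy(),
        sem=sem.to_numpy(),
        n_flies=n_flies,
        kind=kind or "",
    )


def _profiled_gauss_fit(x: np.ndarray, y: np.ndarray, centers, widths):
    """Gaussian + offset least squares with the two linear parameters
    (amplitude, baseline) profiled out; multi-start over (center, width)."""

    def residual(p):
        c, logw = p
        w = np.exp(logw)
        basis = np.exp(-FOUR_LN2 * (x - c) ** 2 / w**2)
        design = np.column_stack([basis, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return design @ coef - y

    best = None
    for c0 in centers:
        for w0 in widths:
            try:
                sol = optimize.least_squares(
                    residual, np.array([c0, np.log(w0)]), method="trf", xtol=1e-12
                )
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return None
    c, logw = best.x
    w = float(np.exp(logw))
    basis = np.exp(-FOUR_LN2 * (x - c) ** 2 / w**2)
    design = np.column_stack([basis, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = design @ coef - y
    return float(c), w, float(coef[0]), float(coef[1]), float(resid @ resid), resid


def fit_azimuthal_rf(curve: TuningCurve) -> RFFit:
    """Gaussian receptive-field fit: response(az) = b + a*exp(-4ln2 (az-c)^2 / fwhm^2).

    Requires >= 5 azimuth samples.  A curve carrying no real peak (fitted
    amplitude indistinguishable from the residual noise) is returned with
    ``degenerate=True``: the FWHM of a flat profile is unidentifiable.
    """
    x = curve.stimulus_values
    y = curve.mean_response
    if x.size < 5:
        raise ValueError("need at least 5 azimuth samples")
    span = float(x.max() - x.min())
    centers = np.quantile(x, [0.2, 0.4, 0.6, 0.8])
    widths = [span / 8.0, span / 4.0, span / 2.0]
    out = _profiled_gauss_fit(x, y, centers, widths)
    if out is None:
        return RFFit(np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)
    c, w, amp, base, rss, resid = out
    resid_sd = float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0
    data_span = float(y.max() - y.min())
    degenerate = abs(amp) <= max(2.0 * resid_sd, 1e-3 * data_span, 1e-12)
    return RFFit(center=c, fwhm=abs(w), amplitude=amp, baseline=base, rss=rss,
                 degenerate=degenerate)


def bar_width_curve(
    df: pd.DataFrame, direction_column: str = "direction"
) -> dict[str, dict]:
    """Per-direction width-response curves with a monotonicity statistic.

    Expects a tidy table (fly_id, stimulus_value = bar width in degrees,
    peak_dff, and a direction column).  Returns, per direction, the mean
    ± SEM curve and the Spearman rank correlation of mean response
    against width (0 by convention when the means are constant).
    """
    out: dict[str, dict] = {}
    for direction, sub in df.groupby(direction_column):
        curve = curve_from_table(sub)
        if np.allclose(curve.mean_response, curve.mean_response[0]):
            rho, p = 0.0, 1.0
        else:
            rho, p = stats.spearmanr(curve.stimulus_values, curve.mean_response)
            rho, p = float(rho), float(p)
        out[str(direction)] = {"curve": curve, "spearman_rho": rho, "spearman_p": p}
    return out


def direction_tuning(df: pd.DataFrame) -> dict:
    """Direction tuning normalised to the largest mean response.

    Returns the normalised curve (max exactly 1), the preferred
    direction(s) — every direction tied at the maximum — and the raw
    maximum used for normalisation.  The output is scale-free: scaling
    all responses by any positive constant leaves it unchanged.
    """
    curve = curve_from_table(df)
    peak = float(np.max(curve.mean_response))
    if peak <= 0:
        raise ValueError("maximum mean response must be positive to normalise")
    norm = curve.mean_response / peak
    is_max = np.isclose(norm, 1.0, rtol=1e-9, atol=1e-12)
    preferred = curve.stimulus_values[is_max].tolist()
    normalized = TuningCurve(
        stimulus_values=curve.stimulus_values,
        mean_response=norm,
        sem=curve.sem / peak,
        n_flies=curve.n_flies,
        kind="direction",
    )
    return {"curve": normalized, "preferred": preferred, "raw_max": peak}


def temporal_frequency_optimum(curve: TuningCurve) -> TfFit:
    """Log-Gaussian temporal-frequency tuning fit.

    Fits response(f) = b + a*exp(-(log2 f - log2 f_opt)^2 / (2 w^2)) over
    the sampled frequencies (>= 4 required, log spacing recommended) and
    returns f_opt in Hz.  A fitted optimum outside the sampled range is
    flagged ``boundary``; if the fit fails outright the sampled argmax is
    returned with ``used_fallback=True``.
    """
    f = curve.stimulus_values
    y = curve.mean_response
    if f.size < 4:
        raise ValueError("need at least 4 sampled frequencies")
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    x = np.log2(f)
    # same profiled machinery; log-Gaussian sigma w relates to FWHM via 4ln2
    out = _profiled_gauss_fit(x, y, centers=x, widths=[0.5, 1.0, 2.0])
    if out is None or out[2] <= 0:
        i = int(np.argmax(y))
        return TfFit(
            f_opt=float(f[i]), amplitude=float(y[i]), baseline=0.0,
            logwidth_octaves=np.nan, rss=np.inf, converged=False, used_fallback=True,
            boundary=i in (0, f.size - 1),
        )
    c, w_fwhm, amp, base, rss, _ = out
    # _profiled_gauss_fit parameterises exp(-4ln2 dx^2 / w^2); convert to sigma
    sigma = w_fwhm / np.sqrt(8.0 * np.log(2.0))
    f_opt = float(2.0**c)
    boundary = not (f.min() <= f_opt <= f.max())
    return TfFit(
        f_opt=f_opt, amplitude=amp, baseline=base,
        logwidth_octaves=float(sigma), rss=rss, boundary=boundary,
    )
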