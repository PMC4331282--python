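"""Seeded synthetic datasets for the three experiment types.

Every analysis stage in this package can be exercised without raw
recordings: this module provides forward models for

- the **rigid-tether** preparation: a causal LTI steering plant driven by
  a ternary white-noise displacement stimulus, with a multiplicative gain
  increase on odor-paired trials;
- the **magnetic-tether** plume assay: circular heading dynamics with a
  binary odor-sensing cone, an odor-attraction pull, a visually damped
  slow turning bias, and a constant search rotation outside the plume —
  so genotypes with "detection and acquisition intact, sustained tracking
  broken" exist by construction;
- the **imaging** preparation: tuned visual drive (receptive field x
  direction x temporal frequency x bar width) passed through a
  single-exponential calcium-indicator filter, with odor-specific gain on
  designated cell types and direct odor drive for octopaminergic cells.

All generators are bit-reproducible under a fixed integer seed.  Their
default parameters define the fixture conditions the tests and the
acceptance analyses run under; they are package conventions chosen for
plausibility, not published measurements, except where a printed summary
value (the ~40% odor gain, the 50° receptive field, the 1 Hz optimum)
pins them down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .calcium import EpochDesign, RoiTrace
from .plume_metrics import HeadingTrace, signed_angular_diff
from .sysid import (
    DEFAULT_PIXEL_STEP_DEG,
    VelocityStimulus,
    WingbeatTrace,
    double_exp_kernel,
)
from .tuning import gaussian_rf, temporal_frequency

__all__ = [
    "PlantParams",
    "AgentProfile",
    "CellModel",
    "VisualStimulus",
    "RigidTrial",
    "PROFILES",
    "CELL_MODELS",
    "gen_white_noise_stimulus",
    "simulate_steering_plant",
    "simulate_rigid_cohort",
    "simulate_plume_flight",
    "simulate_plume_cohort",
    "simulate_roi_trace",
    "simulate_imaging_cohort",
    "simulate_tuning_responses",
    "visual_drive_weight",
]


def _spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


# ---------------------------------------------------------------------------
# rigid tether: steering plant
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantParams:
    """LTI steering-plant parameters.

    ``noise_sd`` defaults to 26.0 ΔWBA a.u., which puts the peak of the
    cross-correlation kernel estimate at a signal-to-noise ratio of ~5
    under the standard 60-s, 100-Hz, 3.75°-pixel acquisition (the
    estimator noise SD is noise_sd / sqrt(sum x^2) per lag).
    ``odor_gain`` = 1.4 encodes the ~40% odor-evoked increase in
    optomotor gain.
    """

    amp: float = 1.0  # ΔWBA a.u. per degree of displacement
    tau_rise: float = 0.02  # s
    tau_decay: float = 0.15  # s
    odor_gain: float = 1.4  # multiplicative on amp for odor trials
    noise_sd: float = 26.0  # ΔWBA a.u. additive white noise

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if self.odor_gain < 0:
            raise ValueError("odor_gain must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_white_noise_stimulus(
    duration: float,
    dt: float,
    pixel_step: float = DEFAULT_PIXEL_STEP_DEG,
    seed: int = 0,
    p_move: float = 0.5,
) -> VelocityStimulus:
    """Ternary white-noise displacement sequence.

    Each sample independently displaces the panorama by -1, 0, or +1
    pixel (probability ``p_move`` of a move, split evenly between signs),
    giving a zero-mean sequence whose power spectrum is flat up to the
    Nyquist frequency within sampling error.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if pixel_step <= 0:
        raise ValueError("pixel_step must be positive")
    if not 0 < p_move <= 1:
        raise ValueError("p_move must lie in (0, 1]")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    steps = rng.choice(
        [-1.0, 0.0, 1.0], size=n, p=[p_move / 2, 1 - p_move, p_move / 2]
    )
    return VelocityStimulus(
        time=np.arange(n) * dt, velocity_impulses=steps * pixel_step, pixel_step=pixel_step
    )


def simulate_steering_plant(
    stimulus: VelocityStimulus,
    plant: PlantParams,
    odor_on: bool = False,
    seed: int = 0,
    kernel_support: float = 1.0,
) -> WingbeatTrace:
    """ΔWBA response: stimulus convolved with the biphasic kernel plus noise.

    y(t) = (g * x)(t) + N(0, noise_sd), with g the causal
    difference-of-exponentials kernel; amplitude is scaled by
    ``odor_gain`` on odor trials.
    """
    dt = stimulus.dt
    if dt >= plant.tau_rise:
        raise ValueError(
            "stimulus sampling too coarse to resolve the plant kernel "
            f"(dt={dt} >= tau_rise={plant.tau_rise})"
        )
    amp = plant.amp * (plant.odor_gain if odor_on else 1.0)
    lags = np.arange(int(round(kernel_support / dt)) + 1) * dt
    g = double_exp_kernel(lags, amp, plant.tau_rise, plant.tau_decay)
    y = np.convolve(stimulus.velocity_impulses, g)[: stimulus.time.size]
    if plant.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, plant.noise_sd, size=y.size)
    return WingbeatTrace(
        time=stimulus.time, dwba=y, condition="odor" if odor_on else "water"
    )


@dataclass
class RigidTrial:
    """One fly's paired rigid-tether recordings (water and odor trials)."""

    fly_id: str
    stimulus_water: VelocityStimulus
    stimulus_odor: VelocityStimulus
    water: WingbeatTrace
    odor: WingbeatTrace


def simulate_rigid_cohort(
    n_flies: int = 15,
    plant: PlantParams | None = None,
    duration: float = 60.0,
    dt: float = 0.01,
    pixel_step: float = DEFAULT_PIXEL_STEP_DEG,
    seed: int = 0,
    fly_amp_cv: float = 0.15,
) -> list[RigidTrial]:
    """Paired odor/water trials for a cohort of simulated flies.

    Each fly draws its own plant amplitude from a mean-preserving
    lognormal (coefficient of variation ``fly_amp_cv``) shared between
    its two conditions, mimicking between-animal gain variability while
    keeping the within-fly odor contrast exactly ``odor_gain``.
    """
    plant = plant or PlantParams()
    trials = []
    for i, ss in enumerate(_spawn_seeds(seed, n_flies)):
        s_stim_w, s_stim_o, s_amp, s_noise_w, s_noise_o = [
            int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
        ]
        rng = np.random.default_rng(s_amp)
        sigma = math.sqrt(math.log(1.0 + fly_amp_cv**2))
        amp_i = plant.amp * rng.lognormal(-0.5 * sigma**2, sigma)
        plant_i = replace(plant, amp=amp_i)
        xw = gen_white_noise_stimulus(duration, dt, pixel_step, seed=s_stim_w)
        xo = gen_white_noise_stimulus(duration, dt, pixel_step, seed=s_stim_o)
        trials.append(
            RigidTrial(
                fly_id=f"fly{i:02d}",
                stimulus_water=xw,
                stimulus_odor=xo,
                water=simulate_steering_plant(xw, plant_i, odor_on=False, seed=s_noise_w),
                odor=simulate_steering_plant(xo, plant_i, odor_on=True, seed=s_noise_o),
            )
        )
    return trials


# ---------------------------------------------------------------------------
# magnetic tether: plume-tracking agent
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgentProfile:
    """Heading-dynamics parameters for one genotype.

    - ``attraction_gain`` (1/s): odor-driven pull of heading toward the
      plume azimuth, active only inside the sensing cone.
    - ``stabilization_gain`` (1/s): visual damping of the slow turning
      bias; setting it to 0 leaves the bias to random-walk, which is what
      breaks sustained tracking while sparing detection and acquisition.
    - ``heading_noise_sd`` (°/√s): fast white heading noise.
    - ``drift_drive_sd`` (°/s² per √s): white torque noise feeding the
      slow turning bias (double-integrated when undamped).
    - ``search_drift`` (°/s): constant rotation while the plume is not
      sensed, emulating circling search.
    """

    label: str = "control"
    attraction_gain: float = 3.0
    stabilization_gain: float = 5.0
    heading_noise_sd: float = 8.0
    drift_drive_sd: float = 0.5
    search_drift: float = 40.0

    def __post_init__(self) -> None:
        for name in ("attraction_gain", "stabilization_gain", "heading_noise_sd",
                     "drift_drive_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


PROFILES: dict[str, AgentProfile] = {
    "control": AgentProfile(label="control"),
    # visual stabilization gone, odor attraction spared: acquires but cannot hold
    "T4T5_blocked": AgentProfile(label="T4T5_blocked", stabilization_gain=0.0),
    "VMAT_rescue": AgentProfile(label="VMAT_rescue"),
    # aminergic-null: odor signalling broken, vision intact
    "d3VMAT": AgentProfile(label="d3VMAT", attraction_gain=0.0),
    "water": AgentProfile(label="water", attraction_gain=0.0),
}


def simulate_plume_flight(
    profile: AgentProfile,
    plume_azimuth: float = 180.0,
    duration: float = 40.0,
    dt: float = 0.02,
    seed: int = 0,
    theta0: float | None = None,
    sensing_cone_deg: float = 90.0,
    fly_id: str = "fly0",
    group: str | None = None,
) -> HeadingTrace:
    """Discrete-time circular heading dynamics in an odor plume.

    Per step: the slow turning bias ``b`` (°/s) integrates white torque
    noise and is exponentially damped at ``stabilization_gain``; the
    heading increment combines the attraction pull (active while the
    unsigned plume error is within half the sensing cone), the bias, the
    search rotation when the plume is not sensed, and fast white noise.
    Headings are wrapped to [0, 360) after each step, so trajectories are
    continuous across the wrap.  With all noise terms zero and the fly
    starting on the plume, the heading is a fixed point.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    theta = np.empty(n)
    th = rng.uniform(0.0, 360.0) if theta0 is None else float(theta0)
    u = 0.0  # torque-noise integrator (°/s²-ish state feeding the bias)
    b = 0.0  # slow turning bias, °/s
    damp = math.exp(-profile.stabilization_gain * dt)
    sq = math.sqrt(dt)
    half_cone = sensing_cone_deg / 2.0
    for i in range(n):
        theta[i] = th
        e = float(signed_angular_diff(th, plume_azimuth))
        sensing = abs(e) <= half_cone and profile.attraction_gain > 0
        u = u * damp + profile.drift_drive_sd * sq * rng.standard_normal()
        b = b * damp + dt * u
        dth = dt * (
            -profile.attraction_gain * e * sensing
            + b
            + (0.0 if sensing else profile.search_drift)
        ) + profile.heading_noise_sd * sq * rng.standard_normal()
        th = (th + dth) % 360.0
    return HeadingTrace(
        time=np.arange(n) * dt,
        heading=theta,
        plume_azimuth=plume_azimuth,
        fly_id=fly_id,
        group=group or profile.label,
    )


def simulate_plume_cohort(
    profile: AgentProfile,
    n_flies: int = 25,
    plume_azimuth: float = 180.0,
    duration: float = 40.0,
    dt: float = 0.02,
    seed: int = 0,
    group: str | None = None,
) -> list[HeadingTrace]:
    seeds = _spawn_seeds(seed, n_flies)
    return [
        simulate_plume_flight(
            profile,
            plume_azimuth=plume_azimuth,
            duration=duration,
            dt=dt,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            fly_id=f"fly{i:02d}",
            group=group,
        )
        for i, ss in enumerate(seeds)
    ]


# ---------------------------------------------------------------------------
# imaging: tuned cell models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellModel:
    """Forward model of one imaged cell type.

    ``odor_gain`` multiplies the visual drive while odor overlaps a
    motion epoch (Hx default 1.2; exactly 1.0 for T4T5 and HSE, which are
    not odor-modulated).  ``odor_direct_drive`` adds a visual-independent
    ΔF/F response during odor pulses (octopaminergic Tdc2 terminals).
    """

    label: str = "Hx"
    rf_center: float = 20.0  # ° azimuth, just ipsilateral to the midline
    rf_fwhm: float = 50.0  # °
    preferred_direction: float = 0.0  # °; 0 = back-to-front on the ipsilateral eye
    direction_conc: float = 2.0
    tf_optimum: float = 1.0  # Hz
    tf_logwidth: float = 1.2  # octaves (sigma of the log-Gaussian)
    odor_gain: float = 1.0
    odor_direct_drive: float = 0.0  # ΔF/F
    indicator_tau: float = 0.6  # s, GCaMP decay
    response_amp: float = 1.0  # peak ΔF/F at the preferred stimulus
    f0: float = 100.0  # baseline fluorescence, a.u.
    width_half_sat: float = 15.0  # ° bar width at half-saturation

    def __post_init__(self) -> None:
        if self.rf_fwhm <= 0 or self.tf_optimum <= 0 or self.indicator_tau <= 0:
            raise ValueError("rf_fwhm, tf_optimum, indicator_tau must be positive")
        if self.odor_gain < 0:
            raise ValueError("odor_gain must be >= 0")


CELL_MODELS: dict[str, CellModel] = {
    "Hx": CellModel(label="Hx", odor_gain=1.2),
    "T4T5": CellModel(label="T4T5", odor_gain=1.0),
    "HSE": CellModel(label="HSE", odor_gain=1.0, preferred_direction=0.0),
    "Tdc2": CellModel(label="Tdc2", odor_gain=1.0, odor_direct_drive=0.5,
                      response_amp=0.0),
}

ARENA_DIRECTIONS_DEG = np.arange(0.0, 360.0, 45.0)  # eight arena directions


@dataclass(frozen=True)
class VisualStimulus:
    """One visual condition of the imaging experiments.

    ``kind`` is "wide_field", "bar", "grating", or "none" (static
    pattern).  ``temporal_frequency`` may be given directly or derived
    from grating speed and wavelength (v / λ).
    """

    kind: str = "wide_field"
    azimuth: float | None = None  # bar position, ° (None: full field)
    direction_deg: float = 0.0
    temporal_frequency: float | None = None
    bar_width: float | None = None
    speed_deg_s: float | None = None
    wavelength_deg: float | None = None

    def tf(self) -> float | None:
        if self.temporal_frequency is not None:
            return self.temporal_frequency
        if self.speed_deg_s is not None and self.wavelength_deg is not None:
            return temporal_frequency(self.speed_deg_s, self.wavelength_deg)
        return None


# 22°/s motion of a 27°-wavelength square wave: the standard pairing stimulus
DEFAULT_PAIRING_STIMULUS = VisualStimulus(
    kind="wide_field", direction_deg=0.0, speed_deg_s=22.0, wavelength_deg=27.0
)


def visual_drive_weight(cell: CellModel, stim: VisualStimulus) -> float:
    """Multiplicative tuning weight of a stimulus for a cell, in [0, 1]-ish.

    Product of receptive-field weight (Gaussian in azimuth, 1 for
    full-field stimuli), direction weight (von-Mises-like), temporal-
    frequency weight (log-Gaussian), and a saturating bar-width weight.
    """
    if stim.kind == "none":
        return 0.0
    w = 1.0
    if stim.azimuth is not None:
        w *= float(gaussian_rf(stim.azimuth, cell.rf_center, cell.rf_fwhm))
    d = math.radians(stim.direction_deg - cell.preferred_direction)
    w *= math.exp(cell.direction_conc * (math.cos(d) - 1.0))
    tf = stim.tf()
    if tf is not None:
        w *= math.exp(
            -((math.log2(tf) - math.log2(cell.tf_optimum)) ** 2)
            / (2.0 * cell.tf_logwidth**2)
        )
    if stim.bar_width is not None:
        w *= stim.bar_width / (stim.bar_width + cell.width_half_sat)
    return w


def simulate_roi_trace(
    cell: CellModel,
    design: EpochDesign | None = None,
    stimulus: VisualStimulus | None = None,
    noise_sd: float = 0.03,
    seed: int = 0,
    frame_rate: float = 10.0,
    roi_id: str = "roi0",
) -> RoiTrace:
    """Fluorescence trace for the epoch protocol.

    drive(t) is the tuning weight times ``response_amp`` during motion
    epochs, multiplied by ``odor_gain`` while the odor pulse overlaps,
    plus ``odor_direct_drive`` during the pulse.  The drive is low-pass
    filtered by a unit-gain single-exponential indicator kernel
    (steady-state response equals the drive), then
    F = f0 * (1 + filtered) + noise, floored to stay strictly positive.
    """
    design = design or EpochDesign()
    stimulus = stimulus or DEFAULT_PAIRING_STIMULUS
    n = int(round(design.total_duration * frame_rate))
    time = np.arange(n) / frame_rate
    drive = np.zeros(n)
    weight = cell.response_amp * visual_drive_weight(cell, stimulus)
    odor_t0, odor_t1 = design.odor_window()
    for k, (t0, t1) in enumerate(design.motion_windows(), start=1):
        mask = (time >= t0) & (time < t1)
        gain = cell.odor_gain if k == design.odor_epoch_index else 1.0
        drive[mask] += weight * gain
    if cell.odor_direct_drive:
        drive[(time >= odor_t0) & (time < odor_t1)] += cell.odor_direct_drive

    # unit-gain exponential indicator filter
    alpha = math.exp(-1.0 / (frame_rate * cell.indicator_tau))
    filtered = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = alpha * acc + (1.0 - alpha) * drive[i]
        filtered[i] = acc

    F = cell.f0 * (1.0 + filtered)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sd * cell.f0, size=n)
    F = np.maximum(F, 1e-3 * cell.f0)
    return RoiTrace(time=time, F=F, roi_id=roi_id, cell_type=cell.label)


def simulate_imaging_cohort(
    cell: CellModel,
    n_flies: int = 13,
    design: EpochDesign | None = None,
    stimulus: VisualStimulus | None = None,
    noise_sd: float = 0.03,
    seed: int = 0,
    frame_rate: float = 10.0,
) -> list[RoiTrace]:
    seeds = _spawn_seeds(seed, n_flies)
    return [
        simulate_roi_trace(
            cell,
            design=design,
            stimulus=stimulus,
            noise_sd=noise_sd,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            frame_rate=frame_rate,
            roi_id=f"fly{i:02d}",
        )
        for i, ss in enumerate(seeds)
    ]


def simulate_tuning_responses(
    cell: CellModel,
    kind: str,
    values: Sequence[float],
    n_flies: int = 7,
    noise_sd: float = 0.05,
    seed: int = 0,
    direction_deg: float | None = None,
):
    """Tidy per-fly peak-ΔF/F table for one tuning experiment.

    ``kind`` selects the varied stimulus dimension: "rf" (bar azimuth),
    "width" (bar width, °), "direction" (grating direction, °), or "tf"
    (grating temporal frequency, Hz).  Each fly's peak response per value
    is the cell's tuning weight times ``response_amp`` plus Gaussian
    noise.  Returns a DataFrame with columns (fly_id, stimulus_kind,
    stimulus_value, peak_dff) ready for the tuning-fit routines.
    """
    import pandas as pd

    values = np.asarray(values, dtype=float)
    rows = []
    seeds = _spawn_seeds(seed, n_flies)
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(int(ss.generate_state(1)[0] % (2**31)))
        for v in values:
            if kind == "rf":
                stim = VisualStimulus(kind="bar", azimuth=float(v),
                                      direction_deg=direction_deg or 0.0)
            elif kind == "width":
                stim = VisualStimulus(kind="bar", bar_width=float(v),
                                      direction_deg=direction_deg or 0.0)
            elif kind == "direction":
                stim = VisualStimulus(kind="grating", direction_deg=float(v),
                                      temporal_frequency=cell.tf_optimum)
            elif kind == "tf":
                stim = VisualStimulus(kind="grating", temporal_frequency=float(v),
                                      direction_deg=direction_deg or cell.preferred_direction)
            else:
                raise ValueError(f"unknown tuning kind {kind!r}")
            resp = cell.response_amp * visual_drive_weight(cell, stim)
            rows.append(
                {
                    "fly_id": f"fly{i:02d}",
                    "stimulus_kind": kind,
                    "stimulus_value": float(v),
                    "peak_dff": resp + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows)
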