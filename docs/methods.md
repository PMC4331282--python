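# Methods

This note documents the models, estimators, and numerical choices behind
the package, and what the synthetic fixtures do and do not establish.

## Steering-plant identification

The rigid-tether preparation is modelled as a causal, linear,
time-invariant plant. The stimulus is a ternary white-noise sequence: at
each display frame the panorama steps by −1, 0, or +1 pixel (3.75°), with
move probability 0.5 split evenly between signs. This gives a zero-mean
sequence with a flat spectrum up to Nyquist and known power, which is what
the cross-correlation estimator assumes.

The estimator is

ĝ(τ) = Σ_t x(t)·y(t+τ) / Σ_t x(t)²

computed only over lags with full overlap (no circular correlation); the
normaliser is the stimulus power over the same overlap window. The kernel
is expressed per degree of displacement; `ImpulseKernel.g_per_pixel`
rescales to the per-pixel convention. Division by stimulus power gives the
kernel units of response per unit impulse; with a white stimulus the
estimator is unbiased for the true kernel and exactly linear in `y`.

The kernel summary is a difference of exponentials
`g(t) = A·(exp(−t/τ_d) − exp(−t/τ_r))` with `τ_d > τ_r > 0` — a sum of two
exponentials with opposite signs, which produces the characteristic fast
rise and slow decay. The fit profiles the linear amplitude out and
optimises only `(log τ_r, log(τ_d − τ_r))`, which enforces positivity and
the ordering constraint by construction and leaves a well-conditioned
two-parameter problem. Five deterministic multi-starts over spread rise
times protect against local minima; the lowest-RSS solution is kept, and
total failure is returned as a flagged result rather than an exception.
`peak_amplitude` is the maximum of the *fitted* curve (evaluated on a 4×
refined lag grid), not of the raw kernel — the fitted peak is what the
cohort statistics compare. Percent change is
`100·(mean odor peak − mean water peak)/mean water peak` with a two-tailed
paired t-test across flies; fully degenerate (zero-variance) pairings are
flagged and reported as p = 1.

Defaults: `max_lag` 1.0 s (the kernel is numerically zero well before
that); plant `τ_r` = 0.02 s, `τ_d` = 0.15 s, amplitude 1 a.u./°. The plant
noise SD of 26 a.u. is derived, not free: the per-lag SD of the kernel
estimate is `noise_sd/√(Σx²)`, and 26 a.u. puts the estimated kernel peak
at SNR ≈ 5 under the standard acquisition (60 s at 100 Hz). The odor gain
of 1.4 is the one generator constant pinned to a published summary value
(the ~40 % odor-evoked increase in optomotor response). Between-fly
amplitude variability is lognormal with CV 0.15, shared within a fly's
pair of conditions, so it cancels in the paired design.

## Plume-tracking model and metrics

Metrics are computed on wrapped headings with the shortest-arc angular
distance. Detection requires a contiguous dwell of ≥ 0.5 s within ±10° of
the plume rather than a single sample — a coarse-sampled fly-through
should not count as detection. Time-in-plume is `dt ×` the count of
in-zone samples over half-open windows `[0, 10)` s (acquisition) and
`[T−10, T)` s (tracking); it is additive over disjoint windows and
monotone in the threshold. Non-detecting flies are excluded before any
time statistic. Detection proportions are compared by chi-square without
continuity correction (configurable); time metrics by unpaired two-tailed
t-tests — between-genotype comparisons involve different animals, so an
unpaired test is the defensible reading. Whole-trial time-in-plume serves
the rescue-genotype comparison.

The generator integrates, per 0.02-s step:

- a slow turning bias `b` (°/s), driven by white torque noise
  (`drift_drive_sd`, 0.5 °/s² per √s) through a leaky integrator damped at
  `stabilization_gain` (5 s⁻¹ in controls);
- an attraction pull `−attraction_gain·e` (3 s⁻¹) toward the plume, active
  only while the unsigned heading error `e` is inside a 90° sensing cone;
- a constant search rotation (40 °/s) while the plume is not sensed; and
- fast white heading noise (8 °/√s).

This architecture is what creates the key behavioural dissociation.
Without visual stabilization the bias double-integrates the torque noise
and grows ∝ t^{3/2}: early in a 40-s trial it is negligible, so detection
and acquisition are intact, while by the final 10 s it displaces the
equilibrium heading (offset `b/attraction_gain`) beyond the ±10° zone and
tracking collapses. An aminergic-null profile instead zeroes the
attraction, which abolishes time-in-plume throughout the trial. Trial
duration defaults to 40 s, the plume to 180°, start headings uniform — so
the first seconds are search for every genotype, keeping acquisition
comparable across groups.

## Calcium-imaging analysis

ΔF/F uses `F0` = mean fluorescence over the final 5 s of the initial rest
period (a rolling-percentile baseline is available for drifting
recordings). Epoch peaks are maxima of ΔF/F over each motion window padded
by 2 s (`lag_pad`) to admit indicator-delayed peaks. Epoch 1 is compared
against every later epoch with a two-sided rank-sum (Mann–Whitney) test,
exact for small tie-free samples; because the same flies contribute to
both epochs, the paired signed-rank p-value is reported alongside. Peaks
are taken per trial and then aggregated (rather than from the
trial-averaged trace): the per-trial order preserves between-fly
variability for the rank statistics.

QC applies three checks in order — movement (> 5 % of frames with a
frame-to-frame change above 50 % of the local level), bleaching (fitted
linear decay above 20 %/min), responsiveness (fewer than 2 motion epochs
whose 1-s-smoothed ΔF/F peak exceeds 2 baseline-noise SDs). The smoothing
matters: the raw maximum of ~100 noise frames routinely exceeds 2 SD, so
an unsmoothed peak test would never exclude a flat noise trace. All QC
thresholds are package conventions, flagged as such in every report.

The cell models drive ΔF/F as a product of tuning weights — Gaussian in
azimuth (FWHM 50°, centered 20° ipsilateral of the midline),
von-Mises-like in direction (concentration 2), log-Gaussian in temporal
frequency (optimum 1 Hz, σ 1.2 octaves), saturating in bar width
(half-saturation 15°) — scaled by `response_amp` (peak ΔF/F 1.0) and
passed through a unit-gain exponential indicator filter (τ = 0.6 s; rise
time neglected, and the 10-s epochs are ≫ τ, so epoch peak ≈ drive). Odor
multiplies the visual drive by `odor_gain` during the paired epoch (Hx
1.2; exactly 1.0 for T4T5 and HSE) and adds `odor_direct_drive` during the
pulse (Tdc2, 0.5 ΔF/F with no visual response). Additive fluorescence
noise defaults to 3 % of baseline. The modelled preferred direction of Hx
is back-to-front on the ipsilateral eye, consistent with its
receptive-field characterisation and lobula-plate layer-2 innervation;
descriptions of its grating tuning in the source literature are
inconsistent on this point (front-to-back vs back-to-front), which is
documented here rather than resolved.

## Tuning fits

The receptive-field and temporal-frequency fits share one numerical core:
a Gaussian basis whose two linear parameters (amplitude, baseline) are
profiled out by linear least squares inside a two-parameter nonlinear
optimisation (center, log-width), multi-started deterministically. RF
width is reported as FWHM — "receptive-field width" has no unique
definition, so the convention is fixed and stated. A flat curve leaves the
width unidentifiable; it is flagged `degenerate` (amplitude within 2
residual SDs of zero) instead of reporting a meaningless number.
Temporal-frequency tuning is fitted in log₂ f; an optimum outside the
sampled range is flagged `boundary`, and a failed fit falls back to the
sampled argmax, flagged. Direction tuning divides by the largest mean
response (maximum exactly 1, ties all reported), making the output
scale-free.

## Pipeline and reproducibility

Scenario runs derive every stream of randomness from one integer seed via
`numpy.random.SeedSequence` spawning, so identical config + seed gives
byte-identical CSVs. Each CSV's first line is a `# config_hash=` comment
and each JSON report embeds the same SHA-256-derived hash of the exact
configuration; provenance (seed, hash, package version, timestamp) goes to
a sidecar so the metric files themselves stay deterministic. Angles are
degrees, times seconds, frequencies Hz throughout public interfaces.

## Problem sizes and what the fixtures show

The acceptance analyses use the cohort sizes of the emulated experiments:
15 flies (paired rigid-tether), 7 (tuning), 13 (Hx pairing), 6–7 (null
controls and Tdc2), 19–32 per plume group. The headline odor-gain figure
is reported as the mean over 5 seeded replicate cohorts, since a single
15-fly cohort at kernel SNR 5 carries ~4 percentage points of sampling
spread.

Passing tests establish that the estimators recover what the generators
encode at realistic noise levels — parameter recovery, not biological
validity. The fixtures idealise real data in known ways: the steering
plant is exactly linear with Gaussian noise (real ΔWBA contains saccades
and slow drifts); plume sensing is binary within a sharp cone (real plume
encounters are intermittent and concentration-dependent); fluorescence
noise is white (real imaging has shot noise, motion artifact, and
bleaching, which only the QC fixtures emulate); and indicator dynamics
omit the rise time. Results on real recordings therefore exercise the same
code paths but not the same error statistics.
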