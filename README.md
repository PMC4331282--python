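# odorgaze

Analysis pipeline for studying how an appetitive odor modulates motion
vision in flying *Drosophila*. Flies tracking an invisible odor plume rely
on gaze-stabilizing optomotor reflexes to hold their heading; odor
strengthens those reflexes. This package implements the three quantitative
analyses used to characterise that cross-modal interaction, together with
seeded synthetic-data generators that emulate each preparation, so the full
pipeline runs and is testable without any recordings.

## What it computes

**Optomotor system identification** (`odorgaze.sysid`). A rigidly tethered
fly is treated as a causal LTI steering plant: the wingbeat-amplitude
difference *y(t)* (ΔWBA, proportional to yaw torque) responds to a
spectrally broad sequence of panorama displacement impulses *x(t)*. The
impulse response is estimated by normalised cross-correlation,

```
ĝ(τ) = Σ_t x(t)·y(t+τ) / Σ_t x(t)²,    τ ∈ [0, max_lag]
```

and summarised by a difference-of-exponentials fit
`g(t) = A·(exp(−t/τ_d) − exp(−t/τ_r))`, `τ_d > τ_r`. Pairing odor with the
visual stimulus multiplies the optomotor gain; the cohort comparison of
fitted peak amplitudes (paired t-test, percent change) quantifies it.

**Plume-tracking metrics** (`odorgaze.plume_metrics`). Heading traces of
magnetically tethered flies are scored in three phases: *detection* (a
≥0.5-s dwell within ±10° of the plume at any time), *acquisition* (time in
the plume during the first 10 s), and *continuous tracking* (time in the
plume during the final 10 s). Groups are compared by a chi-square test on
detection proportions and two-sample t-tests on the time metrics among
detected flies.

**Calcium-imaging epoch analysis** (`odorgaze.calcium`, `odorgaze.tuning`).
ROI fluorescence is converted to ΔF/F against a pre-stimulus baseline;
peak responses are extracted per 10-s motion epoch of the five-epoch
odor-pairing protocol (odor on epoch 2) and compared across epochs with
rank-sum tests. Odor-only experiments use a paired odor-off/odor-on window
comparison. Tuning analyses fit the azimuthal receptive field (Gaussian,
width = FWHM), the bar-width curve (Spearman monotonicity), direction
tuning (normalised to the maximum response), and the temporal-frequency
optimum (log-Gaussian in log₂ f, with `tf = speed / wavelength`).

**Synthetic data** (`odorgaze.synthetic_data`). Forward models for all
three preparations: a steering plant with odor gain 1.4 (encoding the
roughly 40 % odor-evoked increase in optomotor response), plume-tracking
agents whose visual-stabilization and odor-attraction terms are separable
(so "detects and acquires but cannot hold the plume" genotypes exist by
construction), and tuned cell models (Hx odor gain 1.2; T4T5/HSE
unmodulated; Tdc2 directly odor-driven) convolved with a GCaMP-like
indicator kernel. All generators are bit-reproducible under a fixed seed.

## Worked example

```python
from odorgaze import sysid
from odorgaze.synthetic_data import simulate_rigid_cohort

trials = simulate_rigid_cohort(n_flies=15, seed=0)   # paired odor/water trials
fits_w = [sysid.fit_double_exponential(
              sysid.estimate_impulse_response(t.stimulus_water, t.water, max_lag=1.0))
          for t in trials]
fits_o = [sysid.fit_double_exponential(
              sysid.estimate_impulse_response(t.stimulus_odor, t.odor, max_lag=1.0))
          for t in trials]
result = sysid.compare_odor_modulation(fits_w, fits_o)
print(f"odor gain: +{result.percent_change:.1f}% "
      f"(t = {result.t_statistic:.2f}, p = {result.p_value:.2g}, n = {result.n_flies})")
```

prints

```
odor gain: +41.6% (t = 11.26, p = 2.1e-08, n = 15)
```

i.e. the full estimation pipeline recovers the 40 % gain built into the
generator, and the paired t-test across the 15 simulated flies is
decisive. The same cohort runs end to end from the shell:

```
odorgaze run --scenario rigid_odor --seed 0 --out results/rigid
```

which writes `kernel_fits.csv` (per-fly fit parameters per condition) and
`odor_modulation.json`. Other scenarios: `plume_t4t5`, `hx_pairing`,
`water_control`, `tdc2_odor`, `vmat_rescue`; `odorgaze generate|sysid|
plume|imaging|tuning` expose the individual stages on files.

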