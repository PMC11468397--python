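# Methods

This document records the model, the numerical choices, and the design
decisions behind `circapower`. Nothing here states empirical results
beyond what the test suite and `scripts/acceptance.py` compute.

## 1. Domain model

A **protocol** is an ordered list of phases, each with a length in days
and a light schedule: `LD` (12:12 by default, lights on 07:00–19:00) or
`DD` (constant darkness). Interventions (dosing windows with a
day-interval) are annotations; they do not alter simulation directly.
The built-in `seven_week_protocol()` has seven 7-day phases —
habituation (LD), dosing in LD, dosing in DD, two treatment weeks (DD),
an observation week (DD), and a final LD week. All free-running
analyses default to the DD observation phase (`"Observ."`), because a
free-running period is only defined without a Zeitgeber.

An **activity trace** is a uniformly sampled count series (floats;
NaN marks missing samples) with a start clock time, a bin width in
minutes, an animal id, a group label, and the governing light schedule.
Time is internal minutes from recording start; Zeitgeber time (ZT)
anchors ZT0 at lights-on.

## 2. Synthetic cohort generator

The simulator is an inhomogeneous Poisson process emulating PIR-style
locomotor counts. Per minute t the rate is

    lambda(t) = baseline_rate * [ 1 - A_eff + 2 * A_eff * w(phi(t)) ]

where `w` is a raised-cosine bout of width `active_fraction` of the
cycle, normalized so its cycle mean is 1/2. This makes the
time-averaged rate equal `baseline_rate` for any amplitude, so
amplitude manipulations change rhythm shape, not total activity — a
deliberate choice so that CPR differences cannot be confounded with
activity-level differences.

Phase phi(t): in LD phases the bout is clock-locked to lights-off plus
a phase angle `psi_h`; in DD phases phi advances at 1/tau per hour, so
the animal free-runs with its own period tau. tau is drawn once per
animal from N(tau_mean_h, tau_sd_h), clipped to a safe band
(20.5–27.5 h) so every simulated animal stays inside the analysis band.

Counts are Poisson with gamma over-dispersion (`noise_cv` controls the
extra coefficient of variation), matching the bursty look of real PIR
data.

**Group effects.** Disruption (POI-like) from `disruption_onset_day`
multiplies the amplitude by `disruption_amp_factor` and adds
independent per-animal period jitter with SD `disruption_tau_jitter_h`.
Restoration from `restore_onset_day` pulls both back toward baseline by
`restore_fraction`. The default cohort is control n=6 (no disruption),
POI n=8 (amplitude ×0.375, total period SD 0.8 h), CM n=5 (restore
fraction 0.8), E2-CM n=5 (restore fraction 0.95) — i.e. the treated
groups are deliberately specified as *nearly* control-like, so the
generator emulates restoration, not over-correction.

**What it does not emulate:** ultradian bouts, activity onset
anticipation, masking by light pulses, aging trends within a phase, or
inter-day autocorrelation beyond the deterministic phase model.

**Determinism.** Every random stream derives from
`np.random.SeedSequence` keyed by the cohort seed, the CRC-32 of the
group name, and the animal index; per-animal seeds are masked to
< 2^31. Results are therefore independent of simulation order and
reproducible byte-for-byte.

## 3. Spectral analysis

- **Binning.** Default 6-min bins (240 samples/day): fine enough that
  the circadian band is far below Nyquist, coarse enough to tame
  Poisson noise. `bin_counts` requires the trace length to be an
  integer multiple of the new bin; an all-NaN bin stays NaN, otherwise
  NaNs inside a bin are ignored.
- **Missing data.** Spectral routines reject NaN; callers impute first
  (`ActivityTrace.imputed()`, mean fill). Sliding windows with > 10%
  missing are emitted as NaN rows rather than silently imputed.
- **Spectrum.** Mean (or linear) detrend, window taper (Hann default;
  rectangular available for exact Parseval checks), zero-padding by
  `pad_factor` (default 8) for a dense frequency grid, one-sided
  `rfft`, power = |X|²/n_fft, DC excluded from the reported arrays but
  kept in `dc_power` so `total_energy()` can verify Parseval
  (DC + 2·interior + Nyquist once).
- **Period estimate.** Peak power in the 20–28 h band. Ties break
  toward the period nearest 24 h, then toward the lower period
  (lexicographic sort), so the estimator is deterministic on symmetric
  spectra. A three-point quadratic fit on log-power refines the peak;
  it is skipped when a neighbor's power is numerically zero relative
  to the peak (< 1e-9×) — interpolation there only fits round-off —
  and the offset is clipped to ±0.5 bins and the result clamped to the
  band. The record must span at least twice the upper band period
  (≥ 56 h) or a `ValidationError` is raised.
- **CPR.** Trapezoidal integral of power over the 20–28 h band divided
  by the integral over the total band (periods from 2×bin width up to
  the analysis window), on the frequency axis, DC excluded. A record
  with no variance raises `NoRhythmError` rather than returning 0/0.
  `flat_spectrum_cpr` gives the band-fraction expectation for a flat
  spectrum, used as the white-noise calibration oracle.
- **Spectrogram.** Sliding windows (default 96 h window, 12 h step,
  floor((T−W)/S)+1 windows), each spectrum mapped to a fixed
  descending display period grid (32→16 h, 0.25 h step) by nearest
  frequency. Because several display periods can map to one frequency
  bin, `argmax_periods()` resolves ties toward the display period
  closest to the bin's own period.

CPR is computed at the phase level (whole DD observation week as one
spectrum), not per spectrogram window: one number per animal per
phase is what enters the group statistics, and the longer record gives
a finer frequency resolution in the denominator band.

## 4. Group statistics

- Summaries are mean ± SD with SD using n−1 (ddof=1) throughout.
- One-way ANOVA via `scipy.stats.f_oneway`; two-way (group × ZT, with
  interaction) via a statsmodels OLS fit and a type-2 ANOVA table,
  which for the balanced designs used here equals the classical SS
  decomposition (verified against a hand-computed oracle in the
  tests). Incomplete cells or < 2 replicates per cell are rejected.
- Tukey's HSD p-values come from `scipy.stats.studentized_range.sf`
  with the Tukey–Kramer SE for unequal n. Computing them directly
  (rather than through `pairwise_tukeyhsd`) lets the two-way per-ZT
  comparisons use either the **pooled** MSE from the full model
  (default: more df, assumes homoscedasticity across ZT) or a
  **per-stratum** error term (equivalent to a one-way ANOVA within
  each ZT). statsmodels' `pairwise_tukeyhsd` remains the independent
  oracle in the tests.
- Letter codes: each letter marks one fixed contrast
  (a: control–POI, b: CM–POI, c: E2-CM–POI, d: CM–E2-CM) and is
  attached per ZT when that contrast is significant at alpha.

## 5. qPCR

- **Efficiency.** Least-squares slope of Cq against log10 template
  amount over a fivefold dilution series (step −log10(5) per
  dilution); eff% = (10^(−1/slope) − 1)·100; acceptable window
  90–110%. At least 3 dilution points are required and a non-negative
  slope is an error.
- **Relative expression.** Technical replicates are collapsed by mean
  Cq per sample × gene. Dual-reference efficiency-corrected ratio:
  E_t^ΔCq(target) divided by the geometric mean of E_r^ΔCq(ref) over
  the reference genes — the geometric mean because the per-reference
  ratios combine multiplicatively and it reduces exactly to the
  single-reference formula when references agree. `ddcq_fold_change`
  is the classical 2^−ΔΔCq, and the dual-reference formula reduces to
  it exactly when all efficiencies are 2 (tested to 1e-10).
- **Calibrator.** Either an explicit sample list or a column-filter
  map (e.g. all control ZT0 samples); ΔCq is taken against the mean
  calibrator Cq, so the calibrator's own fold change is 1 by
  construction.
- **ZT series.** ZT runs 0–24 with ZT24 treated as a wrap duplicate of
  ZT0: values supplied at ZT24 are used as ZT0 only when ZT0 is
  absent, so re-assembling an already-wrapped series is idempotent.
- **Smoothing.** Tricube-weighted local-linear regression (LOWESS,
  robustness iterations off), evaluated on a 0–24 h grid at 0.5 h
  steps; the neighborhood size is `max(3, ceil(span·n))`. This was
  implemented directly because the statsmodels `lowess(..., xvals=...)`
  interface returns NaN at interior points for small samples
  (observed on statsmodels 0.14.6). The smoother is exact on constant
  and linear data (tested). A local-linear smoother was chosen over a
  spline because it cannot overshoot between the 4-hourly ZT points
  and behaves predictably at the series ends.

## 6. Pipeline and degenerate inputs

`run_pipeline(RunConfig)` validates the configuration (including that
the spectral window fits inside the analysis phase) *before*
simulating, so misconfiguration fails in milliseconds. It then
simulates or loads the cohort, and per animal: slice phase → bin →
impute → period + CPR, recording per-animal failures instead of
aborting the cohort. Outputs are per-animal tables, per-group
summaries, ANOVA and Tukey tables, optional actogram/spectrogram
matrices, and a manifest with a SHA-256 content hash of the
configuration. All tables are written with fixed column order and
default float formatting, making reruns byte-identical.

Degenerate inputs raise `ValidationError` with a pointed message:
negative counts (with row number), non-monotone timestamps, records
shorter than twice the band period, all-constant records (`NoRhythmError`),
qPCR tables with missing columns or non-positive Cq, off-grid ZT
values, and unknown keys in run-config YAML.

## 7. Problem sizes

Defaults target the study design scale: 24 animals × 7 weeks × 1-min
samples (~70k samples/animal) simulate in well under a second each;
the full pipeline, including rasters, runs in a few seconds. The test
suite (~120 tests, including 1000-replicate calibration experiments)
runs in under two minutes; `scripts/acceptance.py` in about one.
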