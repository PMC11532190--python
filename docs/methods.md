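# Methods

This note records the models, parameter choices and numerical conventions
behind `cuffless_bp`, and what the synthetic cohort does and does not
establish about real recordings.

## The measurement chain being modelled

A laboratory study of a cuffless PPG-based BP device against a continuous
volume-clamp (finger-cuff) reference proceeds as follows, and the package
mirrors each step as a separate module:

1. the reference device records a continuous arterial pressure waveform;
   ECG R-peaks delimit cardiac cycles, from which SBP (cycle maximum), DBP
   (cycle minimum) and MAP (time-weighted mean) are extracted and averaged
   over non-overlapping 15-s segments (`beats`);
2. because the finger-cuff is restarted before every activity, its waveform
   is re-anchored per activity to a brachial cuff value — the mean of the
   last two of three readings taken at 1-min spacing during the 4-min
   pre-activity rest (`calibration`);
3. the device-side signal is reduced to per-segment pulse-wave features and
   mapped to BP by regression with subject-wise 3-fold cross-validation;
   the prediction is calibrated once, additively, against the calibrated
   reference during the initial rest (`model`, `calibration`);
4. paired segments feed the Accuracy / Stability / Change statistics, ICC
   and Bland-Altman analyses (`evaluation`).

## Synthetic cohort

### Hemodynamic trajectories

Per subject, baselines are drawn from SBP ~ N(119.3, 9.4²), DBP ~
N(72.6, 7.1²) mmHg, HR ~ N(65, 8²) bpm — the supine baseline distribution of
a healthy adult cohort. Each activity adds a plateau response with linear
onset/offset ramps (20 s; 10 s for the cold pressor, whose sympathetic surge
is fast) during the active bouts:

| activity       | median ΔSBP | ΔDBP | ΔHR | character                         |
|----------------|------------:|-----:|----:|-----------------------------------|
| handgrip ×3    | 21          | 14   | 13  | concurrent SBP and DBP rise       |
| mental stress  | 18          | 10   | 19  | SBP/HR-dominant, modest DBP rise  |
| cold pressor   | 31          | 18   | 11  | rapid, large SBP surge            |

Per-subject amplitudes are lognormal around these medians (log-SD 0.55,
chosen so the IQR/median ratio of the resulting within-subject change
matches laboratory summaries for these stressors). Beat-to-beat noise is
AR(1) with coefficient 0.7 (SD 3 mmHg SBP, 0.7× for DBP): white noise would
understate run-to-run variability in physiological series. HR wanders as a
slow AR(1) (SD 1.5 bpm) and beats are placed where the integrated
instantaneous HR crosses whole numbers. A per-session baseline offset
(SD 3 mmHg) represents between-recording wander. With zero amplitudes and
zero noise the trajectory is exactly the baseline, bit-reproducibly per
seed.

The chosen amplitude medians put the cohort median within-subject
segment-range change near 25.5 / 22.6 / 35.1 mmHg SBP for
handgrip / mental stress / cold pressor (the observed range exceeds the
plateau amplitude by the noise-driven spread of segment extremes, roughly
4 mmHg at these settings).

### Pulse waveform

Each cycle carries one template pulse: a raised-cosine upstroke over the
first 30 % of the cycle, then an exponential decay (rate 3 per cycle) back
to the diastolic level. Emitted samples are rescaled per beat so their
maximum/minimum equal that beat's true SBP/DBP exactly — the rescale absorbs
the sampling grid's miss of the analytic peak, so beat extrema are exact at
any rate ≥ 100 Hz. The template's normalized time-weighted mean is
f ≈ 0.386, and the generator *defines* true MAP = DBP + f·(SBP − DBP), so
trajectory truth and waveform-derived MAP agree by construction (to
< 0.1 mmHg at ≥ 500 Hz; the residual is the half-open-cycle truncation,
which shrinks as 1/fs). The default pipeline rate is 125 Hz: the clean
template is fully characterized well below that, all beat statistics are
rate-invariant to < 0.1 mmHg (tested), and it keeps a 38-subject cohort to a
few seconds of simulation.

### Device error model and features

Seven features (pulse amplitude, half-amplitude width, rise/decay time,
maximum upstroke slope, a reflection-index surrogate, segment HR) are an
*open stand-in* for the proprietary feature sets of real devices: they are a
full-column-rank linear map of the segment-mean (SBP, DBP, MAP, HR), plus
Gaussian feature noise, so a linear regressor can in principle invert them.
What the device "sees" is the truth perturbed by, per parameter:
fixed bias (0.3 mmHg), a per-subject random effect (SD 6 / 4.5 / 5.5 mmHg
for SBP / DBP / MAP), per-segment white noise (same SDs), optional
within-day drift (default 0), and a +2 mmHg day-2 shift that exercises the
Stability statistic. The defaults were set so the *pooled raw* device error
(before one-point calibration) has an SBP SD near 8.7 mmHg, the scale
reported for upper-arm PPG prototypes; after one-point calibration the
per-subject effect largely cancels and the pipeline's pooled SD settles
near 5–6 mmHg. With every field zero the device equals truth and the full
pipeline collapses to (numerically) perfect agreement.

### What passing tests do and do not show

The generator emulates protocol structure, BP response magnitudes, an
additive device error structure, and artifact classes (flat calibration
gaps, high-frequency bursts). It does **not** model the optics of PPG, the
volume-clamp servo, arrhythmia or peripheral artery disease, motion
coupling, or nonlinear BP-feature relationships. Green tests therefore
demonstrate that the *statistical machinery* (processing, calibration
bookkeeping, cross-validation hygiene, agreement statistics) is correct and
that the pipeline behaves properly in calibrated and limiting regimes — not
that any real device meets the criteria.

## Processing conventions and numerical choices

* Cardiac cycles are half-open `[R_i, R_{i+1})`; the trailing partial cycle
  is discarded. MAP uses the trapezoidal rule over the cycle's samples
  divided by the sampled span.
* 15-s windows are aligned to the session start; the final partial window is
  dropped; window value = unweighted mean of accepted beats assigned by
  cycle start. A window is *removed* (flagged missing, never zero-valued)
  when accepted beats cover less than half of it — scattered artifact bursts
  then remove the windows they dominate, which is what the >50 %-removed
  subject-exclusion rule counts. Exclusion is strict: exactly 50 % removed
  is retained.
* Artifact filter defaults: flat-line runs ≥ 0.5 s, samples outside
  [20, 300] mmHg, and 1-s windows with > 30 % of spectral power above 20 Hz.
  These are config values, not claims about any particular device; on the
  generator's injected artifacts the filter recalls ≥ 90 % of corrupted
  samples. A manual-review stage is represented by an optional mask
  override.
* The reference recalibration uses the brachial SBP only and shifts the
  whole waveform additively, so DBP and MAP shift by the same constant —
  the arithmetic consequence of shifting a pressure trace. The one-point
  device anchor is the last 60 s of the initial rest (the standard's "during
  the initial rest period" leaves the extent open; it is configurable).
  Offsets are purely additive — no scale factor.
* Regressor: ridge (α = 10⁻³ by default) on the seven features. Linear
  models keep the recovery guarantees provable (zero-noise held-out RMSE
  < 0.5 mmHg is a test); the regularization handles rank-deficient designs.
  Models are trained on day-1 segments only; day 2 is predicted with the
  frozen ensemble and the day-1 calibration.
* Evaluation modes: `strict` (default) scores each subject with the member
  that never saw its fold; `paper` averages all three members for everyone,
  which is in-sample with respect to the folds and optimistic — both are
  emitted and labelled, neither silently substituted for the other.
* Change candidate set: all ordered window pairs within one recorded
  activity session meeting the |Δref| threshold (15 / 10 / 12 mmHg), with a
  seeded per-subject cap (default 200) to bound the combinatorics; error
  rate = |Δdev − Δref| / |Δref| × 100. Percentiles use linear interpolation
  between order statistics.
* Pair selection is uniform without replacement per subject (22 for
  Accuracy, 44 for Stability drawn from the union of day-1 and day-2 pairs
  of the 24-h subjects). SD uses the n−1 denominator throughout. ICC is the
  one-way random-effects ICC(1,1) on per-pair differences, with the
  unbalanced-k0 correction; negative estimates are reported as-is.
* Bland-Altman: bias ± 1.96 SD on unclamped differences; the ±30 mmHg clamp
  affects plotting only.

## Problem sizes

The default configuration — 38 subjects, 11 with a day-2 handgrip session,
125 Hz waveforms, ~2 400 beats and ~190 segments per subject — runs the full
pipeline in a few seconds and is the size used by the test suite's headline
checks; the noiseless-recovery checks use 9 subjects. Larger cohorts and
1 000 Hz waveforms are supported by the same code paths.

## Known limitations

* The feature set and device error structure are documented stand-ins, not
  reverse-engineered device internals; absolute error magnitudes are only
  as realistic as the configured SDs.
* The Stability arm models the second day as one extra handgrip session
  with a fixed shift, not a true 24-h ambulatory wear.
* No R-peak detection is provided: peak times are an input (the generator
  supplies them; real data would need an upstream detector).
* Counting removed reference data in 15-s segments is one defensible
  reading of the exclusion rule; counting raw samples or beats would give
  slightly different retention on heavily corrupted data.
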