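# cuffless_bp

Evaluation pipeline for **cuffless blood-pressure (BP) devices** against the
agreement statistics of the ISO 81060-3:2022 standard for continuous,
non-invasive BP monitors — built on a fully synthetic laboratory-protocol
cohort so that every stage is testable and reproducible end to end.

It is aimed at researchers developing or benchmarking PPG-based BP
estimation: it implements the complete measurement chain of a
volume-clamp-referenced laboratory study (beat-to-beat reference extraction,
brachial recalibration, one-point device calibration, subject-wise
cross-validated regression) together with the Accuracy / Stability / Change
criteria used to judge such devices.

## What it computes

For paired 15-second segments of reference and device BP (device − reference
differences *d*):

* **Accuracy** — pooled mean and sample SD of *d* over 22 randomly selected
  pairs per subject; pass iff |mean| ≤ 6 mmHg and SD ≤ 10 mmHg.
* **Stability** — the same statistic over 44 pairs per subject drawn from
  day 1 *plus* a day-2 session, with the original one-point calibration
  still applied; same bounds.
* **Change** — for within-activity intervals with reference change
  |Δref| ≥ 15 / 10 / 12 mmHg (SBP / DBP / MAP), the error rate
  |Δdev − Δref| / |Δref| × 100; pass iff the 50th percentile ≤ 25 % and the
  85th percentile ≤ 50 %.
* Supporting statistics: one-way random-effects ICC(1,1) of the differences,
  Bland-Altman bias and 95 % limits of agreement (bias ± 1.96 SD, with the
  ±30 mmHg clamp applied to plotting only), and per-subject within-protocol
  BP range (max − min).

Per cardiac cycle (R-peak to R-peak) the reference waveform yields
SBP = max, DBP = min, MAP = time-weighted (trapezoidal) mean; the continuous
reference is re-anchored before every activity to the mean of the last two
of three brachial cuff readings, while the device estimate receives a single
additive offset per parameter during the initial rest, never recomputed.
Device BP comes from seven open pulse-wave features through a
ridge-regularized linear ensemble: subjects are split into three disjoint
folds, one model per fold-complement, predictions averaged ("paper" mode) or
taken from the subject-held-out member only ("strict" mode, the default).

The synthetic cohort reproduces a three-activity stressor protocol
(isometric handgrip 2 min × 3, serial-subtraction mental stress 5 min, cold
pressor 2 min, each with 4-min rest and 1-min recovery), within-subject
SBP swings of roughly 20–40 mmHg per activity, and a configurable device
error structure (bias, per-subject random effect, segment noise, drift,
day-2 shift). See `docs/methods.md` for the model and its limits.

## Worked example

```python
from cuffless_bp import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1))   # 38 subjects, 11 with day 2
print(result.report.to_table())
```

prints (seed 1):

```
parameter Accuracy mean (SD)     Stability mean (SD)    Change p50, p85 %    verdicts
sbp    -1.10 (5.58)           -1.1 (5.6)             20, 43               acc:pass stab:pass p50:pass p85:pass
dbp    -1.27 (4.28)           -1.1 (4.2)             25, 50               acc:pass stab:pass p50:pass p85:FAIL
map    -0.90 (3.64)           -1.3 (3.8)             19, 38               acc:pass stab:pass p50:pass p85:pass
```

Reading the SBP row: over 836 selected pairs (22 × 38 subjects) the device
sits 1.1 mmHg below the calibrated reference on average with a 5.6 mmHg
spread — inside the 6 (10) mmHg Accuracy envelope — and the median
within-activity change error is 20 %, inside the 25 % bound. `result`
also carries the audit tables (selected pairs, change pairs, exclusion and
calibration logs), Bland-Altman results and ICC estimates
(≈ 0.2 for SBP differences under the default error model).

The same pipeline is available from the shell:

```bash
cuffless-bp simulate --out cohort/ --subjects 38 --seed 1
cuffless-bp run --out results/ --cohort cohort/ --mode strict
cuffless-bp report --report results/report_strict.json
```

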