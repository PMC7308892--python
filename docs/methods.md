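# Methods

## Signal model

Each synthetic subject is a triple (recording, references, ground truth) on
a uniform grid at `sampling_rate_hz` (default 100 Hz — configurable, since
real front-end rates vary; 100 Hz comfortably oversamples cardiac
fundamentals up to ~180 bpm).

The ground-truth SpO2 trajectory is piecewise-constant plateaus joined by
30-s linear ramps. The ramp length is a modelling choice: physiological
desaturation and resaturation are gradual, and a finite ramp also exercises
the stable-reference filter. Two protocols are built in:

- **patient daily activity**: lying, sitting, standing (3 min each), a
  6-min walk, and 3 min of cycling (18 min total), with default plateaus
  95/94/93/87/85 % — resting saturation in the low 90s and a nadir in the
  mid 80s, typical of oxygen-dependent chronic respiratory disease;
- **volunteer stepwise hypoxemia**: three 12-min oxygenation levels
  (97/88/82 %, i.e. normoxemia, mild and severe hypoxemia), with the
  subject cycling through walking/sitting/standing/lying at each level.

The optical channels follow

```
ppg_ir(t)  = DC_ir  · (1 + p · pulse(t))          + ambient(t) + ε(t)
ppg_red(t) = DC_red · (1 + p · ROS(t) · pulse(t)) + ambient(t) + ε(t)
```

where `pulse` is a zero-mean, unit peak-to-trough periodic waveform at the
true heart rate (two Gaussians per cycle: a narrow systolic peak and a
smaller, wider diastolic hump — beat detectors should face asymmetric
morphology, not a sinusoid), `p` is the infrared perfusion fraction (AC/DC,
default 0.02, middle of the 1–4 % range seen in practice), and
`ROS(t) = (spo2_true(t) − b)/a` inverts the calibration line (defaults
`a = −26.8`, `b = 116.9`). Encoding the ratio at the *relative amplitude*
level makes the generator the exact inverse of the ROS definition: on clean
signal the downstream chain recovers `spo2_true` up to filter transients,
which cancel in the red/infrared ratio because both channels carry the same
waveform shape.

There is deliberately no optical tissue model (no Beer–Lambert path
lengths or scattering): ROS is encoded phenomenologically, which is exactly
what a ratio-based pipeline can be validated against.

Other ingredients, all seeded:

- **Motion artefacts**: Poisson events per activity (defaults, per min:
  walking 6, cycling 1.5, standing 0.5, sitting 0.3, lying 0.2), each a
  damped oscillation of 0.5–2 s at 1–4 Hz with amplitude 5–20× the
  pulsatile amplitude, added with the same relative scale to both channels
  (shared mechanical origin).
- **Ambient light**: a constant offset, slow drift (sinusoids at 0.05 and
  0.11 Hz), and a mains component; the identical addend is recorded as the
  ambient channel.
- **Sensor noise**: white Gaussian per channel (default sd 1.0 in channel
  units, i.e. ~5 % of the infrared AC amplitude).
- **Continuous reference**: truth plus AR(1) noise at 1 Hz (φ = 0.8,
  stationary sd 0.4 %), rounded to integer percent — emulating the
  display-level averaging and quantisation of commercial oximeters.
- **Blood gases**: two samples (mid-sitting rest and mid-cycling) with
  independent sd 0.5 % noise.
- **Cohorts**: per-subject seeds derived from a master seed, plus jitter on
  perfusion (±25 % relative), resting heart rate (±8 bpm) and plateau
  levels (±1.5 %).

What the generator does *not* emulate — and hence what passing tests do not
show about real data: wavelength-dependent ambient coupling, sensor
placement and contact-pressure effects, baseline wander of physiological
origin (respiration, vasomotion), arrhythmias, and any deviation of the
true ROS–SpO2 relationship from linearity.

## Processing chain

Defaults: band-pass 0.5–5.0 Hz (covers 30–300 bpm fundamentals),
fourth-order Butterworth applied forward–backward (zero phase; the
effective magnitude response is squared, which is irrelevant to ROS because
it cancels between channels), 40-s windows with a 10-s hop (the window
length is the averaging horizon; the hop is a responsiveness/independence
compromise), at least 20 beats per window, 0.33 s refractory period,
SQI threshold 70.

**Beat detection** runs on the infrared AC channel (better SNR): local
maxima at least a refractory period apart, kept when they exceed 0.4× the
local 90th-percentile amplitude (computed over ~10-s blocks and
interpolated). Flat input yields no beats, not an error.

**Cardiac-gated averaging**: beat-to-beat segments whose endpoints both lie
in the half-open window are resampled to the median beat length (min 32
samples) and averaged. Before averaging, outlier beats are screened
against the element-wise median template: a beat is dropped when its rms
deviation exceeds both 3× the median deviation (adaptive — uniform
broadband noise drops nothing) and 5 % of the template peak-to-trough
(absolute floor — identical clean beats drop nothing). Screening matters:
motion transients have the same *relative* amplitude in both channels, so
un-screened contaminated beats bias ROS toward 1 and compress the
calibration slope even in windows that pass the quality gate. The screen
is decided on the infrared channel and the same beats are averaged in both
channels, so the amplitude ratio compares like with like. `n_beats` is the
number of beats actually averaged.

**DC** is the window mean of the ambient-corrected *raw* channel (not the
band-passed signal); the pulse waveform is zero-mean, so the mean is an
unbiased DC estimate.

**SQI** (the quality index formula here is this package's own explicit
surrogate; only its interface — a 0–100 score with rejection strictly below
70 — mirrors deployed systems, whose formulas are typically proprietary):

```
SQI = 100 · max(0, ρ(template_red, template_ir)) · reg
```

with `ρ` the Pearson correlation of the two ensemble templates and `reg`
the fraction of inter-beat intervals within ±20 % of the window median
(computed on *all* detected beats, screened or not — an irregular rhythm is
a quality problem even if robust averaging can cope with it). Fewer than
two beats scores 0. The index is maximal on clean regular signal and
decreases, in expectation, under added broadband noise.

**Rejection precedence**: `too_few_beats`, then `low_sqi` (strict `< 70`;
a window at exactly 70 is retained), then `unstable_reference` from the
evaluation stage. The dominant activity of a window is the modal per-sample
label, ties broken toward the more motion-prone label
(walking > cycling > standing > sitting > lying).

## Calibration

Ordinary least squares of reference SpO2 on ROS — the minimal, analytically
testable choice; each retained window's ROS is paired with the mean
continuous-reference SpO2 over the same window. Leave-one-out: subject
`i`'s line is fitted on the pooled pairs of all subjects ≠ `i` and applied
only to subject `i`. The coefficient summary is the mean and sample sd
(n−1) across the per-subject models. Degenerate designs (fewer than two
pairs, or all ROS identical) raise an error naming the offending exclusion.
Reported estimates are clamped to [0, 100] %; the unclamped value is kept.

## Evaluation

- **Stability filter**: windows whose within-window continuous-reference
  range exceeds 2 percentage points (or with missing reference samples) are
  discarded — 2 % being the conventional threshold for a clinically
  significant SpO2 difference.
- **Blood-gas pairing**: each sample is paired with the nearest retained
  window centre within 30 s (shorter than any protocol stage); samples with
  no such window are dropped.
- **Conventions**: `bias = mean(est − ref)`; `precision_sd` uses n−1;
  `arms` uses n by its root-mean-square definition, so
  `arms² = bias² + (n−1)/n · precision_sd²` — the identity is asserted in
  the tests. Bland-Altman limits are `bias ± 1.96 · sd`. Pearson r comes
  with a two-sided p-value; zero variance in either series makes r
  undefined and is signalled with a warning, not silently zeroed.
- **Strata**: walking = {walking}; stationary = everything else (cycling is
  seated and counts as stationary); rejection rates use per-stratum
  denominators. Empty strata are omitted rather than reported as zeros.
- Display rounding (0.1 on percentages, 0.01 on correlations) happens only
  in the table writer; JSON and in-memory values keep full precision.

## Numerical and design notes

- All randomness flows from explicit seeds through `numpy` seed sequences;
  identical (config, seed) reproduce bytes.
- Zero-ambient input returns the channel unchanged; exactly constant
  ambient is subtracted at unit gain (a pure offset); a numerically
  degenerate (near-constant) ambient regressor falls back to unit gain
  rather than dividing by ~0.
- The ambient gain is estimated on de-meaned < 0.4 Hz components but the
  *full* ambient series is subtracted, so constant offsets do not leak into
  the DC ratio.
- `extract_ac` rejects signals shorter than three time constants of the
  high-pass corner (6 s at the defaults) rather than filtering
  transient-dominated data.
- Recordings shorter than one window produce an empty window list, not an
  error; an empty window set makes the rejection rate undefined and raises.

## Problem sizes

The shipped experiments use 15-subject cohorts on the 18-min patient
protocol (≈ 105 windows/subject, ≈ 1600 windows per cohort), which gives
coefficient recovery to well under 0.1 in both `a` and `b` and runs in a
few seconds per cohort. The calibration-recovery configuration lowers
sensor noise (sd 0.2) so that recovery accuracy reflects the method rather
than the simulated front end; all other defaults are unchanged.

## Limitations

- The calibration line is assumed linear over 70–100 %; real empirical
  curves flatten at high saturation.
- The SQI surrogate is sensitive to broadband noise and rhythm disruption
  but, by construction, cannot reproduce any particular proprietary index's
  numeric scale beyond the shared 0–100 range and threshold semantics.
- Reference-device error is modelled as unbiased; real oximeters have
  saturation-dependent bias, which leave-one-out calibration would absorb
  into the line.
- Accuracy numbers obtained on this generator characterise the pipeline,
  not any physical sensor.
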