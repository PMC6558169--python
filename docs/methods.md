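# Methods

## Scope and model of the data

`saccadepipe` analyses binocular step-saccade recordings: 1 s windows
sampled at a nominal 300 Hz, starting at the moment a fixation cross
jumps from the screen centre to ±9.2° ("close") or ±18.4° ("far")
horizontal eccentricity. Each sample carries per-eye horizontal and
vertical gaze position in degrees of visual angle (signed, rightward
positive) and a per-eye integer tracker validity code in [0, 4]; codes
above 1 mark unusable samples. Trials belong to a prosaccade task (look
at the target) or an anti-saccade task (look at its mirror position),
with four conditions (left/right × close/far) of 20 trials each per
task. Analysis is horizontal-only; the vertical channel is carried
through I/O and interpolation but does not enter detection.

## Quality control

Per eye, a trial is excluded when any of three rules fires (all strict
inequalities — boundary cases are retained):

* more than 10% of samples missing;
* more than 100 ms missing contiguously, with gap duration = run length
  × the nominal sample interval (robust to timestamp jitter);
* more than 80% of the samples in the first 50 ms missing.

The per-eye verdicts are OR-combined across eyes by default
(`qc_eye_mode="and"` requires both eyes to trip). Retained trials have
interior gaps filled by linear interpolation between the nearest valid
neighbours; leading/trailing gaps take the nearest valid value, and fill
masks are kept as provenance rather than rewriting validity codes.
Visual-inspection rejection is supported as an explicit manual-exclusion
list (reason `manual`); no automatic surrogate is invented. The first
two trials of every condition are practice and dropped; a condition is
accepted when at least 9 adequate trials remain.

## Kinematics

Position, velocity, and acceleration are the 0th/1st/2nd derivatives of
a sliding least-squares polynomial (Savitzky-Golay) fit over an
11-point window (36.7 ms). The filter is zero-phase and exact for
polynomials up to the fit order. The first and last half-window of
samples are flagged outside the valid region (NaN), never padded: no
fabricated kinematics near trial boundaries.

The polynomial order defaults to 6. This is deliberately higher than
the quadratic/cubic customary for slower signals: an 11-point window at
300 Hz spans more than half of a 5–20° saccade (32–65 ms by the main
sequence), and a cubic fit under that window attenuates the peak
velocity of a 5° saccade by ≈7.5% and smears the acceleration-zero
onset ≈5 samples (17 ms) early. Order 6 keeps the same window while
bounding the noise-free peak-velocity error at ≤2.3%, the onset error
at ≤0.7 samples, and the mean latency bias under 0.1° position noise at
about −1 ms; smoothing of the 0th derivative still attenuates white
noise. The order is configurable (`sg_polyorder`) for users who prefer
the classical cubic.

## Saccade detection

* **Candidates.** A saccade-like event is a contiguous run of samples
  with |velocity| > 50°/s sustained for at least 2 consecutive samples;
  one candidate per run, anchored at the run's absolute-velocity
  maximum. Runs separated by at least one sub-threshold sample are
  distinct candidates, which prevents double-counting within one
  movement.
* **Onset.** Within the 50 ms window before the velocity peak the
  direction-signed acceleration rises from zero to its maximum and
  returns to zero exactly at the velocity peak. The scan therefore
  anchors at the signed-acceleration maximum inside the window and
  walks backward to the nearest sample at or below zero; onset is
  marked at the first accelerating sample after that zero. If the
  signed acceleration stays positive across the whole window the
  fallback is the minimum-|acceleration| sample. A window truncated by
  the valid region flags the event `edge`.
* **Offset.** First sample after the peak where the direction-signed
  velocity drops to ≤ 0 (a small positive threshold is configurable,
  default 0). No crossing before the valid region ends flags `edge`.
* **Acceptance.** An event is the trial's saccade when its latency
  (onset time) lies in [100, 600] ms inclusive, its duration is at
  least 12 ms, it is not `edge`, and a stable fixation precedes it:
  every pre-onset sample (from the first valid sample to onset) within
  1.5° of the cross and a pre-onset position range strictly below 0.6°.
  Every failed gate is recorded in `rejection_reasons`.
* **Primary saccade.** The earliest accepted event per eye; eyes are
  detected independently so that binocular dysconjugacy is observable.

## Metrics

Per accepted primary saccade and eye: latency, peak velocity, amplitude
(|position(offset) − position(onset)|), duration, and gain = final
position / reference, where the reference is the target for prosaccades
and its mirror for anti-saccades. A left-eye rightward movement is
adduction, leftward abduction, mirrored for the right eye. An
anti-saccade is correct when its primary saccade moves opposite the
target side; performance is 100 × #correct / #adequate over a subject's
anti-saccade trials (left-eye primary preferred, right-eye fallback).
Task differences per subject use the configured analysis eye (left by
default): latency difference = anti − pro mean latency; peak-velocity
difference = pro − anti mean peak velocity; the scaled variant divides
each trial's peak velocity by its amplitude before averaging
(main-sequence normalisation). Undefined quantities are emitted as
flagged NaN so trial counts stay auditable.

## Dysconjugacy index and INO screening

For each subject and movement direction, every far-condition (18.4°)
prosaccade trial with accepted primaries in *both* eyes contributes the
ratio PV(abducting eye) / PV(adducting eye); the DI is the mean of these
per-trial ratios (mean-of-ratios is robust to trial-count imbalance;
ratio-of-means is available via `di_statistic`). Z-scores standardise
against the healthy-control DI distribution of the same direction with
the sample SD:

    Z_DI = (DI − mean(DI_HC)) / SD(DI_HC)

Controls are scored against the full HC distribution including
themselves (leave-one-out is optional), and the subclinical-INO cutoff
is the highest control Z plus a margin of 2; the screen is strict
(Z must exceed the cutoff). Screening is per direction by default
(`ino_pooled` pools both). The screen is exposed as the
sklearn-compatible estimator `DysconjugacyScreen` (fit on HC DI values;
fitted attributes `mean_`, `sd_`, `hc_z_`, `cutoff_`).

## Synthetic cohort generator

The generator emulates the study conditions rather than any particular
tracker's idiosyncrasies:

* **Waveform.** Minimum-jerk displacement — smooth, analytic, peak
  velocity exactly 1.875·A/D — so every trial's kinematics serve as
  ground truth for the detector.
* **Main sequence.** D = 2.2 ms/° · A + 21 ms (textbook values).
* **Latency.** Truncated normal per task: 195(25) ms prosaccade,
  305(45) ms anti-saccade, truncated to [110, 590] ms so every true
  onset stays inside the 100–600 ms acceptance window with margin.
* **Gain.** Normal(0.93, 0.05), floored at 0.2; amplitude =
  gain × |target|.
* **Direction errors.** Anti-saccade trials move toward the target with
  probability 0.20 (HC) / 0.36 (MS), matching performance around
  80% / 64%.
* **Noise.** Additive Gaussian position noise, SD 0.1°, independent per
  eye but reproducible from a stored per-trial seed. Per-eye
  independence matters: with identical noise on both eyes every control
  DI is exactly 1 and the Z-score reference degenerates.
* **Dropout.** A stationary two-state Markov chain marks validity-4
  bursts on both eyes; the stationary missing fraction equals
  `dropout_prob` (default 0.02) exactly and the mean burst length is
  `dropout_burst_len` (default 3 samples).
* **INO.** `apply_ino` stretches the adducting eye's duration by
  1/factor with amplitude preserved, so the adducting true peak
  velocity is factor × the abducting one — exactly the velocity
  dysconjugacy the DI measures. Factor 1.0 reproduces the input
  bitwise. Default cohort: 34 HC, 33 MS, 5 affected subjects at factor
  0.7, alternating affected direction.

What the generator does **not** emulate: pre-stimulus fixation samples
(acquisition starts at the target jump; fixation checks use pre-onset
samples), corrective/secondary saccades, blinks as physiological events
(dropout is validity-coded only), pupil size, vergence, smooth pursuit,
head movement, tracker calibration drift, and non-Gaussian noise tails.
Passing recovery tests on this generator therefore demonstrates the
correctness of the pipeline's numerics and decision rules under the
stated model, not robustness to every artefact of real recordings.

## Numerical and degenerate-case choices

* Latency window inclusive at both ends; duration "at least 12 ms"
  inclusive; all QC thresholds and the fixation rules strict, as
  printed in the protocol.
* Velocity threshold applies to |velocity|; movement direction is the
  velocity sign at the peak.
* An eye with zero valid samples is a data error, not a silent skip; an
  empty pre-onset window fails the fixation gate.
* SD(DI_HC) = 0 or fewer than two control DI values raise rather than
  emit infinite Z-scores.
* Gap durations use the nominal sample interval, not timestamp
  differences.
* Problem sizes in the validation suite (100 random signals for the
  filter oracle, 40 noise-free saccades, 200 noisy latency trials,
  1000 anti-saccade trials, 30+30-subject cohorts) were chosen to give
  stable statistics at interactive runtimes.

## Known limitations

* The acceleration-onset rule is inherently filter-dependent; with the
  default order-6 fit the residual latency bias is about −1 ms
  (reported by `scripts/acceptance.py` as `latency_bias_ms`), but
  heavier smoothing (e.g. `sg_polyorder=3`) re-introduces an early bias
  of up to half the filter window.
* Gain uses the filtered position at the detected offset; corrective
  saccades after the primary movement are not folded into gain.
* The INO screen inherits the cutoff's dependence on the control-group
  size: with few controls, max(HC Z) is noisy.
* Group-level inference (mixed models, correlations with imaging) is
  out of scope; the package emits the tidy tables such analyses
  consume.
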