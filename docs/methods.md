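# Methods

`motioncue` re-implements, as a reusable and tested pipeline, an EEG decoding
analysis of two competing visual motion cues. A single object moves from the
center of a 25 cm circle (viewed from 50 cm, so the traverse subtends a 14°
visual angle) in a uniformly random direction at one of 11 speeds, and the
question is how well each cue — speed class or direction class — can be read
out from single electrodes of a 32-channel EEG recording, separately under a
gaze-fixed and a gaze-tracking condition. The original recordings are not
publicly deposited, so the package pairs the analysis chain with a
protocol-faithful synthetic-data generator whose ground truth makes every
stage of the chain testable.

## Protocol model

Timing and counts follow the experimental protocol exactly: per trial, 2 s
fixation (the last 0.3 s cued green), a motion whose traverse duration
depends on the speed class, a 1 s hold at the rim, and a 3 s intertrial
interval; 33 trials per session (3 per speed class, directions uniform on
[0°, 360°)); 15 sessions per gaze condition, giving 45 trials per class and
495 motion trials per condition. EEG is 31 signal electrodes (a 32-channel
10-20 cap referenced at CPz) at 500 Hz.

Only the endpoints of the speed ladder are known (traverse durations 0.5 s
down to 0.1 s, i.e. mean screen speeds 25–125 cm/s). We space the 11
durations geometrically between those endpoints (ratio (0.1/0.5)^(1/10)),
preserving the design's multiplicative intent. Angular speed is reported as
the mean over the traverse (end angle / duration), which reproduces the
protocol's printed 28 °/s for the slowest speed. Direction bins partition
the circle with bin 1 anchored at 0° (rightward, counter-clockwise
positive); the anchoring convention is not documented in the source
protocol and is therefore a package convention.

## Synthetic sessions

Each channel is a sum of, in microvolts:

- **Background noise** with power spectrum `(1-w)/f + w` (white fraction
  `w = 0.3`), total SD 8 µV. Channels are independent; no volume-conduction
  correlation structure is modelled. Within the 0.1–13 Hz analysis band the
  background SD is ≈3.2 µV (most 1/f power lies below 0.1 Hz).
- **Alpha oscillation**: 8–12 Hz sinusoid, posterior-weighted, amplitude
  4 µV with a slow random envelope.
- **Blink artifacts**: Poisson events (0.2 Hz by default) confined to
  intertrial intervals (subjects relax their eyes then), ~80 µV biphasic
  waves weighted by a quadratic frontality profile. A flag allows in-trial
  blinks. Ground-truth onsets are kept in `SessionRecording.annotations` so
  artifact removal can be validated.
- **Evoked response** in each motion window: a biphasic kernel (positive
  peak ≈120 ms, trough ≈250 ms after motion onset). Its peak amplitude per
  electrode is `base + speed_gain·(s−1) + direction_gain·cos(2π(d−φ)/11)`
  and its latency shifts by `speed_latency_shift_ms·(s−1)`. Linear speed
  scaling and cosine direction tuning are the simplest forms that make
  parameter recovery testable; the true generative form of the scalp
  response is unknown.
- **Ocular (EOG) component**, eye-tracking condition only: each electrode
  receives `eog_gain · frontality · (laterality·x(t) + y(t))`, where
  `(x, y)` is the gaze's normalized displacement from screen center. The
  gaze itself starts pursuing after a uniform 100–300 ms latency, reaches
  the rim, holds, and returns to center early in the intertrial interval —
  so the EOG ramp, its direction-signed sign, and the return transient all
  follow from the gaze trace.

Gaze is expressed in normalized screen coordinates of a 16:9 27-inch
monitor; because the screen is wider than tall, equal physical excursions
are larger vertically in normalized units, and tracking endpoints form the
vertically elongated ellipse seen in real eye-tracker data. Eye-fixed gaze
is center + 0.008 jitter, giving a dispersion (RMS distance from centroid)
of ≈0.013, well under the 0.030 screening criterion; tracking gives ≈0.13.

Amplitudes are free parameters: the source study reports no microvolt
scales, so the defaults were chosen to put single-trial evoked responses
well below the background SD, forcing decoding to rest on trial averaging
as in the original analysis. Default encoding profiles give posterior sites
speed and direction tuning and frontal sites a strong ocular gain, so the
default subject reproduces the qualitative result pattern: posterior sites
decode best when gaze is fixed, frontal sites dominate direction decoding
under tracking.

Determinism: one master seed; per-session streams derive from
`SeedSequence((seed, condition_index, session_index))`, so any session can
be regenerated independently and identical configurations are bit-identical.

## Signal chain

Fixed order: common-average reference → ICA artifact removal → FIR bandpass
→ epoch extraction with downsampling.

- **Reference**: subtract the instantaneous mean of the 31 signal
  electrodes. This leaks −1/31 of the summed source activity into every
  channel; the parameter-recovery study (below) accounts for it explicitly.
- **ICA blink removal** (sklearn FastICA): components whose time course
  correlates (|r| > 0.8) with a frontal proxy (mean of the two most
  anterior electrodes) are zeroed and the signal reconstructed; if none
  qualifies, the highest-kurtosis component is removed when its kurtosis
  exceeds 5 (blinks are sparse, hence heavy-tailed). Two numerical points
  learned from validation: components are capped at the data's numerical
  rank (30 after common-average referencing — whitening the null direction
  silently corrupts the reconstruction), and the deflation algorithm is the
  default because the synthetic background is nearly Gaussian, leaving the
  symmetric ("parallel") rotation unidentifiable; deflation extracts the
  heavy-tailed blink source first and converges. On hard failure the input
  is returned unchanged with `converged=False`.
- **Bandpass**: 50th-order (51-tap) Hamming-window FIR, 0.1–13 Hz, at
  500 Hz. A 51-tap filter cannot realize a sharp 0.1 Hz high-pass; the
  implemented filter's measured response is the contract (5 Hz gain 1.06,
  100 Hz ≈ −59 dB). The exactly-linear-phase filter is applied once and its
  25-sample group delay removed — zero phase without the magnitude-squaring
  of a forward-backward pass, which would push the ~6 % passband ripple
  outside the ±10 % passband tolerance.
- **Epochs**: per trial, the 0.5 s window from motion onset — identical for
  all speeds, covering the slowest traverse — decimated by stride 20
  (500→25 Hz), keeping the window-start sample: 13 features per electrode
  per trial. No extra anti-alias filter is applied before decimation; the
  13 Hz low-pass already sits at the new Nyquist (12.5 Hz). Documented as
  an approximation. Trials whose window exceeds the recording are dropped
  with a logged warning.
- **Gaze screening**: dispersion = RMS Euclidean distance from the trace
  centroid (the "center" is taken as the centroid; a coordinate-wise
  geometric mean is ill-defined for signed values), thresholded at 0.030.
  Screening is a report only and never gates the pipeline.

## Decoding

Per electrode and cue, multi-class LDA with a trial-averaged hold-3-out
cross-validation. One repetition makes one decision per class: three trials
of the test class are held out and averaged into a "test VEP";
`n_train_veps_per_class` (100 at full scale) training VEPs per class are
formed as averages of three distinct trials drawn from each class's pool,
with the held-out trials excluded from their own class's pool only; LDA is
refit for every decision (the training pool changes with the held-out
trials — an early shared-fit shortcut measurably biased accuracy at small
trial counts and was removed after an exhaustive-enumeration oracle exposed
it). Accuracy γ̂ is the fraction of correct decisions over
`n_repetitions × K` decisions (100 × 11 = 1100 at full scale), accumulated
in a K×K confusion matrix (rows = classified, columns = true).

The LDA is written out explicitly: class means, pooled within-class
covariance shrunk toward the scaled identity by weight `a` (default 0.1 —
with 13 features and ~100 averaged training VEPs per class the pooled
covariance is invertible, but averaging-induced correlation motivates mild
regularization), Gaussian discriminant with uniform priors (classes are
balanced by design), ties broken toward the lowest class index. At
`a = 1` the classifier reduces to nearest class mean; at `a = 0` a singular
pooled covariance raises an error advising shrinkage. When the pooled
covariance is exactly zero (noiseless data) the shrinkage target falls back
to the identity so the degenerate limit remains well defined. The test
suite verifies decision-for-decision agreement with an independent
brute-force Gaussian-Bayes implementation, and verifies the CV scheduler
against exhaustive enumeration of all held-out triples on a small problem.

Two scheme details are genuinely underdetermined by the source description
and are exposed in `CVConfig` rather than asserted: the size of the average
behind each training VEP (default 3, mirroring the test VEP so train and
test features share a distribution), and the repetition structure (default:
each of the 100 repetitions decides every class once, since the reported
confusion matrices contain decisions for every true class).

The nested speed analysis re-runs the CV on the `n` slowest speed classes
for `n = 2…11`, with chance 1/n (50 %, 33.3 %, … 9.1 %).

## Statistics

Significance of one electrode's γ̂ against chance 1/K uses the Wald
interval: significant when `γ̂ − z*·√(γ̂(1−γ̂)/n) > 1/K`, with z* the
two-sided normal quantile at α = 0.01 (2.576). `n` is the number of trials
in the electrode's task (495 at full scale), the definition the source
analysis states; the number of CV decisions is available as an alternative
(`n_column="n_decisions"`). Across the 31 electrodes of one subject, cue,
and condition, Holm–Bonferroni step-down is applied to the equivalent
one-sided normal p-values at family level α/2, which makes the uncorrected
Holm test coincide exactly with the CI rule, so Holm-significant is always
a subset of raw-significant.

A calibration caveat the package's own null study quantifies: CV decisions
share trials across repetitions, so γ̂ is over-dispersed relative to a
binomial proportion (null SD ≈1.5–2× the binomial SD). Consequently the
Wald interval's nominal 99 % coverage of chance on null data erodes to
≈90 %, and the family-wise false-positive rate runs above the nominal 1 %
(≈2–3 % with n = trials; ≈9 % had n = decisions been used — one reason the
trial-count definition is the default). The t-test comparing the two cues
across the 31 electrode accuracies is paired by default (each electrode
contributes one accuracy per cue); a flag allows the unpaired variant.
Pearson r of the 31 paired accuracies quantifies whether the cues occupy
the same sites; it is reported as NA with a reason when either vector is
constant.

## Validation studies and what they show

Run by `tests/test_acceptance.py` and `scripts/acceptance.py` at a reduced
demo scale chosen to keep the full validation suite within a few minutes:
3 sessions per condition with 5 trials per speed class per session (55
trials/session — at the protocol's 3 trials per class, 99 uniformly random
directions leave some direction bin below the 6 trials the hold-3-out
scheme needs, so the demo raises the per-class count instead of the session
count), 20 CV repetitions, 20 training VEPs per class.

- **Null calibration**: 50 subjects with all gains zero; mean γ̂ within
  0.01 of 1/11 and the Holm family-wise false-positive rate within
  `0.01 + 3·√(0.01·0.99/50)`. Mean null γ̂ sits ≈0.008 *below* chance:
  per-decision refitting gives the test class a smaller training pool than
  the competing classes, a small conservative bias inherent to the scheme.
- **Parameter recovery**: speed encoded on P3/Pz/P4, direction on
  Fp1/Fpz/Fp2, gains 6× the in-band noise SD (above the 3× detection
  floor). Source patterns are polarity-balanced — speed gains (+1, −2, +1)
  across the three sites, direction phases a third of the circle apart — so
  the common-average reference does not leak the summed evoked activity
  into the 25 non-encoding electrodes; unbalanced sources of this strength
  leak enough signal through the reference to make non-encoding electrodes
  significant, which is a real property of common-average referencing, not
  an artifact. Exactly the encoding electrodes come out Holm-significant
  for their cue, and the cross-cue Pearson r is negative. With sparse
  (3-of-31) encoding the anticorrelation in r is weak (≈−0.05 to −0.15);
  gains at exactly the 3× floor leave it within Monte-Carlo noise of zero.
- **Separable limit**: with zero noise and a speed-encoding electrode, γ̂
  is exactly 1 with a diagonal confusion matrix.
- **Signal chain**: common-average output means vanish; the FIR passes 5 Hz
  within [0.7, 1.1] and attenuates 100 Hz by ≥20 dB; injected blinks lose
  ≥80 % (measured ≈94 %) of their frontal variance after ICA removal.
- **Gaze screening**: default eye-fixed dispersion < 0.030 < eye-tracking.

Because the generator's channels are independent, nearly Gaussian, and
driven by idealized tuning forms, passing these studies shows the *chain*
is correct and calibrated — it does not certify performance on real EEG,
where volume conduction, non-stationarity, and non-Gaussian artifacts
change both ICA behaviour and attainable accuracies. The subject-level
accuracy figures of the original study derive from undeposited human
recordings and are not reproduction targets.

## Known limitations

- Single-electrode decoding only (as in the source analysis); no
  multi-electrode joint classifier.
- Direction tuning that is purely cosine-shaped makes mirror-symmetric
  direction pairs indistinguishable at a single electrode; multiple
  electrodes with different preferred phases resolve this, single ones
  cannot exceed ≈6/11 accuracy even noiselessly.
- The EOG model is a linear projection of gaze displacement; saccade
  microstructure, pupillometry, and blink–pursuit interactions are not
  modelled.
- EDF ingest (optional, via `mne`) carries no gaze trace; gaze screening of
  ingested sessions reports the fixation default.
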