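# motioncue

EEG decoding of two competing visual motion cues — **speed** and
**direction** — from single electrodes.

A small object moves from the center of a 25 cm circle (50 cm viewing
distance, a 14° traverse of the gaze) in a uniformly random direction at one
of 11 speeds (mean screen speeds 25–125 cm/s; traverse durations 0.5 s down
to 0.1 s), while a 32-channel EEG is recorded under two conditions: gaze
fixed at the center, or smoothly pursuing the object. Because speed and
direction vary independently in every trial, each cue acts as noise for the
other, and the scientific question is which electrodes — and which cue — a
linear classifier can read out. `motioncue` is a tested, reusable
implementation of that whole analysis for researchers in EEG decoding and
visual BCIs: a protocol-faithful synthetic session generator with
controllable ground truth (the original recordings are not public), the
signal chain, the classifier, and the significance statistics.

## The method

Per electrode, the classifier input is the 0–0.5 s post-motion-onset
waveform, bandpassed to 0.1–13 Hz and downsampled to 25 samples/s (13
features). Decoding is multi-class LDA (Gaussian classes, pooled shrunken
covariance Σ, uniform priors) with a trial-averaged hold-3-out
cross-validation: per repetition and class, 3 same-class trials are averaged
into a test VEP x̄, 100 training VEPs per class are random 3-trial averages
from the remaining pool, and the predicted class is

    argmax_c  x̄ᵀ Σ⁻¹ μ_c − ½ μ_cᵀ Σ⁻¹ μ_c .

Accuracy γ̂ over all decisions is tested against chance 1/K with the Wald
interval, γ̂ − z*√(γ̂(1−γ̂)/n) > 1/K at α = 0.01 (n = number of trials),
Holm–Bonferroni-corrected over the 31 electrodes; per subject, a paired
two-tailed t-test and the Pearson r over the 31 paired accuracies compare
the two cues. A nested analysis restricts to the n slowest speeds
(chance 50 %, 33.3 %, … 9.1 %).

## Worked example

Run the reduced demo (3 sessions per condition, 5 electrodes, 20 CV
repetitions) end to end — simulate, preprocess, decode both cues under both
gaze conditions, test significance:

```bash
$ motioncue run --demo --seed 7 --out demo_report
subject    condition  t_statistic  p_value  pearson_r preferred_cue  alpha
     S1    eye_fixed    -0.302920 0.777051   0.569742          none   0.01
     S1 eye_tracking    -4.770315 0.008838   0.786419     direction   0.01
report bundle in demo_report (26 files)
```

Under the eye-fixed condition neither cue dominates across these electrodes
(p = 0.78). Under eye-tracking, direction decoding is significantly better
than speed (p = 0.009): the pursuit-locked ocular signal carries the motion
direction, and the frontal electrodes pick it up, e.g. from
`demo_report/significance_eye_tracking_direction.tsv`:

| electrode | gamma_hat | chance | holm_significant |
|---|---|---|---|
| Fp1 | 0.359 | 0.091 | True |
| Fp2 | 0.377 | 0.091 | True |

γ̂ ≈ 0.36–0.38 against a 9.1 % chance level — the frontal sites decode the
pursued direction roughly four times above chance, while the same sites stay
near chance for speed. The bundle also contains per-electrode confusion
matrices, the gaze-dispersion screening table (eye-fixed sessions ≈ 0.011,
eye-tracking ≈ 0.13, on either side of the 0.030 criterion), and a
`manifest.json` hashing every output for reproducibility; rerunning with the
same seed reproduces every table byte for byte.

The same stages are available individually (`motioncue simulate`,
`preprocess`, `decode`, `stats`, `report`) and as a library:

```python
from motioncue import SynthConfig, generate_session, preprocess_session
from motioncue import extract_motion_epochs, leave_three_out_cv, CVConfig

recording, trials = generate_session(SynthConfig(seed=0), "eye_fixed", 0)
clean, info = preprocess_session(recording)
epochs = extract_motion_epochs(clean, trials)
result = leave_three_out_cv(epochs.electrode("P4"), config=CVConfig(cue="speed"))
print(result.gamma_hat, result.confusion.shape)   # e.g. 0.188 (11, 11)
```

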