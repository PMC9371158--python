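# Methods

`wearcam` studies what 1D convolutional classifiers of wearable
accelerometer windows actually learn: the activity's key events, the
performer's personal movement signature, or acquisition artifacts.  It
does so by training the same architectures under different validation
protocols, explaining their decisions with a time-series adaptation of
grad-CAM, and auditing the explanations against physical evidence.

## Data model

A window is a `151 x 3` matrix of raw acceleration in m/s² sampled at
50 Hz (an inclusive-endpoint 3 s segment: `3 * 50 + 1 = 151` samples),
peak-centred so the dominant key event sits at timestep 75.  Timestep `i`
occurs at `i / 50` s; one sample elapses in 0.02 s, the time scale against
which a one-sample level shift is physically implausible.  Gravity is not
removed: the classifiers consume raw signals, so a ~9.81 m/s² offset rides
on the (rotated) gravity axis.  Windows carry an activity label, an integer
subject id and a trial index; a dataset adds an ordered activity vocabulary
and a subject roster, and not every subject need appear in every activity.

## Validation protocols

* **SD** (subject-dependent): an unstratified seeded hold-out over windows,
  validation size `round(0.3 * n)` (nearest, ties to even; clamped so both
  sides are non-empty), default seed 42.  The shuffle is this package's own
  Fisher-Yates permutation, so plans are reproducible here but not
  bit-identical to other libraries' shufflers.
* **SI** (subject-independent): windows routed by subject; default hold-out
  subjects 1-9 of a 30-subject roster (30% of subjects).  No randomness.
* **BUI** (biometric user identification): one SD-semantics split per
  activity with the subject id as the class target; activities with fewer
  than two windows or a single subject are skipped with a recorded reason.

SD measures apparent performance with subject leakage — on peak-centred
benchmark data the validation windows of a subject/activity pair are
near-duplicates of training windows.  SI measures generalisation to new
people.  The contrast between the two is the central diagnostic.

## Architectures and training

`CNN1` (4 blocks of two same-padded conv layers, 100 filters, kernel 8,
ceiling-mode max pooling size 2 stride 2 after blocks 1-3) and `CNN2`
(3 blocks, kernel 4, pooling after blocks 1-2) both end in one dropout
(0.5) and a softmax head.  With a 151-sample input the final conv feature
maps have 19 (CNN1: 151→76→38→19) and 38 (CNN2) temporal positions; this
pooling placement is the unique simple arrangement reproducing those
resolutions, and `last_conv_length` computes it as a pure function.

The network is implemented directly in NumPy with hand-written
backpropagation (im2col convolutions, Adam with default hyperparameters,
categorical cross-entropy — the standard loss for a softmax classifier).
This keeps the designated-layer activations and class-score gradients that
grad-CAM needs first-class, and makes the finite-difference oracle in the
test suite a genuinely independent check of the gradients.  Training
checkpoints the epoch with the best validation macro F1 (earliest on
ties).  Protocol defaults are 300 epochs at batch 256; the test suite and
audit experiments use reduced problems (~1,500-window cohorts, ≤40 epochs,
batch 64, 16-32 filters in a 2-block custom spec with dropout 0.2 suited
to the small parameter count) so everything runs in CPU minutes.  Inputs
are fed raw by default; `TrainConfig(standardize=True)` enables optional
per-channel standardization fitted on the training split.

The designated explanation layer is the output of the final convolutional
block (post-ReLU, and post-pool when that block pools; CNN1/CNN2's final
blocks do not pool, so this is exactly the last conv layer's activation).
The class score `y^c` is the pre-softmax logit by default; a post-softmax
variant is behind `score_mode="prob"`.

## 1D grad-CAM

For feature maps `A[i, k]` (`Z` positions, `K` maps) and gradients
`G[i, k] = dy^c / dA[i, k]`:

1. `alpha_k = (1/Z) sum_i G[i, k]` — gradient pooling over time only;
2. raw map `= sum_k alpha_k A[:, k]` — negatives preserved (no ReLU; the
   image-domain ReLU variant is behind a flag);
3. min-max normalisation to [0, 1]; a constant raw map normalises to all
   zeros, so "no contrast" reads as "no importance";
4. nearest-neighbour upsampling to the input length with the index rule
   `out[j] = values[floor(j*Z/N)]`, giving crisp piecewise-constant bands.

Nearest-neighbour interpolation introduces no new values, so normalising
before or after upsampling is equivalent; this package normalises first.
The heatmap is shared across the three axes (feature maps mix axes after
the first convolution).  Threshold masks use an inclusive boundary
(`value >= tau`), default `tau = 0.7`.

## Audit procedures

* **Importance extent**: the fraction of timesteps with heatmap ≥ tau —
  the formalisation of "how much of the signal the model looks at".  The
  expected qualitative ordering is BUI ≥ SD ≥ SI on average: an
  identification model must read the personal signature between key
  events, an SD HAR model partly does, an SI HAR model is pushed towards
  the key events alone.  This is a stochastic tendency, not a per-window
  assertion.
* **Discontinuity detection**: events wherever a one-sample difference
  exceeds 10 m/s² (configurable; a robust `k x` median-absolute-difference
  alternative is available).  The default separates merged-trial level
  shifts (|Δ| ≈ 11-12 m/s²) from smooth motion: a 2 Hz, 5 m/s²-amplitude
  oscillation at 50 Hz moves at most ~1.3 m/s² per sample.
* **Co-localization**: the fraction of super-threshold heatmap timesteps
  within ±2 samples of a detected jump, compared with the halo's coverage
  fraction (the exact chance level for a uniformly random mask; verified
  by Monte-Carlo in the tests).  Enrichment = score/chance.
* **Performance correlation**: sample Pearson r between per-activity HAR
  scores and per-activity BUI scores, with the two-sided noncorrelation
  p-value from `t = r sqrt((n-2)/(1-r^2))` on n-2 degrees of freedom
  (cross-checked against `scipy.stats.pearsonr`).  Macro-F1 pairing by
  default, accuracy by flag; computed over all paired activities and over
  the ADL subset.
* **Bias flags**: a class is flagged only when its SD-SI recall gap
  exceeds 0.20 *and* discontinuity events are present in its windows.
  The conjunction matters: a gap alone can reflect honest subject
  variability, artifacts alone need not hurt generalisation.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the *structure* of a peak-centred fall/ADL
benchmark: 151×3 windows at 50 Hz, 9 ADL + 8 fall classes with the
published per-class window totals and subject counts (including missing
subject-activity pairs), ~30 subjects, gravity included.  Three archetypes
are used — harmonic locomotion, posture transitions (an acceleration bump
plus a sigmoidal gravity rotation), and impulsive falls (free-fall dip,
impact spike, damped ring, re-orientation).

Subject signatures scale linearly with `signature_strength`: stride
frequency offsets (±0.4 Hz), per-axis gains (±50%), harmonic timbre,
smoothing width (20-50 ms), and a device-orientation rotation (≤ ~35°).
On top of these, each (subject, activity) pair draws an idiosyncratic
execution style (amplitude ±45%, tempo ±40%, rotation extent ±55%, all at
strength 1): one person's rendition of an activity can cross into a
neighbouring class's template, which is what makes held-out subjects
genuinely hard.  At strength 0 all subjects are generatively identical.

Two deliberate design points:

* The four posture-transition classes share a single archetype (amplitude
  3.4 m/s², width 0.36 s, gravity rotation 0.85 rad in a common sagittal
  plane); their within-group identity is expressed through execution style
  (and any planted artifacts), not through subject-independent template
  contrasts.  This models the extreme person-dependence these classes show
  under subject-independent evaluation and is the regime in which protocol
  gaps and artifact shortcuts are visible at desk scale.
* Planted discontinuities are subject-consistent by default: a
  (subject, activity) session has one characteristic jump position and
  per-axis sign pattern (positions drawn uniformly over the window
  interior, so the cohort-level position distribution stays uniform;
  a fixed `sign_pattern` can override the per-session signs), jittered by
  a few samples per window.  This mirrors the merged-trial mechanism of
  real acquisition faults — a session's windows share the merge boundary —
  and is precisely what lets a subject-dependent model memorise artifacts
  that a subject-independent model cannot exploit.  Artifacts may be
  restricted to the y/z axes (default) or planted on all three, the two
  variants observed in practice.  Fully independent per-window plants are
  available (`subject_consistent=False`).

What the generator does **not** emulate: biomechanically realistic gait,
gyroscope/magnetometer channels, device-placement asymmetries, drift or
resampling noise, or any quantitative estimate of real inter-subject
variability (the signature ranges are engineering choices).  Passing tests
on synthetic cohorts therefore demonstrate that the pipeline detects the
phenomena it is designed to detect when they are present — not that any
particular real dataset contains them.

## Numerical choices and degenerate cases

* Even-kernel same padding puts the extra sample on the right.
* Max pooling pads odd lengths with −inf (ceiling mode); `last_conv_length`
  is monotone in input length.
* Softmax uses the log-sum-exp shift; prediction ties break to the lowest
  class index.
* Zero-denominator metrics (empty class, never-predicted class, p+r = 0)
  return 0 and are flagged `undefined` so macro means stay defined.
* Correlation with a zero-variance vector is reported undefined, not an
  error; fewer than 3 pairs is an error.
* Co-localization without events or without super-threshold timesteps is
  reported undefined, not an exception.
* All generator randomness flows from named `SeedSequence` streams keyed by
  (subject, activity, trial), so outputs are independent of generation
  order; cross-language ports can match at the distribution level, not
  bit-for-bit.

## Known limitations

Training is pure NumPy on one CPU: full 300-epoch CNN1 runs on an
11,771-window cohort are possible but slow; the audit methodology is
demonstrated at reduced scale.  Per-class recall estimates in small
cohorts rest on few held-out subjects and are accordingly noisy — the
audit averages over seeds for this reason.  The archive adapter's layout
defaults are best-effort and must be verified against the archive actually
downloaded.  Per-axis heatmap attribution is out of scope.
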