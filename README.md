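# wearcam

Explainability and bias auditing for 1D convolutional classifiers of
wearable accelerometer windows.

Human-activity-recognition (HAR) models trained on smartphone
accelerometer benchmarks often look excellent under a *subject-dependent*
(SD) hold-out — where the same people appear in training and validation —
and then degrade sharply when validated *subject-independently* (SI).
`wearcam` is a toolkit for diagnosing why: it trains HAR and
biometric-user-identification (BUI) CNNs under both protocols, explains
their decisions with a grad-CAM variant adapted to time series, and audits
models and datasets for two specific failure modes:

* **personal-signature leakage** — SD models partially memorise *who* is
  moving rather than *what* they are doing; and
* **acquisition artifacts** — physically implausible one-sample level
  shifts (e.g. merged trial segments) that models learn as class
  shortcuts.

It is aimed at researchers working with fixed-length, peak-centred
tri-axial windows (151 samples × 3 axes at 50 Hz, the convention of the
standard fall/ADL smartphone benchmarks) and ships a synthetic cohort
generator so the whole pipeline is testable without any external download.

## The method

For a window fed to a trained 1D CNN, grad-CAM asks which temporal regions
drove the score `y^c` of class `c`.  With `A^k_i` the activation of
feature map `k` at position `i` of the last convolutional block (`Z`
positions) the importance weights pool the gradient over time only,

    α_k = (1/Z) Σ_i  ∂y^c / ∂A^k_i ,

and the heatmap is the weighted combination `Σ_k α_k A^k`, kept signed (no
ReLU), min–max normalised to [0, 1], and upsampled to the 151-sample input
with nearest-neighbour interpolation so the coarse importance bands stay
crisp.  On top of the heatmaps the audit computes:

* **importance extent** — the fraction of timesteps above a threshold
  τ (default 0.7): identification models read wide extents (the personal
  signature lives between key events), SI HAR models narrow ones;
* **discontinuity co-localization** — one-sample jumps above 10 m/s² are
  detected from the discrete derivative (at 50 Hz a jump of ~11 m/s² in
  0.02 s is not a human movement) and compared against the heatmap's hot
  regions; enrichment far above chance means the model keys on artifacts;
* **HAR↔BUI correlation** — Pearson r (with the t-based noncorrelation
  p-value) between per-activity HAR and subject-identification
  performance, quantifying how much activity recognition rides on personal
  information;
* **bias flags** — classes combining a large SD−SI recall gap (> 0.20)
  with detected discontinuity events.

## Worked example

```python
import wearcam as w
from wearcam.synthgen import SynthConfig, BiasInjectionSpec
from wearcam.bias_audit import AuditConfig, run_audit

dataset = w.generate_dataset(
    SynthConfig(n_subjects=8, windows_per_subject_activity=8,
                signature_strength=0.8), seed=4)
injected, plants = w.inject_discontinuities(
    dataset, BiasInjectionSpec(affected_axes=(0, 1, 2)), seed=4)

plans = {"SD": w.split_subject_dependent(injected, 0.3, 42),
         "SI": w.split_subject_independent(injected, [1, 2])}
spec = w.build_small_architecture(17, n_filters=24, n_blocks=3)
models = {tag: w.train_model(spec, injected, plans[tag],
                             w.TrainConfig(epochs=25, batch_size=64, seed=4))
          for tag in plans}
report = run_audit(models, plans, injected, AuditConfig(seed=4))
print(report.flagged_classes)
```

Running `python examples/05_bias_audit.py` (the same experiment) prints:

```
planted 579 discontinuities in 193 windows of ['LyingDownFS', 'SittingDown', 'StandingUpFL', 'StandingUpFS']
detected 568 discontinuity events in 4 classes
importance extent [SD]: mean 0.52 (n=170)
importance extent [SI]: mean 0.38 (n=170)
flagged classes: ['StandingUpFS', 'StandingUpFL', 'LyingDownFS', 'SittingDown']
  StandingUpFS: recall gap +0.46, 136 events
  StandingUpFL: recall gap +0.84, 150 events
  LyingDownFS: recall gap +0.34, 139 events
  SittingDown: recall gap +0.72, 143 events
```

The planted classes — and only those — are flagged: each combines a large
subject-independent recall collapse with physical jump evidence, and the
subject-dependent model reads a wider share of each window (extent 0.52 vs
0.38) — the personal-signature leakage the toolkit is built to expose.  The
`examples/` directory holds one short script per capability (cohort
generation, split protocols, training and metrics, heatmaps, the audit),
and the `wearcam` CLI exposes the same pipeline as subcommands
(`generate`, `inject`, `split`, `train`, `evaluate`, `explain`, `audit`,
`report`) for shell use, writing a manifest beside every output.

Architecture facts worth knowing: with 151-sample inputs the final conv
feature maps have 19 positions for CNN1 (kernel 8, pooling after blocks
1–3: 151→76→38→19) and 38 for CNN2, so a CNN2 heatmap has twice the
temporal resolution of a CNN1 heatmap before upsampling.

## Documentation

`docs/methods.md` describes the model, the audit statistics, the synthetic
generator's assumptions and limits, and all numerical edge-case decisions.
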