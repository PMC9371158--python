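"""Train a small 1D CNN on the SD protocol and report the standard metrics.

Uses a reduced custom architecture (a few minutes of CPU at most); the
full-scale CNN1/CNN2 specs are available through build_architecture
with 300-epoch TrainConfig defaults for full-scale runs.
"""

import wearcam as w
from wearcam.eval_metrics import evaluate_predictions
from wearcam.synthgen import SynthConfig

dataset = w.generate_dataset(
    SynthConfig(n_subjects=6, windows_per_subject_activity=4, signature_strength=0.6), seed=5
)
plan = w.split_subject_dependent(dataset, 0.3, seed=42)
spec = w.build_small_architecture(len(dataset.activity_vocabulary), n_filters=16)
model = w.train_model(spec, dataset, plan, w.TrainConfig(epochs=12, batch_size=64, seed=0))

best = max(h["val_macro_f1"] for h in model.training_history)
print(f"checkpoint epoch {model.checkpoint_epoch}, best validation macro F1 {best:.3f}")

x_val = dataset.values()[plan.val_indices]
y_true = [dataset.activities()[i] for i in plan.val_indices]
report = evaluate_predictions(y_true, model.predict_labels(x_val), model.classes)
print(f"accuracy {report.accuracy:.3f} | macro F1 {report.macro_f1:.3f} | "
      f"weighted F1 {report.weighted_f1:.3f}")
print(f"weighted recall == accuracy: {abs(report.weighted_recall - report.accuracy) < 1e-12}")
# Macro averages treat all 17 classes equally; weighted averages follow the
# class imbalance, and weighted recall is algebraically the accuracy.
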