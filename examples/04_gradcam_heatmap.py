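"""Produce a 1D grad-CAM heatmap for one window and threshold it.

The heatmap is the time-pooled-gradient weighting of the final conv block's
feature maps, min-max normalised and nearest-neighbour upsampled to the
input length, so every timestep gets an importance value in [0, 1].
"""

import numpy as np

import wearcam as w
from wearcam.bias_audit import importance_extent
from wearcam.synthgen import SynthConfig

dataset = w.generate_dataset(
    SynthConfig(n_subjects=5, windows_per_subject_activity=4, signature_strength=0.6), seed=9
)
plan = w.split_subject_dependent(dataset, 0.3, seed=42)
spec = w.build_small_architecture(len(dataset.activity_vocabulary), n_filters=16)
model = w.train_model(spec, dataset, plan, w.TrainConfig(epochs=10, batch_size=64, seed=1))

i = int(plan.val_indices[0])
window = dataset[i]
class_index = model.classes.index(window.activity)
heatmap = w.explain(model, window, class_index)

print(f"window {i} ({window.activity}): heatmap length {len(heatmap)}, "
      f"source resolution {heatmap.source_resolution} positions, "
      f"range [{heatmap.values.min():.2f}, {heatmap.values.max():.2f}]")

mask = w.threshold_mask(heatmap, tau=0.7)
extent = importance_extent(heatmap, tau=0.7)
hot = np.flatnonzero(mask.mask)
print(f"importance extent at tau=0.7: {extent:.2f} "
      f"({len(hot)} of {len(heatmap)} timesteps; first hot timestep {hot[0] if len(hot) else '-'})")
w.render_overlay(window, heatmap, tau=0.7, path="scratch/heatmap_overlay.png")
print("overlay figure written to scratch/heatmap_overlay.png")
# The extent — the fraction of the window above threshold — is the scalar
# used to compare how much signal SI, SD and identification models consume.
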