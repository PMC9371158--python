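"""The three validation protocols: SD hold-out, SI by subject, per-activity BUI.

Shows how the same cohort is partitioned under each protocol and why the
subject-independent split is the one that measures generalisation to new
people.
"""

import wearcam as w
from wearcam.synthgen import SynthConfig

dataset = w.generate_dataset(SynthConfig(n_subjects=10, windows_per_subject_activity=4), seed=3)

sd = w.split_subject_dependent(dataset, val_fraction=0.3, seed=42)
print(f"SD: {sd.n_train} train / {sd.n_val} validation windows "
      f"(subjects shared across both sides)")

si = w.split_subject_independent(dataset, val_subjects=[1, 2, 3])
subs = dataset.subjects()
print(f"SI: {si.n_train} train / {si.n_val} validation windows; "
      f"validation subjects {sorted(set(subs[si.val_indices]))} never seen in training")

bui = w.make_bui_subsets(dataset, val_fraction=0.3, seed=42)
print(f"BUI: {len(bui)} per-activity subsets (skipped: {bui.skipped or 'none'})")
plan = bui["Walking"]
print(f"  Walking subset: {plan.n_train}/{plan.n_val} windows, "
      f"target = subject identity")
# One identification network per activity mirrors the idea that every
# activity's signal carries the performer's personal signature.
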