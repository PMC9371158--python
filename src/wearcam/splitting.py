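"""Train/validation partitioning for the three evaluation protocols.

* **SD** (subject-dependent): a seeded uniform shuffle of all windows with a
  hold-out fraction; the same subjects appear on both sides.  Defaults
  mirror the standard protocol for this benchmark: 70/30 with seed 42.
* **SI** (subject-independent): windows are routed by subject so the train
  and validation subject sets are disjoint; by default subjects 1-9 (30% of
  a 30-subject roster) are held out.
* **BUI** (biometric user identification): one SD-style split per activity,
  where the classification target becomes the subject identity.

The SD shuffle is an explicit seeded Fisher-Yates permutation owned by this
package, so plans are exactly reproducible here (but not bit-identical to
splits produced by other libraries' shufflers).
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from wearcam.signal_data import Dataset

__all__ = [
    "SplitPlan",
    "BuiSubsets",
    "split_subject_dependent",
    "split_subject_independent",
    "make_bui_subsets",
    "validate_plan",
]

DEFAULT_VAL_FRACTION = 0.3
DEFAULT_SPLIT_SEED = 42
DEFAULT_SI_VAL_SUBJECTS = tuple(range(1, 10))


@dataclass
class SplitPlan:
    """A train/validation partition of window indices.

    ``train_indices`` and ``val_indices`` are disjoint and together cover
    every eligible window exactly once.  For SI plans the subject sets of
    the two sides are disjoint; for BUI plans all indices share one
    activity and the class target is the subject identifier.
    """

    strategy: str  # "SD" | "SI" | "BUI"
    train_indices: np.ndarray
    val_indices: np.ndarray
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.train_indices = np.sort(np.asarray(self.train_indices, dtype=np.int64))
        self.val_indices = np.sort(np.asarray(self.val_indices, dtype=np.int64))

    @property
    def n_train(self) -> int:
        return len(self.train_indices)

    @property
    def n_val(self) -> int:
        return len(self.val_indices)

    def to_json(self) -> str:
        return json.dumps(
            {
                "strategy": self.strategy,
                "seed": self.seed,
                "params": self.params,
                "train_indices": self.train_indices.tolist(),
                "val_indices": self.val_indices.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            strategy=d["strategy"],
            train_indices=np.array(d["train_indices"], dtype=np.int64),
            val_indices=np.array(d["val_indices"], dtype=np.int64),
            seed=d.get("seed"),
            params=d.get("params", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SplitPlan":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _fisher_yates(n: int, rng: np.random.Generator) -> np.ndarray:
    """Explicit seeded Fisher-Yates permutation of range(n)."""
    perm = np.arange(n, dtype=np.int64)
    for i in range(n - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        perm[i], perm[j] = perm[j], perm[i]
    return perm


def split_subject_dependent(
    dataset: Dataset,
    val_fraction: float = DEFAULT_VAL_FRACTION,
    seed: int = DEFAULT_SPLIT_SEED,
    *,
    indices: Sequence[int] | None = None,
) -> SplitPlan:
    """Unstratified seeded hold-out over windows (subjects shared across sides).

    The validation size is ``round(val_fraction * n)`` (nearest, ties to
    even), clamped to ``[1, n-1]`` so both sides are non-empty.  ``indices``
    restricts the split to a subset of the dataset (used by the
    per-activity BUI subsets); by default all windows are eligible.
    """
    if not 0 < val_fraction < 1:
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    pool = (
        np.arange(len(dataset), dtype=np.int64)
        if indices is None
        else np.asarray(sorted(indices), dtype=np.int64)
    )
    n = len(pool)
    if n < 2:
        raise ValueError(f"need at least 2 windows to split, got {n}")
    n_val = int(round(val_fraction * n))
    n_val = min(max(n_val, 1), n - 1)  # both sides non-empty
    perm = _fisher_yates(n, np.random.default_rng(seed))
    shuffled = pool[perm]
    return SplitPlan(
        strategy="SD" if indices is None else "BUI",
        train_indices=shuffled[n_val:],
        val_indices=shuffled[:n_val],
        seed=seed,
        params={"val_fraction": val_fraction},
    )


def split_subject_independent(
    dataset: Dataset, val_subjects: Sequence[int] | None = None
) -> SplitPlan:
    """Route windows by subject: held-out subjects form the validation set.

    Defaults to holding out subjects 1-9 when the roster contains them
    (30% of the standard 30-subject roster).  No shuffling or seed is
    involved; the plan depends only on subject membership.
    """
    roster = set(dataset.subject_roster)
    if val_subjects is None:
        val_subjects = [s for s in DEFAULT_SI_VAL_SUBJECTS if s in roster]
    val_set = set(int(s) for s in val_subjects)
    if not val_set:
        raise ValueError("val_subjects must be non-empty")
    if not val_set <= roster:
        raise ValueError(f"val_subjects {sorted(val_set - roster)} not in subject roster")
    if val_set == roster:
        raise ValueError("val_subjects must be a proper subset of the roster")
    subjects = dataset.subjects()
    in_val = np.isin(subjects, sorted(val_set))
    return SplitPlan(
        strategy="SI",
        train_indices=np.flatnonzero(~in_val),
        val_indices=np.flatnonzero(in_val),
        seed=None,
        params={"val_subjects": sorted(val_set)},
    )


@dataclass
class BuiSubsets(Mapping):
    """Mapping activity -> BUI SplitPlan, plus skip reasons for ineligible activities."""

    plans: dict[str, SplitPlan]
    skipped: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> SplitPlan:
        return self.plans[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.plans)

    def __len__(self) -> int:
        return len(self.plans)


def make_bui_subsets(
    dataset: Dataset,
    val_fraction: float = DEFAULT_VAL_FRACTION,
    seed: int = DEFAULT_SPLIT_SEED,
) -> BuiSubsets:
    """One SD-semantics split per activity; class target is the subject.

    Activities with fewer than 2 windows are skipped with reason
    ``TOO_FEW_WINDOWS``; activities performed by a single subject with
    ``SINGLE_SUBJECT`` (a one-class identification problem is vacuous).
    Skipped activities are listed in the result's ``skipped`` metadata.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    plans: dict[str, SplitPlan] = {}
    skipped: dict[str, str] = {}
    subjects = dataset.subjects()
    for activity in dataset.activity_vocabulary:
        idx = dataset.indices_for_activity(activity)
        if len(idx) < 2:
            skipped[activity] = "TOO_FEW_WINDOWS"
            continue
        if len(np.unique(subjects[idx])) < 2:
            skipped[activity] = "SINGLE_SUBJECT"
            continue
        plan = split_subject_dependent(dataset, val_fraction, seed, indices=idx)
        plan.params["activity"] = activity
        plan.params["target"] = "subject"
        plans[activity] = plan
    return BuiSubsets(plans=plans, skipped=skipped)


def validate_plan(plan: SplitPlan, dataset: Dataset) -> list[str]:
    """Return a list of violated partition invariants (empty when valid)."""
    problems: list[str] = []
    train, val = set(plan.train_indices.tolist()), set(plan.val_indices.tolist())
    if train & val:
        problems.append("train and validation indices overlap")
    all_idx = train | val
    if plan.strategy == "BUI":
        activities = dataset.activities()
        acts = {activities[i] for i in all_idx}
        if len(acts) > 1:
            problems.append(f"BUI plan spans multiple activities: {sorted(acts)}")
    elif all_idx != set(range(len(dataset))):
        problems.append("plan does not cover every window exactly once")
    if plan.strategy == "SI":
        subjects = dataset.subjects()
        if {subjects[i] for i in train} & {subjects[i] for i in val}:
            problems.append("SI plan shares subjects across train and validation")
    return problems
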