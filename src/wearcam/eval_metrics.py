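"""Confusion matrices and one-vs-all classification metrics.

Rows of the confusion matrix are true classes and columns are predictions,
so per-class recall (the true positive rate) can be read off the row-
normalised diagonal.  Precision, recall and F1 are computed one-vs-all per
class and aggregated two ways: *macro* (unweighted mean over classes) and
*weighted* (support-weighted mean).  Weighted recall coincides with overall
accuracy — an algebraic identity that is asserted on every report.

Zero-denominator cases (a class never predicted, or with zero support)
return 0 for the affected metric and are flagged ``undefined`` so macro
means stay well defined while the degeneracy remains visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "confusion_matrix",
    "per_class_metrics",
    "aggregate",
    "macro_f1",
    "evaluate_predictions",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes), rows = true, cols = predicted
    class_labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if len(self.class_labels) != self.counts.shape[0]:
            raise ValueError("class_labels length must match matrix size")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_labels, columns=self.class_labels)


@dataclass
class ClassMetrics:
    """Per-class one-vs-all tallies and derived metrics, in class-label order."""

    class_labels: list
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    undefined: list[tuple[Hashable, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
                "tn": self.tn,
                "support": self.support,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
            },
            index=self.class_labels,
        )


@dataclass
class MetricsReport:
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float
    per_class: ClassMetrics

    def __post_init__(self) -> None:
        # weighted recall = sum_c support_c/total * TP_c/support_c = trace/total
        if self.per_class.support.sum() > 0:
            assert abs(self.weighted_recall - self.accuracy) < 1e-12

    def to_dict(self) -> dict:
        return {
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
            "accuracy": self.accuracy,
            "per_class": {
                str(lbl): {
                    "precision": float(p),
                    "recall": float(r),
                    "f1": float(f),
                    "support": int(s),
                }
                for lbl, p, r, f, s in zip(
                    self.per_class.class_labels,
                    self.per_class.precision,
                    self.per_class.recall,
                    self.per_class.f1,
                    self.per_class.support,
                )
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, class_labels: Sequence
) -> ConfusionMatrix:
    """Tally ``counts[r][c] = #{i : true_i = r, pred_i = c}``."""
    if len(y_true) != len(y_pred):
        raise ValueError(f"y_true has {len(y_true)} entries, y_pred {len(y_pred)}")
    labels = list(class_labels)
    index = {lbl: i for i, lbl in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"true label {t!r} not in class_labels")
        if p not in index:
            raise ValueError(f"predicted label {p!r} not in class_labels")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_labels=labels)


def per_class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    counts = cm.counts
    total = counts.sum()
    tp = np.diag(counts).astype(np.int64)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = total - tp - fp - fn
    support = counts.sum(axis=1)

    undefined: list[tuple[Hashable, str]] = []

    def _safe_div(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
        out = np.zeros(len(num), dtype=np.float64)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        for i in np.flatnonzero(~ok):
            undefined.append((cm.class_labels[i], name))
        return out

    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    pr_sum = precision + recall
    f1 = np.zeros_like(precision)
    nz = pr_sum > 0
    f1[nz] = 2 * precision[nz] * recall[nz] / pr_sum[nz]
    for i in np.flatnonzero(~nz):
        undefined.append((cm.class_labels[i], "f1"))

    return ClassMetrics(
        class_labels=list(cm.class_labels),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        undefined=undefined,
    )


def aggregate(metrics: ClassMetrics) -> MetricsReport:
    """Macro and support-weighted aggregation plus overall accuracy."""
    support = metrics.support.astype(np.float64)
    total = support.sum()
    if total > 0:
        weights = support / total
        accuracy = float(metrics.tp.sum() / total)
    else:
        weights = np.zeros_like(support)
        accuracy = 0.0
    return MetricsReport(
        macro_precision=float(metrics.precision.mean()),
        macro_recall=float(metrics.recall.mean()),
        macro_f1=float(metrics.f1.mean()),
        weighted_precision=float(np.dot(weights, metrics.precision)),
        weighted_recall=float(np.dot(weights, metrics.recall)),
        weighted_f1=float(np.dot(weights, metrics.f1)),
        accuracy=accuracy,
        per_class=metrics,
    )


def macro_f1(y_true: Sequence, y_pred: Sequence, class_labels: Sequence) -> float:
    """Unweighted mean F1 over classes; the model-checkpointing metric."""
    return aggregate(per_class_metrics(confusion_matrix(y_true, y_pred, class_labels))).macro_f1


def evaluate_predictions(
    y_true: Sequence, y_pred: Sequence, class_labels: Sequence
) -> MetricsReport:
    """Convenience: confusion matrix -> per-class metrics -> aggregated report."""
    return aggregate(per_class_metrics(confusion_matrix(y_true, y_pred, class_labels)))
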