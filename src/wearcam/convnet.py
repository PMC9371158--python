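"""1D convolutional classifiers with explicit activation/gradient access.

Two reference architectures are provided.  Both stack convolutional blocks
of two length-preserving (same-padded) conv layers with 100 filters and
ReLU, follow selected blocks with ceiling-mode max pooling (size 2, stride
2), apply one dropout (rate 0.5) between the final block and the softmax
head, and are trained with Adam on categorical cross-entropy, checkpointing
the epoch with the best validation macro F1:

* **CNN1** — 4 blocks, kernel 8, pooling after blocks 1-3.  On a
  151-sample window the final feature maps have 19 temporal positions
  (151 -> 76 -> 38 -> 19 under ceiling halving).
* **CNN2** — 3 blocks, kernel 4, pooling after blocks 1-2.  Final
  resolution 38.

The network is implemented directly in NumPy with hand-written
backpropagation (im2col convolutions), which keeps the designated-layer
activations ``A^k_i`` and the class-score gradients ``dy^c / dA^k_i``
needed by grad-CAM first-class rather than framework internals.  The
designated layer is the output of the final convolutional block.

Reference-protocol training defaults are 300 epochs at batch size 256; small
custom specs and reduced epochs are used throughout the test suite, where
problems are scaled to desk size.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from wearcam.eval_metrics import macro_f1
from wearcam.signal_data import Dataset, SignalWindow
from wearcam.splitting import SplitPlan

__all__ = [
    "ConvBlock",
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "Prediction",
    "build_architecture",
    "last_conv_length",
    "train_model",
    "predict",
    "activations_and_gradient",
]


@dataclass(frozen=True)
class ConvBlock:
    n_conv_layers: int = 2
    n_filters: int = 100
    kernel_size: int = 8
    followed_by_pool: bool = True


@dataclass
class ModelSpec:
    name: str  # "CNN1" | "CNN2" | "custom"
    blocks: list[ConvBlock]
    n_classes: int
    pool_size: int = 2
    pool_stride: int = 2
    dropout_rate: float = 0.5
    input_length: int = 151
    input_axes: int = 3

    @property
    def n_conv_layers(self) -> int:
        return sum(b.n_conv_layers for b in self.blocks)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "blocks": [
                {
                    "n_conv_layers": b.n_conv_layers,
                    "n_filters": b.n_filters,
                    "kernel_size": b.kernel_size,
                    "followed_by_pool": b.followed_by_pool,
                }
                for b in self.blocks
            ],
            "n_classes": self.n_classes,
            "pool_size": self.pool_size,
            "pool_stride": self.pool_stride,
            "dropout_rate": self.dropout_rate,
            "input_length": self.input_length,
            "input_axes": self.input_axes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            name=d["name"],
            blocks=[ConvBlock(**b) for b in d["blocks"]],
            n_classes=d["n_classes"],
            pool_size=d["pool_size"],
            pool_stride=d["pool_stride"],
            dropout_rate=d["dropout_rate"],
            input_length=d["input_length"],
            input_axes=d["input_axes"],
        )


@dataclass
class TrainConfig:
    """Training protocol; defaults follow the reference protocol (300 epochs,
    batch 256, Adam with default hyperparameters, macro-F1 checkpointing)."""

    epochs: int = 300
    batch_size: int = 256
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    seed: int = 0
    standardize: bool = False  # raw windows by default
    score_mode: str = "logit"  # y^c for grad-CAM: pre-softmax ("logit") or "prob"


@dataclass
class Prediction:
    class_scores: np.ndarray  # softmax probabilities, sum to 1
    predicted_class: int  # lowest-index maximizer

    @property
    def label_index(self) -> int:
        return self.predicted_class


def build_architecture(name: str, n_classes: int) -> ModelSpec:
    """Construct the CNN1 or CNN2 specification for ``n_classes`` outputs."""
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    if name == "CNN1":
        blocks = [ConvBlock(2, 100, 8, followed_by_pool=(i < 3)) for i in range(4)]
    elif name == "CNN2":
        blocks = [ConvBlock(2, 100, 4, followed_by_pool=(i < 2)) for i in range(3)]
    else:
        raise ValueError(f"unknown architecture {name!r}; expected 'CNN1' or 'CNN2'")
    return ModelSpec(name=name, blocks=blocks, n_classes=n_classes)


def build_small_architecture(
    n_classes: int,
    n_filters: int = 24,
    kernel_size: int = 8,
    n_blocks: int = 2,
    dropout_rate: float = 0.2,
) -> ModelSpec:
    """A reduced custom spec for desk-scale experiments: ``n_blocks`` blocks
    of one conv layer each, every block followed by pooling, and a lighter
    dropout suited to the much smaller parameter count."""
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    blocks = [ConvBlock(1, n_filters, kernel_size, followed_by_pool=True) for _ in range(n_blocks)]
    return ModelSpec(name="custom", blocks=blocks, n_classes=n_classes, dropout_rate=dropout_rate)


def last_conv_length(spec: ModelSpec, input_length: int) -> int:
    """Temporal length of the final conv block's output for a given input.

    Convolutions are length-preserving (same padding); each pooling stage
    applies ceiling-mode halving (size 2, stride 2), i.e. L -> ceil(L/2).
    """
    if input_length < 1:
        raise ValueError("input_length must be >= 1")
    length = input_length
    for block in spec.blocks:
        if block.followed_by_pool:
            length = -(-(length - spec.pool_size) // spec.pool_stride) + 1 if length >= spec.pool_size else 1
    return length


# ---------------------------------------------------------------------------
# layers (forward + backward)


def _same_pad(length: int, kernel: int) -> tuple[int, int]:
    # asymmetric padding for even kernels: extra sample on the right
    return (kernel - 1) // 2, kernel // 2


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, kernel: int):
    """x: (B, L, C); w: (kernel * C, F); length-preserving convolution."""
    B, L, C = x.shape
    pl, pr = _same_pad(L, kernel)
    xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
    idx = np.arange(L)[:, None] + np.arange(kernel)[None, :]
    cols = xp[:, idx, :].reshape(B, L, kernel * C)
    out = cols @ w + b
    return out, (cols, x.shape, kernel)


def _conv_backward(dout: np.ndarray, w: np.ndarray, cache):
    cols, x_shape, kernel = cache
    B, L, C = x_shape
    dw = np.einsum("blm,blf->mf", cols, dout)
    db = dout.sum(axis=(0, 1))
    dcols = (dout @ w.T).reshape(B, L, kernel, C)
    pl, pr = _same_pad(L, kernel)
    dxp = np.zeros((B, L + pl + pr, C))
    for k in range(kernel):
        dxp[:, k : k + L, :] += dcols[:, :, k, :]
    dx = dxp[:, pl : pl + L, :]
    return dx, dw, db


def _pool_forward(x: np.ndarray):
    """Ceiling-mode max pool, size 2 stride 2 (odd lengths padded with -inf)."""
    B, L, C = x.shape
    L2 = (L + 1) // 2
    if L % 2:
        x = np.concatenate([x, np.full((B, 1, C), -np.inf)], axis=1)
    pairs = x.reshape(B, L2, 2, C)
    arg = pairs.argmax(axis=2)
    out = np.take_along_axis(pairs, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (arg, L, L2)


def _pool_backward(dout: np.ndarray, cache):
    arg, L, L2 = cache
    B, _, C = dout.shape
    dpairs = np.zeros((B, L2, 2, C))
    np.put_along_axis(dpairs, arg[:, :, None, :], dout[:, :, None, :], axis=2)
    return dpairs.reshape(B, 2 * L2, C)[:, :L, :]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _init_params(spec: ModelSpec, rng: np.random.Generator) -> dict:
    params: dict[str, np.ndarray] = {}
    c_in = spec.input_axes
    li = 0
    for block in spec.blocks:
        for _ in range(block.n_conv_layers):
            fan_in = block.kernel_size * c_in
            params[f"conv{li}_w"] = rng.normal(0.0, math.sqrt(2.0 / fan_in), (fan_in, block.n_filters))
            params[f"conv{li}_b"] = np.zeros(block.n_filters)
            c_in = block.n_filters
            li += 1
    flat = last_conv_length(spec, spec.input_length) * c_in
    bound = math.sqrt(6.0 / (flat + spec.n_classes))
    params["fc_w"] = rng.uniform(-bound, bound, (flat, spec.n_classes))
    params["fc_b"] = np.zeros(spec.n_classes)
    return params


def _forward(
    spec: ModelSpec,
    params: dict,
    x: np.ndarray,
    *,
    train: bool = False,
    drop_rng: np.random.Generator | None = None,
):
    """Full forward pass.  Returns logits and a cache for backprop/grad-CAM."""
    caches = []
    h = x
    li = 0
    for block in spec.blocks:
        for _ in range(block.n_conv_layers):
            z, cache = _conv_forward(h, params[f"conv{li}_w"], params[f"conv{li}_b"], block.kernel_size)
            relu_mask = z > 0
            h = z * relu_mask
            caches.append(("conv", li, cache, relu_mask))
            li += 1
        if block.followed_by_pool:
            h, pcache = _pool_forward(h)
            caches.append(("pool", None, pcache, None))
    feature_maps = h  # designated layer: final conv block output
    if train and spec.dropout_rate > 0:
        keep = 1.0 - spec.dropout_rate
        mask = (drop_rng.uniform(size=h.shape) < keep) / keep
        h = h * mask
        caches.append(("dropout", None, mask, None))
    B = h.shape[0]
    flat = h.reshape(B, -1)
    logits = flat @ params["fc_w"] + params["fc_b"]
    caches.append(("fc", None, (flat, feature_maps.shape), None))
    return logits, feature_maps, caches


def _backward(spec: ModelSpec, params: dict, dlogits: np.ndarray, caches) -> dict:
    grads: dict[str, np.ndarray] = {}
    kind, _, (flat, fmap_shape), _ = caches[-1]
    assert kind == "fc"
    grads["fc_w"] = flat.T @ dlogits
    grads["fc_b"] = dlogits.sum(axis=0)
    dh = (dlogits @ params["fc_w"].T).reshape(fmap_shape)
    for kind, li, cache, relu_mask in reversed(caches[:-1]):
        if kind == "dropout":
            dh = dh * cache
        elif kind == "pool":
            dh = _pool_backward(dh, cache)
        else:  # conv (+ ReLU)
            dh = dh * relu_mask
            dh, dw, db = _conv_backward(dh, params[f"conv{li}_w"], cache)
            grads[f"conv{li}_w"] = dw
            grads[f"conv{li}_b"] = db
    return grads


@dataclass
class TrainedModel:
    """A trained classifier exposing the last conv block's activations and
    the gradient of a class score with respect to them."""

    spec: ModelSpec
    params: dict
    classes: list
    training_history: list[dict] = field(default_factory=list)
    checkpoint_epoch: int = -1
    warnings: list[str] = field(default_factory=list)
    score_mode: str = "logit"
    target: str = "activity"  # or "subject"
    standardize: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd) per axis

    @property
    def designated_layer(self) -> str:
        return f"conv{self.spec.n_conv_layers - 1}"

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        if self.standardize is not None:
            mean, sd = self.standardize
            x = (x - mean) / sd
        return x

    def scores(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Softmax probabilities for a stack of windows (n, L, C)."""
        x = self._prepare(np.asarray(x, dtype=np.float64))
        out = []
        for start in range(0, len(x), batch_size):
            logits, _, _ = _forward(self.spec, self.params, x[start : start + batch_size])
            out.append(_softmax(logits))
        return np.concatenate(out) if out else np.zeros((0, self.spec.n_classes))

    def predict_labels(self, x: np.ndarray) -> list:
        return [self.classes[i] for i in self.scores(x).argmax(axis=1)]

    def class_score_from_maps(self, feature_maps: np.ndarray, class_index: int) -> float:
        """Class score as a function of the designated-layer activations.

        Used as the independent route for finite-difference checks of
        :func:`activations_and_gradient` (dropout is inactive at inference,
        so the head is flatten -> dense -> optional softmax).
        """
        flat = np.asarray(feature_maps).reshape(1, -1)
        logits = flat @ self.params["fc_w"] + self.params["fc_b"]
        if self.score_mode == "prob":
            return float(_softmax(logits)[0, class_index])
        return float(logits[0, class_index])

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "params.npz", **self.params)
        sidecar = {
            "spec": self.spec.to_dict(),
            "classes": [c if isinstance(c, str) else int(c) for c in self.classes],
            "checkpoint_epoch": self.checkpoint_epoch,
            "score_mode": self.score_mode,
            "target": self.target,
            "warnings": self.warnings,
        }
        (path / "model.json").write_text(json.dumps(sidecar, indent=2) + "\n", encoding="utf-8")
        pd.DataFrame(self.training_history).to_csv(path / "history.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        sidecar = json.loads((path / "model.json").read_text(encoding="utf-8"))
        with np.load(path / "params.npz") as npz:
            params = {k: npz[k] for k in npz.files}
        history = pd.read_csv(path / "history.tsv", sep="\t").to_dict("records")
        return cls(
            spec=ModelSpec.from_dict(sidecar["spec"]),
            params=params,
            classes=sidecar["classes"],
            training_history=history,
            checkpoint_epoch=sidecar["checkpoint_epoch"],
            warnings=sidecar.get("warnings", []),
            score_mode=sidecar.get("score_mode", "logit"),
            target=sidecar.get("target", "activity"),
        )


def _targets_for_plan(dataset: Dataset, plan: SplitPlan) -> tuple[np.ndarray, list, str]:
    if plan.strategy == "BUI" or plan.params.get("target") == "subject":
        labels = dataset.subjects()
        used = np.concatenate([plan.train_indices, plan.val_indices])
        classes = sorted({int(labels[i]) for i in used})
        return labels, classes, "subject"
    return dataset.activities(), list(dataset.activity_vocabulary), "activity"


def train_model(
    spec: ModelSpec, dataset: Dataset, plan: SplitPlan, config: TrainConfig
) -> TrainedModel:
    """Train with Adam on categorical cross-entropy, checkpointing the epoch
    with the highest validation macro F1 (earliest epoch on ties).

    Class targets are activities for SD/SI plans and subject identifiers for
    BUI plans.  A class present in validation but absent from training is
    recorded as a warning (it depresses macro metrics but is not an error).
    """
    if plan.n_train == 0:
        raise ValueError("training set is empty")
    labels, classes, target = _targets_for_plan(dataset, plan)
    if len(classes) != spec.n_classes:
        raise ValueError(
            f"spec expects {spec.n_classes} classes but the plan's targets have {len(classes)}"
        )
    index = {c: i for i, c in enumerate(classes)}
    x_all = dataset.values()
    if x_all.shape[1] != spec.input_length or x_all.shape[2] != spec.input_axes:
        raise ValueError(
            f"windows have shape {x_all.shape[1:]} but spec expects "
            f"({spec.input_length}, {spec.input_axes})"
        )

    xt = x_all[plan.train_indices]
    yt = np.array([index[labels[i] if target == "activity" else int(labels[i])] for i in plan.train_indices])
    xv = x_all[plan.val_indices]
    yv_labels = [labels[i] if target == "activity" else int(labels[i]) for i in plan.val_indices]

    warnings: list[str] = []
    missing_in_train = sorted(set(yv_labels) - {classes[i] for i in np.unique(yt)}, key=str)
    if missing_in_train:
        warnings.append(
            f"classes present in validation but absent from training: {missing_in_train}"
        )

    stats = None
    if config.standardize:
        mean = xt.mean(axis=(0, 1), keepdims=True)
        sd = xt.std(axis=(0, 1), keepdims=True) + 1e-8
        stats = (mean, sd)
        xt = (xt - mean) / sd
        xv = (xv - mean) / sd

    rng = np.random.default_rng(config.seed)
    params = _init_params(spec, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(val) for k, val in params.items()}
    step = 0

    model = TrainedModel(
        spec=spec,
        params=copy.deepcopy(params),
        classes=classes,
        warnings=warnings,
        score_mode=config.score_mode,
        target=target,
        standardize=stats,
    )
    best_f1 = -1.0

    n = len(xt)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = xt[batch], yt[batch]
            logits, _, caches = _forward(spec, params, xb, train=True, drop_rng=rng)
            probs = _softmax(logits)
            eps = 1e-12
            epoch_loss += -np.log(probs[np.arange(len(yb)), yb] + eps).sum()
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = _backward(spec, params, dlogits, caches)
            step += 1
            lr_t = config.learning_rate * math.sqrt(1 - config.beta2**step) / (1 - config.beta1**step)
            for k in params:
                m[k] = config.beta1 * m[k] + (1 - config.beta1) * grads[k]
                v[k] = config.beta2 * v[k] + (1 - config.beta2) * grads[k] ** 2
                params[k] = params[k] - lr_t * m[k] / (np.sqrt(v[k]) + config.eps)

        val_pred: list = []
        for start in range(0, len(xv), 512):
            logits, _, _ = _forward(spec, params, xv[start : start + 512])
            val_pred.extend(classes[i] for i in logits.argmax(axis=1))
        f1 = macro_f1(yv_labels, val_pred, classes) if len(xv) else 0.0
        model.training_history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n, 1), "val_macro_f1": f1}
        )
        if f1 > best_f1:
            best_f1 = f1
            model.params = copy.deepcopy(params)
            model.checkpoint_epoch = epoch
    return model


def predict(model: TrainedModel, windows: Sequence[SignalWindow]) -> list[Prediction]:
    """Softmax scores and argmax class for each window (ties -> lowest index)."""
    spec = model.spec
    for w in windows:
        if w.values.shape != (spec.input_length, spec.input_axes):
            raise ValueError(
                f"window shape {w.values.shape} does not match expected "
                f"({spec.input_length}, {spec.input_axes})"
            )
    if not windows:
        return []
    scores = model.scores(np.stack([w.values for w in windows]))
    return [
        Prediction(class_scores=s, predicted_class=int(s.argmax())) for s in scores
    ]


def activations_and_gradient(
    model: TrainedModel, window: SignalWindow, class_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Designated-layer feature maps and class-score gradient for one window.

    Returns ``(A, G)`` where ``A[i, k]`` is the activation of feature map k
    at temporal position i (final conv block output) and ``G[i, k]`` is
    ``d y^c / d A[i, k]`` for the requested class, with ``y^c`` the
    pre-softmax class score by default (``score_mode="prob"`` uses the
    softmax output instead).  Both matrices have shape
    ``(last_conv_length(spec, input_length), n_filters)``.
    """
    spec = model.spec
    if not 0 <= class_index < spec.n_classes:
        raise ValueError(f"class_index {class_index} out of range [0, {spec.n_classes})")
    if window.values.shape != (spec.input_length, spec.input_axes):
        raise ValueError(
            f"window shape {window.values.shape} does not match expected "
            f"({spec.input_length}, {spec.input_axes})"
        )
    x = model._prepare(window.values[None, :, :].astype(np.float64))
    logits, feature_maps, _ = _forward(spec, model.params, x)
    if model.score_mode == "prob":
        p = _softmax(logits)[0]
        dlogits = -p[class_index] * p
        dlogits[class_index] += p[class_index]
        dlogits = dlogits[None, :]
    else:
        dlogits = np.zeros((1, spec.n_classes))
        dlogits[0, class_index] = 1.0
    # inference-mode head is flatten -> dense, so the gradient w.r.t. the
    # designated layer is the dense backprojection reshaped to map layout
    dflat = dlogits @ model.params["fc_w"].T
    grad = dflat.reshape(feature_maps.shape)
    return feature_maps[0], grad[0]
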