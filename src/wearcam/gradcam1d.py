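"""Grad-CAM for 1D convolutional time-series classifiers.

The saliency pipeline pools the class-score gradients over time to obtain
one importance weight per feature map,

    alpha_k = (1/Z) * sum_i  dy^c / dA[i, k],

forms the weighted combination ``sum_k alpha_k A[:, k]`` over the
designated layer's activations, and — in the time-series adaptation — keeps
negative contributions (no ReLU by default; the original image-domain ReLU
variant is available behind a flag), min-max normalises the result into
[0, 1], and upsamples it to the input length with nearest-neighbour
interpolation so the coarse bands of importance remain crisp, piecewise-
constant blocks instead of being smoothed away.

Normalisation order note: nearest-neighbour interpolation introduces no new
values, so normalising before or after upsampling yields the same heatmap;
this package normalises first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from wearcam.convnet import TrainedModel, activations_and_gradient
from wearcam.signal_data import SignalWindow

__all__ = [
    "ImportanceWeights",
    "Heatmap",
    "ThresholdMask",
    "importance_weights",
    "combine_maps",
    "normalize_heatmap",
    "upsample_nearest",
    "explain",
    "threshold_mask",
    "render_overlay",
]

DEFAULT_TAU = 0.7


@dataclass
class ImportanceWeights:
    """Per-feature-map weights alpha^c_k (time-averaged class-score gradients)."""

    alpha: np.ndarray
    class_index: int = 0


@dataclass
class Heatmap:
    """Per-timestep importance in [0, 1] at the input window's length."""

    values: np.ndarray
    class_index: int
    source_resolution: int  # temporal positions of the designated layer

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ThresholdMask:
    mask: np.ndarray  # boolean, mask[i] <=> heatmap[i] >= tau
    tau: float = DEFAULT_TAU


def importance_weights(gradient: np.ndarray, class_index: int = 0) -> ImportanceWeights:
    """Global average pooling of the gradient over the time dimension only.

    ``gradient`` has shape (positions Z, maps K); alpha_k is the mean of
    column k.
    """
    gradient = np.asarray(gradient, dtype=np.float64)
    if gradient.size == 0:
        raise ValueError("gradient matrix is empty")
    if gradient.ndim != 2:
        raise ValueError(f"gradient must be 2-D (positions x maps), got shape {gradient.shape}")
    return ImportanceWeights(alpha=gradient.mean(axis=0), class_index=class_index)


def combine_maps(
    weights: ImportanceWeights, maps: np.ndarray, *, relu: bool = False
) -> np.ndarray:
    """Weighted combination ``sum_k alpha_k A[:, k]`` over feature maps.

    Negative values are preserved by default (the time-series adaptation);
    ``relu=True`` restores the image-domain convention of clipping them.
    """
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim != 2:
        raise ValueError(f"feature maps must be 2-D (positions x maps), got shape {maps.shape}")
    if maps.shape[1] != len(weights.alpha):
        raise ValueError(
            f"{len(weights.alpha)} weights cannot combine {maps.shape[1]} feature maps"
        )
    raw = maps @ weights.alpha
    return np.maximum(raw, 0.0) if relu else raw


def normalize_heatmap(raw: np.ndarray) -> np.ndarray:
    """Min-max normalisation to [0, 1]; a constant input maps to all zeros
    (no contrast reads as no importance)."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def upsample_nearest(values: np.ndarray, target_length: int) -> np.ndarray:
    """Nearest-neighbour upsampling: ``out[j] = values[floor(j * L / N)]``.

    Produces piecewise-constant blocks; the output value set is a subset of
    the input's.  Also valid for N < L (nearest-neighbour downsampling).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot upsample an empty vector")
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    src = np.floor(np.arange(target_length) * len(values) / target_length).astype(int)
    return values[src]


def explain(
    model: TrainedModel,
    window: SignalWindow,
    class_index: int,
    *,
    relu: bool = False,
) -> Heatmap:
    """End-to-end 1D grad-CAM heatmap for one window and class.

    Equivalent to the composition ``upsample_nearest(normalize_heatmap(
    combine_maps(importance_weights(G), A)), N)`` with (A, G) from
    :func:`wearcam.convnet.activations_and_gradient`.
    """
    maps, grad = activations_and_gradient(model, window, class_index)
    weights = importance_weights(grad, class_index)
    raw = combine_maps(weights, maps, relu=relu)
    normalized = normalize_heatmap(raw)
    values = upsample_nearest(normalized, window.n_timesteps)
    return Heatmap(values=values, class_index=class_index, source_resolution=maps.shape[0])


def threshold_mask(heatmap: Heatmap, tau: float = DEFAULT_TAU) -> ThresholdMask:
    """Boolean mask of timesteps with importance >= tau (inclusive boundary)."""
    if not 0 <= tau <= 1:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    return ThresholdMask(mask=heatmap.values >= tau, tau=tau)


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def render_overlay(
    window: SignalWindow,
    heatmap: Heatmap,
    tau: float | None = None,
    *,
    path: str | Path,
    events: list | None = None,
) -> Path:
    """Plot the window's axes with heatmap shading and save the figure.

    With ``tau`` given, only super-threshold runs are shaded (one band per
    maximal run of the mask); otherwise a continuous alpha shading shows
    the full heatmap, where nearest-neighbour banding is visible as
    constant-colour blocks.  ``events`` (objects with ``timestep``
    attributes) are marked with vertical lines.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(heatmap) != window.n_timesteps:
        raise ValueError(
            f"heatmap length {len(heatmap)} does not match window length {window.n_timesteps}"
        )
    t = window.times()
    fig, ax = plt.subplots(figsize=(9, 4))
    for axis in range(window.n_axes):
        ax.plot(t, window.values[:, axis], lw=0.9, label="xyz"[axis] if axis < 3 else f"axis{axis}")
    if tau is not None:
        for start, stop in _mask_runs(heatmap.values >= tau):
            ax.axvspan(t[start], t[min(stop, len(t) - 1)], color="crimson", alpha=0.25, lw=0)
    else:
        for j, v in enumerate(heatmap.values):
            if v > 0:
                ax.axvspan(
                    t[j],
                    t[j] + window.sampling_interval_s,
                    color="crimson",
                    alpha=0.35 * float(v),
                    lw=0,
                )
    for ev in events or []:
        ax.axvline(ev.timestep / window.sample_rate_hz, color="k", ls="--", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("acceleration (m/s²)")
    ax.set_title(f"{window.activity} — subject {window.subject}, class {heatmap.class_index}")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
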