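"""First-layer Grad-CAM saliency and its aggregation into day x behavior
importance maps.

For a trained classifier and one input window, let A^k be the k-th post-ReLU
feature map of the *first* convolutional layer (with "same" padding these
share the input's day x channel grid, so no upsampling is needed) and Y the
positive-class score.  The neuron-importance weights are global average
pooled gradients,

    alpha_k = (1/Z) * sum_ij  dY / dA^k_ij        (Z = cells per map)

and the saliency map is the rectified weighted combination

    L = ReLU( sum_k alpha_k * A^k ),

a non-negative day-lag x channel heatmap.  Targeting the first layer keeps
the map aligned with the raw input features: each cell scores how much that
(day, behavior) cell contributed to predicting an event.

Aggregation normalizes each map to unit sum (dropping all-zero maps),
averages within subject and then across subjects, and reports per-channel
and per-day-lag marginals plus a descending channel ranking.  Day axes are
labelled as lags -1 .. -W, lag -1 being the day immediately before the
predicted day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import CNNPredictor
from .preprocess import WindowSample

__all__ = [
    "SaliencyMap",
    "ImportanceSummary",
    "gradcam_first_layer",
    "gradcam_batch",
    "input_gradient_batch",
    "first_layer_alphas",
    "aggregate_saliency",
    "plot_importance",
]


@dataclass
class SaliencyMap:
    """Non-negative W x C Grad-CAM heatmap for one window sample, aligned to
    the input grid (row i = day-lag -(W - i), column = behavior channel)."""

    values: np.ndarray  # (W, C), >= 0
    subject_id: str
    target_day: int
    positive_class: int = 1


@dataclass
class ImportanceSummary:
    """Mean normalized saliency across samples and subjects."""

    mean_map: np.ndarray  # (W, C)
    channel_totals: np.ndarray  # (C,) column sums of mean_map
    lag_totals: np.ndarray  # (W,) row sums of mean_map
    channel_ranking: list[int]  # channel indices, descending importance
    lag_labels: list[int]  # -W .. -1, aligned to mean_map rows
    n_maps: int
    n_dropped: int  # all-zero maps excluded from the average
    channel_names: tuple[str, ...] | None = None


def gradcam_first_layer(
    predictor: CNNPredictor, sample: WindowSample | np.ndarray
) -> SaliencyMap:
    """Grad-CAM heatmap of the positive-class score on the first conv layer.

    The gradient is taken with respect to the pre-sigmoid score; since the
    sigmoid has strictly positive slope this scales all alpha_k by a common
    positive factor and leaves the (normalized) map unchanged.
    """
    maps, sal = gradcam_batch(predictor, [sample])
    return sal[0]


def gradcam_batch(
    predictor: CNNPredictor, samples: Sequence[WindowSample | np.ndarray]
) -> tuple[np.ndarray, list[SaliencyMap]]:
    """Vectorized Grad-CAM over many samples.

    Returns the raw (N, W, C) stack of heatmaps and the wrapped
    :class:`SaliencyMap` list.
    """
    if not predictor.fitted:
        raise ValueError("Grad-CAM requires a trained predictor")
    xs, sids, days = [], [], []
    for s in samples:
        if isinstance(s, WindowSample):
            xs.append(s.X.astype(float)[..., None])
            sids.append(s.subject_id)
            days.append(s.target_day)
        else:
            arr = np.asarray(s, dtype=float)
            xs.append(arr if arr.ndim == 3 else arr[..., None])
            sids.append("")
            days.append(-1)
    x = np.stack(xs)
    if x.shape[1:3] != predictor.input_shape:
        raise ValueError(
            f"sample shape {x.shape[1:3]} does not match model input "
            f"{predictor.input_shape}"
        )
    acts, grads = predictor.net.grad_wrt_first_maps(x)  # (N, W, C, K) each
    alpha = grads.mean(axis=(1, 2))  # (N, K): average-pooled gradients
    heat = np.einsum("nhwk,nk->nhw", acts, alpha, optimize=True)
    heat = np.maximum(heat, 0.0)
    out = [
        SaliencyMap(values=heat[i], subject_id=sids[i], target_day=days[i])
        for i in range(len(heat))
    ]
    return heat, out


def input_gradient_batch(
    predictor: CNNPredictor, samples: Sequence[WindowSample | np.ndarray]
) -> tuple[np.ndarray, list[SaliencyMap]]:
    """Input-gradient saliency: |d(score)/d(input cell)| per (day, channel).

    A sharper alternative to first-layer Grad-CAM for these inputs: Grad-CAM
    condenses each filter's gradient to one global scalar and re-introduces
    spatial structure only through the activation maps, which on sparse
    binary windows mostly echo where *any* event occurred.  The raw input
    gradient keeps the gradient's own spatial structure and localizes the
    evidence the model actually uses (it agrees with per-channel occlusion
    where Grad-CAM does not); see the methods note.
    """
    if not predictor.fitted:
        raise ValueError("input-gradient saliency requires a trained predictor")
    xs, sids, days = [], [], []
    for s in samples:
        if isinstance(s, WindowSample):
            xs.append(s.X.astype(float)[..., None])
            sids.append(s.subject_id)
            days.append(s.target_day)
        else:
            arr = np.asarray(s, dtype=float)
            xs.append(arr if arr.ndim == 3 else arr[..., None])
            sids.append("")
            days.append(-1)
    x = np.stack(xs)
    if x.shape[1:3] != predictor.input_shape:
        raise ValueError(
            f"sample shape {x.shape[1:3]} does not match model input "
            f"{predictor.input_shape}"
        )
    heat = np.abs(predictor.net.grad_wrt_input(x)[..., 0])
    out = [
        SaliencyMap(values=heat[i], subject_id=sids[i], target_day=days[i])
        for i in range(len(heat))
    ]
    return heat, out


def first_layer_alphas(
    predictor: CNNPredictor, sample: WindowSample | np.ndarray
) -> np.ndarray:
    """The alpha_k weights for one sample (used by gradient-oracle checks)."""
    if isinstance(sample, WindowSample):
        x = sample.X.astype(float)[None, ..., None]
    else:
        arr = np.asarray(sample, dtype=float)
        x = arr[None, ..., None] if arr.ndim == 2 else arr[None]
    _, grads = predictor.net.grad_wrt_first_maps(x)
    return grads[0].mean(axis=(0, 1))


def aggregate_saliency(
    maps: Sequence[SaliencyMap],
    normalize: bool = True,
    channel_names: Sequence[str] | None = None,
) -> ImportanceSummary:
    """Average saliency maps into one importance summary.

    Each map is normalized to sum to 1 (all-zero maps are dropped and
    counted); normalized maps are averaged within subject first, then the
    subject means are averaged, so prolific subjects do not dominate.
    """
    if not maps:
        raise ValueError("need at least one saliency map")
    shape = maps[0].values.shape
    for s in maps:
        if s.values.shape != shape:
            raise ValueError("saliency maps have mismatched shapes")
    per_subject: dict[str, list[np.ndarray]] = {}
    dropped = 0
    for s in maps:
        total = s.values.sum()
        if normalize:
            if total <= 0:
                dropped += 1
                continue
            v = s.values / total
        else:
            v = s.values
        per_subject.setdefault(s.subject_id, []).append(v)
    if not per_subject:
        raise ValueError("all saliency maps were zero; nothing to aggregate")
    subject_means = [np.mean(vs, axis=0) for vs in per_subject.values()]
    mean_map = np.mean(subject_means, axis=0)
    channel_totals = mean_map.sum(axis=0)
    lag_totals = mean_map.sum(axis=1)
    ranking = list(np.argsort(-channel_totals, kind="stable"))
    w = shape[0]
    return ImportanceSummary(
        mean_map=mean_map,
        channel_totals=channel_totals,
        lag_totals=lag_totals,
        channel_ranking=[int(i) for i in ranking],
        lag_labels=list(range(-w, 0)),
        n_maps=len(maps) - dropped,
        n_dropped=dropped,
        channel_names=tuple(channel_names) if channel_names is not None else None,
    )


def plot_importance(summary: ImportanceSummary, path=None, title: str = ""):
    """Render the mean day-lag x channel map as a heatmap (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(summary.mean_map, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(summary.lag_labels)))
    ax.set_yticklabels([f"Day {l}" for l in summary.lag_labels])
    if summary.channel_names:
        ax.set_xticks(range(len(summary.channel_names)))
        ax.set_xticklabels(summary.channel_names, rotation=60, ha="right", fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="mean normalized saliency")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
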