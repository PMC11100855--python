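"""The convolutional next-day classifier and the prevalence baseline.

One model is trained per subject x target x window length.  The architecture
is fixed (two conv blocks with batch normalization and 2x2 max pooling, a
64-unit dense layer, dropout 0.5, sigmoid output) and trained with Adam on
binary cross-entropy — 50 epochs and batch size 32 by default.  The baseline
predictor draws i.i.d. Bernoulli predictions at the training-set label
prevalence: the "guess from historical frequency" reference the permutation
null formalizes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .nn import SmallCNN, TrainingDivergedError
from .preprocess import WindowSample, samples_to_arrays

__all__ = [
    "ModelSpec",
    "CNNPredictor",
    "BaselinePredictor",
    "build_model",
    "train",
    "predict_proba",
    "predict_label",
    "fit_baseline",
    "baseline_predict",
    "save_predictor",
    "load_predictor",
    "TrainingDivergedError",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyperparameters (defaults as published)."""

    conv1_filters: int = 32
    conv1_kernel: tuple[int, int] = (3, 3)
    conv2_filters: int = 64
    conv2_kernel: tuple[int, int] = (2, 2)
    dense_units: int = 64
    dropout_rate: float = 0.5
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3


@dataclass
class CNNPredictor:
    """An (un)trained CNN bound to a fixed input shape ``(W, C)``."""

    input_shape: tuple[int, int]
    spec: ModelSpec
    net: SmallCNN
    fitted: bool = False
    history: list[float] = field(default_factory=list)


def build_model(
    input_shape: tuple[int, int], seed: int = 0, **overrides
) -> CNNPredictor:
    """Assemble the untrained classifier for windows of shape ``(W, C)``.

    Both spatial dimensions must be >= 4: with "same"-padded convolutions and
    two floor-divided 2x2 poolings, a dimension below 4 would collapse to
    zero before the flatten.  The flattened width is deterministic:
    ``(W//4) * (C//4)`` — e.g. 7x8 -> 1x2x64 = 128, 14x9 -> 3x2x64 = 384.
    """
    spec = ModelSpec(**overrides)
    h, w = input_shape
    if h < 4 or w < 4:
        raise ValueError(
            f"input shape {input_shape} unsupported: two 2x2 floor-poolings need "
            "both spatial dims >= 4 (a 3-day window would pool to zero rows)"
        )
    net = SmallCNN(
        (h, w),
        conv1_filters=spec.conv1_filters,
        conv1_kernel=spec.conv1_kernel,
        conv2_filters=spec.conv2_filters,
        conv2_kernel=spec.conv2_kernel,
        dense_units=spec.dense_units,
        dropout_rate=spec.dropout_rate,
        seed=seed,
    )
    return CNNPredictor(input_shape=(h, w), spec=spec, net=net)


def _as_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, tuple) and len(samples) == 2:
        x, y = samples
        return np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    return samples_to_arrays(list(samples))


def train(
    predictor: CNNPredictor,
    train_samples: Sequence[WindowSample] | tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    epochs: int | None = None,
) -> CNNPredictor:
    """Fit in place and return the predictor.

    Same data + same seed reproduces the same parameters (per platform).
    Per-epoch mean loss lands in ``predictor.history``; a non-finite loss
    aborts with :class:`TrainingDivergedError`.
    """
    x, y = _as_arrays(train_samples)
    if len(x) == 0:
        raise ValueError("cannot train on an empty sample list")
    if x.shape[1:3] != predictor.input_shape:
        raise ValueError(
            f"sample shape {x.shape[1:3]} does not match model input "
            f"{predictor.input_shape}"
        )
    predictor.net.fit(
        x,
        y,
        epochs=predictor.spec.epochs if epochs is None else epochs,
        batch_size=predictor.spec.batch_size,
        learning_rate=predictor.spec.learning_rate,
        seed=seed,
    )
    predictor.history = list(predictor.net.history)
    predictor.fitted = True
    return predictor


def predict_proba(
    predictor: CNNPredictor,
    samples: Sequence[WindowSample] | tuple[np.ndarray, np.ndarray] | np.ndarray,
) -> np.ndarray:
    """Positive-class probabilities in [0, 1] (dropout off, batch norm on
    stored running statistics)."""
    if isinstance(samples, np.ndarray):
        x = samples.astype(float)
        if x.ndim == 3:
            x = x[..., None]
    else:
        x, _ = _as_arrays(samples)
    if x.shape[1:3] != predictor.input_shape:
        raise ValueError(
            f"sample shape {x.shape[1:3]} does not match model input "
            f"{predictor.input_shape}"
        )
    return predictor.net.predict_proba(x)


def predict_label(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: 1 iff score >= threshold (ties go to the positive class)."""
    return (np.asarray(scores) >= threshold).astype(int)


# ---------------------------------------------------------------------------
# Prevalence baseline


@dataclass(frozen=True)
class BaselinePredictor:
    """Predicts i.i.d. Bernoulli(p_hat) where p_hat is the training-set
    label prevalence — prediction from historical frequency alone."""

    prevalence: float

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")


def fit_baseline(train_labels: Sequence[int] | np.ndarray) -> BaselinePredictor:
    y = np.asarray(train_labels, dtype=float)
    if y.size == 0:
        raise ValueError("need at least one training label")
    return BaselinePredictor(prevalence=float(y.mean()))


def baseline_predict(
    baseline: BaselinePredictor, n: int, seed: int = 0
) -> np.ndarray:
    """n i.i.d. Bernoulli(p_hat) binary predictions."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    return (rng.random(n) < baseline.prevalence).astype(int)


# ---------------------------------------------------------------------------
# Serialization: parameters as .npz + spec as JSON sidecar


def save_predictor(predictor: CNNPredictor, path: str | Path) -> None:
    """Write a versioned bundle: ``<path>.npz`` (parameters + running stats)
    and ``<path>.json`` (spec, input shape, training history)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **predictor.net.state_arrays())
    meta = {
        "format_version": 1,
        "input_shape": list(predictor.input_shape),
        "spec": asdict(predictor.spec),
        "fitted": predictor.fitted,
        "history": predictor.history,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_predictor(path: str | Path) -> CNNPredictor:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_d = dict(meta["spec"])
    for key in ("conv1_kernel", "conv2_kernel"):
        spec_d[key] = tuple(spec_d[key])
    predictor = build_model(tuple(meta["input_shape"]), **spec_d)
    with np.load(path.with_suffix(".npz")) as state:
        predictor.net.load_state_arrays({k: state[k].copy() for k in state.files})
    predictor.fitted = bool(meta["fitted"])
    predictor.history = list(meta.get("history", []))
    return predictor
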