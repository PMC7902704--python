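"""A small LeNet-style CNN for multi-view tree images.

Architecture (for 150 x 100 x 1 inputs): four 3x3 convolution blocks with
8/16/32/64 filters and ReLU, each followed by 2x2 max pooling, a 0.3
dropout after the third convolution, then flatten, a 128-unit ReLU dense
layer, a 0.5 dropout, and a softmax output over the species classes.
Trained with categorical cross-entropy and Adam; pixels are scaled to
[0, 1]; the predicted species is the class of highest probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._nn import (
    Adam,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2D,
    Sequential,
    softmax_cross_entropy,
)
from .projection import GrayImage

__all__ = [
    "CNNConfig",
    "TrainResult",
    "build_model",
    "train",
    "predict",
    "images_to_array",
    "encode_labels",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters of the classifier.

    ``pool_stride`` defaults to 2 so each pooling stage halves the feature
    map; a stride-1 pooling variant remains available for experimentation
    but blows up the flatten layer.
    """

    input_shape: tuple[int, int, int] = (150, 100, 1)
    conv_filters: tuple[int, ...] = (8, 16, 32, 64)
    kernel: int = 3
    pool: int = 2
    pool_stride: int = 2
    conv_padding: str = "same"
    dropout_after_conv3: float = 0.3
    dropout_after_dense: float = 0.5
    dense_units: int = 128
    n_classes: int = 7
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(f < 1 for f in self.conv_filters):
            raise ValueError("all conv filter counts must be >= 1")
        for r in (self.dropout_after_conv3, self.dropout_after_dense):
            if not 0 <= r < 1:
                raise ValueError(f"dropout rate {r} must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


@dataclass
class TrainResult:
    """Fitted model plus its training history and provenance."""

    model: Sequential
    history: dict[str, list[float]] = field(default_factory=dict)
    seed: int = 0
    config: CNNConfig = field(default_factory=CNNConfig)

    def history_to_json(self, path: str | Path) -> None:
        payload = {
            "history": self.history,
            "seed": self.seed,
            "config": _config_dict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _config_dict(config: CNNConfig) -> dict:
    d = asdict(config)
    d["input_shape"] = list(d["input_shape"])
    d["conv_filters"] = list(d["conv_filters"])
    return d


def build_model(config: CNNConfig = CNNConfig()) -> Sequential:
    """Assemble the network; raises if the input is too small to pool four times."""
    f1, f2, f3, f4 = config.conv_filters
    layers = [
        Conv2D(f1, config.kernel, config.conv_padding, activation="relu"),
        MaxPool2D(config.pool, config.pool_stride),
        Conv2D(f2, config.kernel, config.conv_padding, activation="relu"),
        MaxPool2D(config.pool, config.pool_stride),
        Conv2D(f3, config.kernel, config.conv_padding, activation="relu"),
        MaxPool2D(config.pool, config.pool_stride),
        Dropout(config.dropout_after_conv3),
        Conv2D(f4, config.kernel, config.conv_padding, activation="relu"),
        MaxPool2D(config.pool, config.pool_stride),
        Flatten(),
        Dense(config.dense_units, activation="relu"),
        Dropout(config.dropout_after_dense),
        Dense(config.n_classes, activation="softmax"),
    ]
    try:
        return Sequential(layers, input_shape=config.input_shape, seed=config.seed)
    except ValueError as exc:
        raise ValueError(
            f"input shape {config.input_shape} cannot pass four pooling stages: {exc}"
        ) from exc


def encode_labels(labels: Sequence[str], label_order: Sequence[str]) -> np.ndarray:
    """One-hot encode species labels in the given class order."""
    index = {lab: i for i, lab in enumerate(label_order)}
    onehot = np.zeros((len(labels), len(label_order)), dtype=np.float32)
    for row, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"label {lab!r} not in label set {list(label_order)}")
        onehot[row, index[lab]] = 1.0
    return onehot


def images_to_array(images: Sequence[GrayImage]) -> np.ndarray:
    """Stack images into an (N, H, W, 1) float32 array scaled to [0, 1]."""
    arr = np.stack([img.pixels for img in images]).astype(np.float32) / 255.0
    return arr[..., None]


def train(
    model: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: CNNConfig = CNNConfig(),
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainResult:
    """Train with Adam on softmax cross-entropy; seeded and reproducible.

    ``y_train`` is one-hot.  Zero epochs returns the model untouched with an
    empty history.  A NaN loss aborts with diagnostics rather than silently
    producing a broken model.
    """
    n = x_train.shape[0]
    if n == 0:
        raise ValueError("training set is empty")
    if y_train.shape != (n, model.output_shape[0]):
        raise ValueError(
            f"labels shape {y_train.shape} incompatible with "
            f"{n} samples x {model.output_shape[0]} classes"
        )
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if validation is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []
    if config.epochs == 0:
        return TrainResult(model=model, history={}, seed=config.seed, config=config)

    rng = np.random.default_rng(config.seed)
    dropout_rng = np.random.default_rng(config.seed + 1)
    optimizer = Adam(learning_rate=config.learning_rate)
    bs = config.batch_size
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, train=True, rng=dropout_rng)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch}, batch {start // bs} "
                    f"(lr={config.learning_rate}, batch_size={bs}); "
                    "reduce the learning rate or check input scaling"
                )
            model.backward(dlogits)
            optimizer.step(model.params_grads())
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == yb.argmax(axis=1)).sum())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(correct / n)
        if validation is not None:
            xv, yv = validation
            vlogits = model.forward(xv, train=False)
            vloss, _ = softmax_cross_entropy(vlogits, yv)
            history["val_loss"].append(vloss)
            history["val_accuracy"].append(
                float((vlogits.argmax(axis=1) == yv.argmax(axis=1)).mean())
            )
    return TrainResult(model=model, history=history, seed=config.seed, config=config)


def predict(
    model: Sequential,
    x: np.ndarray,
    label_order: Sequence[str] | None = None,
    batch_size: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-image class probabilities and hard labels.

    Probabilities are a softmax simplex; the hard label is the argmax, ties
    resolving to the lowest class index.  Returns (probs, labels) where
    labels are indices, or species strings when ``label_order`` is given.
    """
    probs = np.concatenate(
        [model.predict_proba(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    )
    idx = probs.argmax(axis=1)
    if label_order is not None:
        labels = np.array([label_order[i] for i in idx])
    else:
        labels = idx
    return probs, labels


def save_weights(model: Sequential, path: str | Path) -> None:
    np.savez(path, *(p for p, _ in model.params_grads()))


def load_weights(model: Sequential, path: str | Path) -> None:
    with np.load(path) as data:
        keys = sorted(data.files, key=lambda k: int(k.rsplit("_", 1)[1]))
        model.set_weights([data[k] for k in keys])
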