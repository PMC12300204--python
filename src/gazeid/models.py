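"""The two identification classifiers and their training configuration.

Two fixed architectures are used:

* ``lstm`` — two recurrent layers of 64 units with a 0.5-dropout layer
  between them, a 64-unit dense layer and a softmax output; consumes the
  100-step x 7-channel time-series feature matrices.
* ``dense`` — three hidden layers of 100, 75 and 50 relu units and a softmax
  output; consumes the 16-value statistical vectors.

Both train with Adam (learning rate 0.001) on categorical cross-entropy for
a fixed number of epochs with early stopping disabled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import ValidationError

KINDS = ("lstm", "dense")


@dataclass(frozen=True)
class ModelSpec:
    kind: str
    num_labels: int
    lstm_units: int = 64
    dense_hidden: tuple[int, int, int] = (100, 75, 50)
    dropout_rate: float = 0.5
    n_channels: int = 7
    n_stats: int = 16

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"kind must be one of {KINDS}")
        if self.num_labels < 2:
            raise ValidationError("num_labels must be >= 2")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 150
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


class Classifier:
    """A built (possibly trained) network plus its spec and loss trace."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        if spec.kind == "lstm":
            self.net = nn.LSTMClassifier(
                n_channels=spec.n_channels,
                n_labels=spec.num_labels,
                n_units=spec.lstm_units,
                dropout=spec.dropout_rate,
                seed=seed,
            )
        else:
            self.net = nn.DenseClassifier(
                n_in=spec.n_stats,
                n_labels=spec.num_labels,
                hidden=spec.dense_hidden,
                seed=seed,
            )
        self.loss_trace: list[float] = []

    def expected_input(self) -> tuple[int, ...]:
        if self.spec.kind == "lstm":
            return (100, self.spec.n_channels)
        return (self.spec.n_stats,)


def build_model(spec: ModelSpec, seed: int = 0) -> Classifier:
    """Instantiate the network described by ``spec`` with seeded weights."""
    return Classifier(spec, seed=seed)


def train(model: Classifier, x: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> list[float]:
    """Train in place for exactly ``cfg.epochs`` epochs; returns the loss trace."""
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if x.shape[1:] != model.expected_input():
        raise ValidationError(
            f"feature shape {x.shape[1:]} does not match model input {model.expected_input()}"
        )
    present = np.unique(y)
    if len(present) != model.spec.num_labels or present.min() < 0 or present.max() >= model.spec.num_labels:
        missing = sorted(set(range(model.spec.num_labels)) - set(present.tolist()))
        raise ValidationError(f"classes absent from training data: {missing}")
    model.loss_trace = nn.fit(
        model.net, x, y,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.learning_rate,
        seed=cfg.seed,
    )
    return model.loss_trace


def predict_proba(model: Classifier, x: np.ndarray) -> np.ndarray:
    """Per-sample class-probability vectors (rows sum to 1)."""
    x = np.asarray(x, dtype=np.float32)
    if x.shape[1:] != model.expected_input():
        raise ValidationError(
            f"feature shape {x.shape[1:]} does not match model input {model.expected_input()}"
        )
    return model.net.predict_proba(x).astype(np.float64)


def save_checkpoint(model: Classifier, path) -> None:
    """Parameters as NPZ with a JSON sidecar carrying the spec."""
    np.savez(path, **model.net.params)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(asdict(model.spec), fh, indent=2)


def load_checkpoint(path) -> Classifier:
    sidecar = str(path) + ".json"
    with open(sidecar) as fh:
        raw = json.load(fh)
    raw["dense_hidden"] = tuple(raw["dense_hidden"])
    model = Classifier(ModelSpec(**raw))
    with np.load(path) as data:
        for k in model.net.params:
            model.net.params[k] = data[k]
    return model
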