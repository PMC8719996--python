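"""Three-layer feedforward network (logistic sigmoid on both layers) and its
error back-propagation training.

Training minimises squared error with online (per-sample) gradient descent
and a seeded per-epoch shuffle; it stops when the epoch's mean squared error
reaches ``error_goal`` or at ``max_epochs``.  A full-batch mode exists for
diagnostics.  Class decisions are the argmax of the output activations,
ties broken toward the lower index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .util import ValidationError, as_rng

__all__ = [
    "BPNNModel",
    "TrainConfig",
    "TrainHistory",
    "DivergenceError",
    "init_network",
    "forward",
    "hidden_activations",
    "sample_loss",
    "gradients",
    "mse",
    "train_backprop",
    "predict_labels",
    "model_to_json",
    "model_from_json",
]

MAX_HIDDEN = 64


class DivergenceError(RuntimeError):
    pass


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class BPNNModel:
    W1: np.ndarray  # (n_hidden, n_in)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_out, n_hidden)
    b2: np.ndarray  # (n_out,)

    def __post_init__(self):
        W1 = np.asarray(self.W1, dtype=np.float64)
        b1 = np.asarray(self.b1, dtype=np.float64)
        W2 = np.asarray(self.W2, dtype=np.float64)
        b2 = np.asarray(self.b2, dtype=np.float64)
        if W1.ndim != 2 or W2.ndim != 2 or b1.ndim != 1 or b2.ndim != 1:
            raise ValidationError("weight/threshold arrays have wrong rank")
        nh, ni = W1.shape
        no = W2.shape[0]
        if W2.shape[1] != nh or b1.shape[0] != nh or b2.shape[0] != no:
            raise ValidationError("inconsistent layer dimensions")
        if not (1 <= nh <= MAX_HIDDEN):
            raise ValidationError(f"n_hidden must be in [1, {MAX_HIDDEN}], got {nh}")
        for arr in (W1, b1, W2, b2):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("non-finite weight")
        object.__setattr__(self, "W1", W1)
        object.__setattr__(self, "b1", b1)
        object.__setattr__(self, "W2", W2)
        object.__setattr__(self, "b2", b2)

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_out(self) -> int:
        return self.W2.shape[0]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.5
    max_epochs: int = 200
    error_goal: float = 1e-3
    seed: int = 0
    batch: str = "online"  # "online" | "full"
    momentum: float = 0.0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")
        if self.error_goal < 0:
            raise ValidationError("error_goal must be >= 0")
        if self.batch not in ("online", "full"):
            raise ValidationError(f"unknown batch mode {self.batch!r}")


@dataclass
class TrainHistory:
    mse: list[float] = field(default_factory=list)
    stop_reason: str = "max_epochs"


def init_network(n_in: int, n_hidden: int, n_out: int, seed: int = 0) -> BPNNModel:
    """Random model with i.i.d. uniform [-0.5, 0.5] weights and thresholds."""
    if n_in < 1 or n_hidden < 1 or n_out < 1:
        raise ValidationError("network dimensions must be positive")
    rng = as_rng(seed)
    return BPNNModel(
        W1=rng.uniform(-0.5, 0.5, (n_hidden, n_in)),
        b1=rng.uniform(-0.5, 0.5, n_hidden),
        W2=rng.uniform(-0.5, 0.5, (n_out, n_hidden)),
        b2=rng.uniform(-0.5, 0.5, n_out),
    )


def hidden_activations(model: BPNNModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_in:
        raise ValidationError(f"expected {model.n_in} inputs, got {X.shape[1]}")
    return _sigmoid(X @ model.W1.T + model.b1)


def forward(model: BPNNModel, X: np.ndarray) -> np.ndarray:
    """Output activations; accepts a single sample (1-D) or a batch (2-D)."""
    x = np.asarray(X, dtype=np.float64)
    single = x.ndim == 1
    H = hidden_activations(model, x)
    Y = _sigmoid(H @ model.W2.T + model.b2)
    return Y[0] if single else Y


def mse(model: BPNNModel, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean over samples and outputs of the squared error."""
    pred = forward(model, np.atleast_2d(X))
    return float(np.mean((pred - np.atleast_2d(Y)) ** 2))


def sample_loss(model: BPNNModel, x: np.ndarray, t: np.ndarray) -> float:
    """Half squared error of a single sample (the quantity backprop descends)."""
    y = forward(model, x)
    return float(0.5 * np.sum((y - t) ** 2))


def gradients(model: BPNNModel, x: np.ndarray, t: np.ndarray):
    """Analytic gradients of sample_loss w.r.t. (W1, b1, W2, b2)."""
    x = np.asarray(x, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    h = _sigmoid(model.W1 @ x + model.b1)
    y = _sigmoid(model.W2 @ h + model.b2)
    dz2 = (y - t) * y * (1.0 - y)
    gW2 = np.outer(dz2, h)
    gb2 = dz2
    dz1 = (model.W2.T @ dz2) * h * (1.0 - h)
    gW1 = np.outer(dz1, x)
    gb1 = dz1
    return gW1, gb1, gW2, gb2


def train_backprop(
    model: BPNNModel, X: np.ndarray, Y: np.ndarray, cfg: TrainConfig
) -> tuple[BPNNModel, TrainHistory]:
    """Gradient-descent training on squared error.

    Online mode shuffles the sample order each epoch (seeded) and updates
    after every sample; full mode averages gradients over the whole set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if len(X) == 0:
        raise ValidationError("empty training set")
    if len(X) != len(Y):
        raise ValidationError("X and Y lengths differ")
    if Y.shape[1] != model.n_out:
        raise ValidationError("target width differs from n_out")

    rng = as_rng(cfg.seed)
    W1, b1 = model.W1.copy(), model.b1.copy()
    W2, b2 = model.W2.copy(), model.b2.copy()
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)
    lr, mom = cfg.learning_rate, cfg.momentum
    history = TrainHistory()

    for _epoch in range(cfg.max_epochs):
        if cfg.batch == "online":
            for i in rng.permutation(len(X)):
                x, t = X[i], Y[i]
                h = _sigmoid(W1 @ x + b1)
                y = _sigmoid(W2 @ h + b2)
                dz2 = (y - t) * y * (1.0 - y)
                dz1 = (W2.T @ dz2) * h * (1.0 - h)
                vW2 = mom * vW2 - lr * np.outer(dz2, h)
                vb2 = mom * vb2 - lr * dz2
                vW1 = mom * vW1 - lr * np.outer(dz1, x)
                vb1 = mom * vb1 - lr * dz1
                W2 += vW2
                b2 += vb2
                W1 += vW1
                b1 += vb1
        else:
            H = _sigmoid(X @ W1.T + b1)
            Yp = _sigmoid(H @ W2.T + b2)
            dZ2 = (Yp - Y) * Yp * (1.0 - Yp) / len(X)
            dZ1 = (dZ2 @ W2) * H * (1.0 - H)
            W2 -= lr * dZ2.T @ H
            b2 -= lr * dZ2.sum(axis=0)
            W1 -= lr * dZ1.T @ X
            b1 -= lr * dZ1.sum(axis=0)

        H = _sigmoid(X @ W1.T + b1)
        Yp = _sigmoid(H @ W2.T + b2)
        err = float(np.mean((Yp - Y) ** 2))
        if not np.isfinite(err):
            raise DivergenceError(
                f"training diverged (non-finite MSE); reduce learning_rate={lr}"
            )
        history.mse.append(err)
        if err <= cfg.error_goal:
            history.stop_reason = "error_goal"
            break
    else:
        history.stop_reason = "max_epochs"

    return BPNNModel(W1=W1, b1=b1, W2=W2, b2=b2), history


def predict_labels(model: BPNNModel, X: np.ndarray) -> np.ndarray:
    """Argmax class per sample, ties broken toward the lower index."""
    return np.argmax(forward(model, np.atleast_2d(X)), axis=1)


def model_to_json(model: BPNNModel) -> str:
    return json.dumps(
        {
            "n_in": model.n_in,
            "n_hidden": model.n_hidden,
            "n_out": model.n_out,
            "W1": model.W1.ravel().tolist(),
            "b1": model.b1.tolist(),
            "W2": model.W2.ravel().tolist(),
            "b2": model.b2.tolist(),
        }
    )


def model_from_json(doc: str) -> BPNNModel:
    d = json.loads(doc)
    ni, nh, no = d["n_in"], d["n_hidden"], d["n_out"]
    return BPNNModel(
        W1=np.array(d["W1"], dtype=np.float64).reshape(nh, ni),
        b1=np.array(d["b1"], dtype=np.float64),
        W2=np.array(d["W2"], dtype=np.float64).reshape(no, nh),
        b2=np.array(d["b2"], dtype=np.float64),
    )
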