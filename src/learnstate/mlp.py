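"""From-scratch multilayer perceptron: forward pass, input-layer dropout,
exact backpropagation, and minibatch gradient-descent training with a
parameter-change stopping rule.

The default head is a 3-unit softmax with categorical cross-entropy, which is
what the 3-state confusion matrices require.  A single-unit linear-regression
head (``output_mode="regression"``, MSE loss, prediction by rounding to the
nearest class index) is kept behind a flag for fidelity with configurations
that report one output neuron.

Dropout is applied to the *input* layer only, in inverted form: each input
unit is retained with probability P and surviving activations are scaled by
1/P, so the expected pre-activation matches the eval-mode pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class MLPModel:
    """Layer sizes, per-layer weights/biases, and the dropout keep-probability."""

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    keep_prob: float = 1.0
    output_mode: str = "softmax"  # or "regression"

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 3:
            raise ValueError("need input, at least one hidden, and output layer")
        if not 0 < self.keep_prob <= 1:
            raise ValueError("keep_prob must lie in (0, 1]")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (self.layer_sizes[l + 1], self.layer_sizes[l]):
                raise ValueError(f"weight matrix {l} has wrong shape {w.shape}")
            if b.shape != (self.layer_sizes[l + 1],):
                raise ValueError(f"bias vector {l} has wrong shape {b.shape}")

    @property
    def n_classes(self) -> int:
        return self.layer_sizes[-1]

    def copy(self) -> "MLPModel":
        return MLPModel(
            self.layer_sizes,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.keep_prob,
            self.output_mode,
        )


@dataclass
class TrainConfig:
    learning_rate: float = 0.05
    max_iter: int = 200
    stop_threshold: float = 1e-6
    batch_size: int = 95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.max_iter < 1 or self.batch_size < 1:
            raise ValueError("max_iter and batch_size must be positive")
        if not self.stop_threshold > 0:
            raise ValueError("stop threshold must be positive")


def init_mlp(
    layer_sizes: tuple[int, ...],
    seed: int = 0,
    keep_prob: float = 1.0,
    output_mode: str = "softmax",
) -> MLPModel:
    """He-initialized weights (variance 2/fan-in, suited to rectifiers), zero biases."""
    if any(s < 1 for s in layer_sizes):
        raise ValueError("all layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return MLPModel(tuple(layer_sizes), weights, biases, keep_prob, output_mode)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class ForwardPass:
    """Per-layer activations (a[0] is the possibly-dropped input) and pre-activations."""

    activations: list[np.ndarray]
    pre_activations: list[np.ndarray]
    dropout_mask: Optional[np.ndarray] = None

    @property
    def output(self) -> np.ndarray:
        return self.activations[-1]


def forward(
    model: MLPModel,
    X: np.ndarray,
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
) -> ForwardPass:
    """Run the network on a batch (rows = samples).

    ``mode="train"`` draws an inverted-dropout mask for the input layer (kept
    for the backward pass); ``mode="eval"`` is deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"input width {X.shape[1]} does not match model input size {model.layer_sizes[0]}"
        )
    mask = None
    a = X
    if mode == "train" and model.keep_prob < 1.0:
        if rng is None:
            rng = np.random.default_rng()
        mask = (rng.random(X.shape) < model.keep_prob).astype(float)
        a = X * mask / model.keep_prob
    activations = [a]
    pre_activations = []
    n_layers = len(model.weights)
    for l, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ w.T + b
        pre_activations.append(z)
        if l < n_layers - 1:
            a = np.maximum(z, 0.0)  # ReLU hidden units
        elif model.output_mode == "softmax":
            a = _softmax(z)
        else:
            a = z
        activations.append(a)
    return ForwardPass(activations, pre_activations, mask)


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


def loss_value(model: MLPModel, output: np.ndarray, y: np.ndarray) -> float:
    """Mean categorical cross-entropy (softmax head) or MSE (regression head)."""
    if model.output_mode == "softmax":
        t = _one_hot(y, model.n_classes)
        return float(-(t * np.log(np.clip(output, 1e-12, None))).sum(axis=1).mean())
    return float(((output.ravel() - np.asarray(y, dtype=float)) ** 2).mean())


def backward(
    model: MLPModel, X: np.ndarray, y: np.ndarray, fp: ForwardPass
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact batch-averaged gradients of the loss w.r.t. every weight and bias.

    For the softmax/cross-entropy head the output delta is (p - t)/m; ReLU
    gates the hidden deltas; the input dropout mask (with its 1/P scaling) is
    already folded into ``fp.activations[0]``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[0]
    if fp.activations[0].shape[0] != m:
        raise ValueError("activations do not match this batch (stale forward pass?)")
    if model.output_mode == "softmax":
        delta = (fp.output - _one_hot(y, model.n_classes)) / m
    else:
        delta = 2.0 * (fp.output - np.asarray(y, dtype=float).reshape(-1, 1)) / m
    grads_w = [np.empty_like(w) for w in model.weights]
    grads_b = [np.empty_like(b) for b in model.biases]
    for l in range(len(model.weights) - 1, -1, -1):
        grads_w[l] = delta.T @ fp.activations[l]
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ model.weights[l]) * (fp.pre_activations[l - 1] > 0)
    return grads_w, grads_b


def train_mlp(
    model: MLPModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> tuple[MLPModel, list[float]]:
    """Minibatch gradient descent: W <- W - a*gW, b <- b - a*gb.

    One iteration is a full shuffled pass over the data.  Training stops after
    ``max_iter`` iterations or as soon as the maximum absolute parameter
    change over a full pass drops below ``stop_threshold``.  Returns the
    trained model (a copy) and the per-iteration loss history.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    model = model.copy()
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    batch = min(cfg.batch_size, n)
    history: list[float] = []
    for _ in range(cfg.max_iter):
        order = rng.permutation(n)
        prev_w = [w.copy() for w in model.weights]
        prev_b = [b.copy() for b in model.biases]
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            fp = forward(model, X[idx], mode="train", rng=rng)
            gw, gb = backward(model, X[idx], y[idx], fp)
            for l in range(len(model.weights)):
                model.weights[l] -= cfg.learning_rate * gw[l]
                model.biases[l] -= cfg.learning_rate * gb[l]
        epoch_loss = loss_value(model, forward(model, X).output, y)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"training diverged: non-finite loss {epoch_loss} "
                f"(learning rate {cfg.learning_rate})"
            )
        history.append(epoch_loss)
        max_change = max(
            max(np.abs(w - pw).max() for w, pw in zip(model.weights, prev_w)),
            max(np.abs(b - pb).max() for b, pb in zip(model.biases, prev_b)),
        )
        if max_change < cfg.stop_threshold:
            break
    return model, history


def predict_proba(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Row-stochastic class-probability matrix (softmax head)."""
    out = forward(model, X, mode="eval").output
    if model.output_mode == "softmax":
        return out
    # Regression head: distance-to-class-index converted to a point mass.
    k = model.n_classes if model.n_classes > 1 else 3
    cls = np.clip(np.rint(out.ravel()), 0, k - 1).astype(int)
    return _one_hot(cls, k)


def predict(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Class labels: argmax of probabilities, ties toward the lowest index."""
    return predict_proba(model, X).argmax(axis=1)
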