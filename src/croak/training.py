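"""Adam optimization and the softmax cross-entropy training loop.

The optimizer keeps two exponentially smoothed per-parameter accumulators:
the squared-gradient (second) moment X_t <- rho X_t + (1-rho) g^2 and the
gradient (first) moment F_t <- rho_f F_t + (1-rho_f) g.  Both start at zero,
which biases early averages toward zero, so bias-corrected estimates
X_hat = X/(1-rho^t), F_hat = F/(1-rho_f^t) drive the update

    w <- w - lr * F_hat / (sqrt(X_hat) + eps).

Decay defaults rho = 0.999, rho_f = 0.9, eps = 1e-8 are the canonical Adam
constants.  The loss is softmax cross-entropy over the class logits; the
study protocol trains full-batch (batch size equal to the whole training
set) which :class:`TrainConfig` mirrors, mini-batching kicking in only when
``batch_size`` is smaller than the data.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp


@dataclass
class TrainConfig:
    """Study-protocol defaults: 1000 epochs, lr 2e-5, full batch (1400)."""

    epochs: int = 1000
    learning_rate: float = 2e-5
    batch_size: int = 1400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class AdamState:
    """Per-parameter moment accumulators and step counter."""

    second_moment: list[np.ndarray]
    first_moment: list[np.ndarray]
    rho: float = 0.999
    rho_f: float = 0.9
    learning_rate: float = 2e-5
    epsilon: float = 1e-8
    step_count: int = 0

    @classmethod
    def init(cls, params: list[np.ndarray], learning_rate: float,
             rho: float = 0.999, rho_f: float = 0.9, epsilon: float = 1e-8) -> "AdamState":
        return cls(
            second_moment=[np.zeros_like(p) for p in params],
            first_moment=[np.zeros_like(p) for p in params],
            rho=rho, rho_f=rho_f, learning_rate=learning_rate, epsilon=epsilon,
        )


def adam_step(
    state: AdamState, params: list[np.ndarray], grads: list[np.ndarray]
) -> None:
    """One in-place Adam update of every parameter array.

    Raises on non-finite gradients, naming the offending parameter block.
    """
    state.step_count += 1
    t = state.step_count
    bc2 = 1.0 - state.rho**t
    bc1 = 1.0 - state.rho_f**t
    for k, (p, g) in enumerate(zip(params, grads)):
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in parameter block {k}")
        x = state.second_moment[k]
        f = state.first_moment[k]
        x *= state.rho
        x += (1.0 - state.rho) * g * g
        f *= state.rho_f
        f += (1.0 - state.rho_f) * g
        x_hat = x / bc2 if bc2 > 0 else x
        f_hat = f / bc1 if bc1 > 0 else f
        p -= state.learning_rate * f_hat / (np.sqrt(x_hat) + state.epsilon)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over rows and its gradient w.r.t. the logits.

    ``labels`` are 1-based class indices (1..C).
    """
    logits = np.atleast_2d(logits)
    n, n_classes = logits.shape
    y = np.asarray(labels, dtype=np.int64) - 1
    if np.any(y < 0) or np.any(y >= n_classes):
        raise ValueError(f"labels must lie in 1..{n_classes}")
    lse = logsumexp(logits, axis=1)
    loss = float(np.mean(lse - logits[np.arange(n), y]))
    probs = np.exp(logits - lse[:, None])
    probs[np.arange(n), y] -= 1.0
    return loss, probs / n


def train(
    model,
    X: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    rho: float = 0.999,
    rho_f: float = 0.9,
    epsilon: float = 1e-8,
) -> list[float]:
    """Optimize ``model`` in place; returns the per-epoch loss history.

    Full-batch when ``batch_size >= N`` (the study setting); otherwise
    seeded mini-batch shuffling.  Fully deterministic under
    ``config.seed`` in single-threaded execution.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n = X.shape[0]
    if labels.shape[0] != n:
        raise ValueError("X and labels must have the same number of rows")
    state = AdamState.init(
        model.params, config.learning_rate, rho=rho, rho_f=rho_f, epsilon=epsilon
    )
    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    full_batch = config.batch_size >= n
    for epoch in range(config.epochs):
        if full_batch:
            loss, dlogits = softmax_cross_entropy(model.forward(X), labels)
            grads = model.backward(dlogits)
            adam_step(state, model.params, grads)
            epoch_loss = loss
        else:
            order = rng.permutation(n)
            losses, weights = [], []
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                loss, dlogits = softmax_cross_entropy(model.forward(X[idx]), labels[idx])
                grads = model.backward(dlogits)
                adam_step(state, model.params, grads)
                losses.append(loss)
                weights.append(idx.size)
            epoch_loss = float(np.average(losses, weights=weights))
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        history.append(epoch_loss)
    return history


def predict(model, X: np.ndarray) -> np.ndarray:
    """1-based argmax class predictions."""
    logits = model.forward(np.asarray(X, dtype=np.float64))
    return np.argmax(logits, axis=1) + 1


def save_loss_history(history: list[float], path, seconds: float | None = None) -> None:
    """CSV log: epoch, loss, cumulative seconds (if timed)."""
    import pandas as pd

    df = pd.DataFrame({"epoch": np.arange(1, len(history) + 1), "loss": history})
    if seconds is not None:
        df["seconds"] = seconds
    df.to_csv(path, index=False)


class Stopwatch:
    """Minimal wall-clock timer for the informational training-period log."""

    def __enter__(self):
        self.start = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.perf_counter() - self.start
        return False


__all__ = [
    "TrainConfig",
    "AdamState",
    "adam_step",
    "softmax_cross_entropy",
    "train",
    "predict",
    "save_loss_history",
    "Stopwatch",
]
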