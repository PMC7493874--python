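"""Mini-batch training with early stopping and best-epoch checkpointing.

The loss is binary cross-entropy on a single sigmoid output.  After each
epoch the monitored validation quantity is evaluated; the weights of the
best epoch are kept and restored at the end (model checkpointing), and
training stops once the monitor has failed to improve for more than
``patience`` consecutive epochs — with patience 0, training runs exactly
one epoch past the best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network, sigmoid


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class EarlyStopConfig:
    """What to monitor and how long to wait.

    monitor: "balanced_accuracy", "sensitivity" (maximized) or "loss"
    (minimized), always computed on the validation set.
    """

    monitor: str = "balanced_accuracy"
    patience: int = 10
    min_delta: float = 0.0

    def __post_init__(self):
        if self.monitor not in ("balanced_accuracy", "sensitivity", "loss"):
            raise ValueError(f"unknown monitor {self.monitor!r}")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def as_dict(self) -> dict:
        return {
            "epochs": self.epochs,
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_metric": self.val_metric,
            "best_epoch": self.best_epoch,
        }


def _bce(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, 1e-7, 1 - 1e-7)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _monitor_value(monitor: str, probs: np.ndarray, y: np.ndarray) -> float:
    if monitor == "loss":
        return _bce(probs, y)
    pred = probs >= 0.5
    pos = y == 1
    if monitor == "sensitivity":
        return float(pred[pos].mean()) if pos.any() else 0.0
    sens = float(pred[pos].mean()) if pos.any() else 0.0
    spec = float((~pred[~pos]).mean()) if (~pos).any() else 0.0
    return (sens + spec) / 2


def fit_network(
    network: Network,
    optimizer,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    max_epochs: int = 100,
    batch_size: int = 32,
    early_stop: EarlyStopConfig | None = None,
    seed: int = 0,
) -> TrainingHistory:
    """Train in place; returns the history.  Deterministic under ``seed``.

    Raises :class:`TrainingError` on a single-class training set or a
    non-finite loss.
    """
    y_train = np.asarray(y_train, dtype=np.float64).reshape(-1)
    y_val = np.asarray(y_val, dtype=np.float64).reshape(-1)
    if x_train.shape[0] != y_train.size or x_val.shape[0] != y_val.size:
        raise TrainingError("feature/label length mismatch")
    if np.unique(y_train).size < 2:
        raise TrainingError("training set contains a single class")
    es = early_stop or EarlyStopConfig()
    sign = -1.0 if es.monitor == "loss" else 1.0
    rng = np.random.default_rng(seed)

    history = TrainingHistory()
    best_score = -np.inf
    best_weights = network.clone_weights()
    since_best = 0

    n = x_train.shape[0]
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = x_train[idx]
            yb = y_train[idx]
            logits = network.forward(xb, training=True, rng=rng).reshape(-1)
            probs = sigmoid(logits)
            loss = _bce(probs, yb)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {loss!r} "
                    f"(lr too high or exploding activations)"
                )
            epoch_loss += loss * idx.size
            # d(BCE)/d(logit) = sigmoid(z) - y, averaged over the batch
            grad = ((probs - yb) / idx.size).astype(np.float32).reshape(-1, 1)
            network.backward(grad)
            optimizer.step(network)

        val_probs = network.predict_proba(x_val)
        metric = _monitor_value(es.monitor, val_probs, y_val)
        history.epochs.append(epoch)
        history.train_loss.append(epoch_loss / n)
        history.val_loss.append(_bce(val_probs, y_val))
        history.val_metric.append(metric)

        score = sign * metric
        if score > best_score + es.min_delta:
            best_score = score
            best_weights = network.clone_weights()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > es.patience:
                break

    network.set_weights(best_weights)
    return history
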