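"""Training loop: cross-entropy, SGD/Adam, equal-interval step LR decay.

The learning-rate schedule multiplies the initial rate by gamma once
every step_size epochs:

    lr(epoch) = initial_lr * gamma ** floor(epoch / step_size)

L2 regularization enters as optimizer weight decay on convolution and
fully connected weights (batch-norm parameters and biases are exempt).
Default hyperparameters are the Bayesian-search optimum for this
architecture: Adam, lr 1.9e-4, weight decay 2e-4, step_size 15,
gamma 0.085, batch 64, 100 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .metrics import ConfusionMatrix, confusion

__all__ = [
    "HyperParams",
    "EpochRecord",
    "TrainHistory",
    "DivergenceError",
    "scheduled_lr",
    "make_optimizer",
    "train_model",
    "predict_logits",
    "evaluate",
]

OPTIMIZERS = ("SGD", "Adam")


@dataclass
class HyperParams:
    optimizer: str = "Adam"
    learning_rate: float = 0.00019
    step_size: int = 15
    gamma: float = 0.085
    weight_decay: float = 0.0002
    batch_size: int = 64
    epochs: int = 100

    def __post_init__(self):
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; choose from {OPTIMIZERS}"
            )
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.step_size < 1:
            raise ValueError("step_size must be >= 1")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "optimizer", "learning_rate", "step_size", "gamma",
            "weight_decay", "batch_size", "epochs")}


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    train_acc: float
    val_acc: float | None


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lrs(self) -> list[float]:
        return [r.lr for r in self.records]

    @property
    def train_losses(self) -> list[float]:
        return [r.train_loss for r in self.records]

    @property
    def val_accs(self) -> list[float | None]:
        return [r.val_acc for r in self.records]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame([r.__dict__ for r in self.records]).to_csv(path, index=False)


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


def scheduled_lr(initial_lr: float, gamma: float, step_size: int, epoch: int) -> float:
    """Equal-interval step decay: initial_lr * gamma ** floor(epoch/step_size).

    The exponent uses integer division — the rate is constant within each
    step_size-epoch interval and drops by a factor gamma between them.
    """
    if step_size < 1:
        raise ValueError("step_size must be >= 1")
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return initial_lr * gamma ** (epoch // step_size)


def make_optimizer(model: nn.Network, hp: HyperParams):
    """SGD (momentum-free) or Adam over the model parameters with L2
    weight decay on decay-flagged (conv/fc weight) parameters."""
    cls = {"SGD": nn.SGD, "Adam": nn.Adam}[hp.optimizer]
    return cls(model.params(), lr=hp.learning_rate, weight_decay=hp.weight_decay)


def _accuracy(logits: np.ndarray, labels: np.ndarray) -> float:
    return float((logits.argmax(axis=1) == labels).mean())


def predict_logits(model: nn.Network, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    outs = [model.forward(X[i: i + batch_size], train=False)
            for i in range(0, len(X), batch_size)]
    return np.concatenate(outs, axis=0)


def train_model(model: nn.Network, X_train: np.ndarray, y_train: np.ndarray,
                hp: HyperParams, rng=None,
                X_val: np.ndarray | None = None,
                y_val: np.ndarray | None = None,
                stop_at_val_acc: float | None = None,
                bn_recal_samples: int = 256):
    """Minibatch training with the step-decay schedule.

    Inputs are standardized NCHW float32 batches. Returns (history,
    checkpoint); the checkpoint holds the state with the best validation
    accuracy (final state when no validation set is given). A non-finite
    loss aborts with the epoch index. `stop_at_val_acc` optionally ends
    training early once validation accuracy reaches the given level.

    Before each inference-mode measurement the batch-norm running
    statistics are recalibrated on up to `bn_recal_samples` training
    items, so evaluation reflects the current weights rather than stale
    running estimates (set 0 to disable).
    """
    rng = nn.make_rng(rng)
    opt = make_optimizer(model, hp)
    history = TrainHistory()
    best = {"val_acc": -np.inf, "epoch": -1, "state": model.state_dict()}
    n = len(X_train)
    for epoch in range(hp.epochs):
        opt.lr = scheduled_lr(hp.learning_rate, hp.gamma, hp.step_size, epoch)
        order = rng.permutation(n)
        losses, accs = [], []
        for i in range(0, n, hp.batch_size):
            idx = order[i: i + hp.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            accs.append(_accuracy(logits, yb))
        val_acc = None
        if X_val is not None:
            if bn_recal_samples:
                # use this epoch's shuffled order so the recalibration
                # subset mixes classes even on class-sorted inputs
                model.recalibrate_bn(X_train[order[:bn_recal_samples]],
                                     hp.batch_size)
            val_acc = _accuracy(predict_logits(model, X_val, hp.batch_size), y_val)
            if val_acc > best["val_acc"]:
                best = {"val_acc": val_acc, "epoch": epoch,
                        "state": model.state_dict()}
        history.records.append(EpochRecord(
            epoch=epoch, lr=opt.lr, train_loss=float(np.mean(losses)),
            train_acc=float(np.mean(accs)), val_acc=val_acc,
        ))
        if stop_at_val_acc is not None and val_acc is not None \
                and val_acc >= stop_at_val_acc:
            break
    if X_val is None:
        if bn_recal_samples and hp.epochs > 0:
            sub = rng.permutation(n)[:bn_recal_samples]
            model.recalibrate_bn(X_train[sub], hp.batch_size)
        best = {"val_acc": None, "epoch": hp.epochs - 1, "state": model.state_dict()}
    return history, best


def evaluate(model: nn.Network, X: np.ndarray, y: np.ndarray, n_classes: int,
             batch_size: int = 64, labels=None) -> ConfusionMatrix:
    """Argmax predictions accumulated into a confusion matrix."""
    if len(X) == 0:
        raise ValueError("cannot evaluate on an empty subset")
    preds = predict_logits(model, X, batch_size).argmax(axis=1)
    return confusion(y, preds, n_classes, labels)
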