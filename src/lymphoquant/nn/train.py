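"""Training loop: pixel-wise MSE, Adam, plateau LR scheduling, checkpoints.

The learning-rate schedule follows the plateau rule: if the monitored
validation loss does not improve for ``patience`` consecutive epochs the
rate is multiplied by ``factor`` (default 0.2), i.e. eta_{t+1} = alpha * eta_t
at each plateau event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .network import DensityNet, _to_input

__all__ = ["Adam", "ReduceLROnPlateau", "TrainHistory", "train", "mse_loss"]


class Adam:
    """Plain Adam.  The optimizer slot is pluggable: anything exposing
    ``step(params)`` and a mutable ``lr`` works in :func:`train`."""

    def __init__(self, lr: float = 1e-2, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params) -> None:
        self.t += 1
        for p in params:
            g = p.tensor.grad
            if g is None:
                continue
            m = self._m.setdefault(p.name, np.zeros_like(p.tensor.data))
            v = self._v.setdefault(p.name, np.zeros_like(p.tensor.data))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p.tensor.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self, params) -> None:
        for p in params:
            p.tensor.grad = None


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience``
    non-improving epochs (strict improvement of the monitored value)."""

    def __init__(self, optimizer, factor: float = 0.2, patience: int = 10):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.best: float | None = None
        self.num_bad = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, metric: float) -> bool:
        """Record one epoch's monitored value; returns True on reduction."""
        if self.best is None or metric < self.best:
            self.best = metric
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad >= self.patience:
            self.optimizer.lr = self.factor * self.optimizer.lr
            self.num_bad = 0
            return True
        return False


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    checkpoints: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "lr": self.lr,
            }
        )


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def _epoch_loss(model: DensityNet, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        pred = model.forward(x[i : i + batch]).data[:, 0]
        total += float(((pred - y[i : i + batch]) ** 2).sum())
        n += pred.size
    return total / n


def train(
    model: DensityNet,
    train_images: np.ndarray,
    train_targets: np.ndarray,
    val_images: np.ndarray | None = None,
    val_targets: np.ndarray | None = None,
    epochs: int = 20,
    batch_size: int = 8,
    optimizer=None,
    checkpoint_every: int = 6,
    seed: int = 0,
) -> TrainHistory:
    """Fit the model on (N, H, W, 3) tiles against (N, H, W) density maps.

    Validation defaults to the training set when not supplied (smoke-test
    mode).  Raises on an empty training set and aborts on NaN loss.
    """
    if len(train_images) == 0:
        raise ValueError("empty training set")
    x = _to_input(np.asarray(train_images))
    y = np.asarray(train_targets, dtype=float)
    if val_images is None:
        xv, yv = x, y
    else:
        xv = _to_input(np.asarray(val_images))
        yv = np.asarray(val_targets, dtype=float)

    opt = optimizer or Adam(lr=model.config.learning_rate)
    sched = ReduceLROnPlateau(
        opt,
        factor=model.config.scheduler_factor,
        patience=model.config.scheduler_patience,
    )
    rng = np.random.default_rng(seed)
    hist = TrainHistory()

    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(x))
        running, npix = 0.0, 0
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            opt.zero_grad(model.params)
            pred = model.forward(x[idx])
            loss = mse_loss(pred, y[idx][:, None, :, :])
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise FloatingPointError(
                    f"non-finite training loss ({lv}) at epoch {epoch}"
                )
            loss.backward()
            opt.step(model.params)
            running += lv * pred.data.size
            npix += pred.data.size
        val = _epoch_loss(model, xv, yv, batch_size)
        hist.epochs.append(epoch)
        hist.train_loss.append(running / npix)
        hist.val_loss.append(val)
        hist.lr.append(opt.lr)
        sched.step(val)
        if checkpoint_every and epoch % checkpoint_every == 0:
            hist.checkpoints[epoch] = model.state_dict()
    return hist
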