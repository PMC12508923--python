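"""Training loop: Adam on the mean-absolute-error objective.

The reference recipe is Adam with learning rate 1e-4, 50 epochs, batch
size 8, minimising the mean absolute error between the network output and
the ground-truth PFOS spectrum (both in [-1, 1]-normalized units).  The
loop is fully seeded -- initialisation, shuffling and batching all derive
from one integer -- and keeps the parameters of the epoch with the best
validation MAE.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .evaluation import records_to_arrays
from .exceptions import TrainingDivergedError
from .models import UNet1d, demultiplex
from .nn import Adam
from .simulate import DatasetSplits

__all__ = ["TrainConfig", "TrainHistory", "train", "fit_arrays", "batch_mae"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch training loss, validation MAE and wall time."""

    train_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def batch_mae(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute difference over every point of every spectrum in a
    batch -- the same definition the evaluation metric uses."""
    return float(np.mean(np.abs(pred - target)))


def _validation_mae(model: UNet1d, X_val: np.ndarray, Y_val: np.ndarray,
                    batch_size: int) -> float:
    errs = []
    for i in range(0, X_val.shape[0], batch_size):
        pred = demultiplex(model, X_val[i:i + batch_size])
        errs.append(np.abs(pred - Y_val[i:i + batch_size]).mean(axis=1))
    return float(np.concatenate(errs).mean())


def fit_arrays(model: UNet1d, X: np.ndarray, Y: np.ndarray,
               X_val: np.ndarray | None, Y_val: np.ndarray | None,
               config: TrainConfig, verbose: bool = False
               ) -> tuple[UNet1d, TrainHistory]:
    """Train on ``(n, length)`` arrays already normalized to [-1, 1].

    Returns the model carrying the best-validation parameters (final
    parameters when no validation set is given) and the history.
    """
    dtype = model.config.np_dtype
    X = np.ascontiguousarray(X, dtype=dtype)[:, None, :]
    Y = np.ascontiguousarray(Y, dtype=dtype)[:, None, :]
    has_val = X_val is not None and Y_val is not None
    if has_val:
        X_val = np.ascontiguousarray(X_val, dtype=dtype)
        Y_val = np.ascontiguousarray(Y_val, dtype=dtype)

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_params: list[np.ndarray] | None = None

    n = X.shape[0]
    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            out = model.forward(xb)
            diff = out - yb
            loss = float(np.abs(diff).mean())
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch + 1} "
                    f"(learning rate {config.learning_rate})"
                )
            epoch_losses.append(loss)
            opt.zero_grad()
            model.backward((np.sign(diff) / diff.size).astype(dtype))
            opt.step()
        history.train_loss.append(float(np.mean(epoch_losses)))
        if has_val:
            vm = _validation_mae(model, X_val, Y_val, max(config.batch_size, 32))
            history.val_mae.append(vm)
            if vm < best_val:
                best_val = vm
                history.best_epoch = epoch
                best_params = [p.value.copy() for p in model.parameters()]
        else:
            history.best_epoch = epoch
        history.epoch_seconds.append(time.perf_counter() - t0)
        if verbose:
            msg = f"epoch {epoch + 1}/{config.epochs} loss {history.train_loss[-1]:.5f}"
            if has_val:
                msg += f" val_mae {history.val_mae[-1]:.5f}"
            print(msg)

    if best_params is not None:
        for p, value in zip(model.parameters(), best_params):
            p.value[...] = value
    return model, history


def train(model: UNet1d, splits: DatasetSplits, config: TrainConfig,
          verbose: bool = False) -> tuple[UNet1d, TrainHistory]:
    """Train a built network on dataset splits (records are normalized to
    [-1, 1] per spectrum, the paired truth sharing each mixture's scale)."""
    if not splits.train:
        raise ValueError("empty training split")
    X, Y = records_to_arrays(splits.train)
    if splits.validation:
        X_val, Y_val = records_to_arrays(splits.validation)
    else:
        X_val = Y_val = None
    return fit_arrays(model, X, Y, X_val, Y_val, config, verbose=verbose)
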