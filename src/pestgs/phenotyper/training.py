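"""Training loop with early stopping, and seeded k-fold cross-validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from pestgs.nn import Adam, Sequential, bce_loss, mse_loss

_LOSSES = {"mse": mse_loss, "bce": bce_loss}

#: Minimum decrease of the validation loss that counts as an improvement.
MIN_DELTA = 1e-6


@dataclass
class TrainReport:
    """Bookkeeping of one training run."""

    best_epoch: int
    stopped_epoch: int
    train_losses: list[float]
    val_losses: list[float]
    best_val_loss: float
    best_val_metric: float
    hyperparams: dict = field(default_factory=dict)
    val_maes: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_epoch": self.best_epoch,
            "stopped_epoch": self.stopped_epoch,
            "train_losses": [round(v, 8) for v in self.train_losses],
            "val_losses": [round(v, 8) for v in self.val_losses],
            "val_maes": [round(v, 8) for v in self.val_maes],
            "best_val_loss": round(self.best_val_loss, 8),
            "best_val_metric": round(self.best_val_metric, 8),
            "hyperparams": self.hyperparams,
        }


def _as_2d(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float32)
    return y[:, None] if y.ndim == 1 else y


def train_with_early_stopping(
    net: Sequential,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    loss: str = "mse",
    patience: int = 35,
    max_epochs: int = 300,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[Sequential, TrainReport]:
    """Train ``net`` with Adam, halting after ``patience`` non-improving epochs.

    An improvement is a strict decrease of the validation loss by at least
    ``MIN_DELTA``. The weights from the best validation epoch are restored
    before returning. MAE on the validation set is tracked for regression
    (``loss='mse'``) as the accompanying performance metric.
    """
    X_tr, y_tr = train_set
    X_va, y_va = val_set
    if len(X_tr) == 0 or len(X_va) == 0:
        raise ValueError("training and validation sets must be non-empty")
    if loss not in _LOSSES:
        raise ValueError(f"loss must be one of {sorted(_LOSSES)}")
    loss_fn = _LOSSES[loss]
    X_tr = np.asarray(X_tr, dtype=np.float32)
    X_va = np.asarray(X_va, dtype=np.float32)
    y_tr, y_va = _as_2d(y_tr), _as_2d(y_va)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 881]))
    opt = Adam(net.parameters(trainable_only=True), lr=lr)

    best_val = np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    best_metric = np.inf
    train_losses: list[float] = []
    val_losses: list[float] = []
    val_maes: list[float] = []
    since_best = 0
    stopped_epoch = max_epochs

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(X_tr))
        batch_losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            pred = net.forward(X_tr[idx], train=True, rng=rng)
            l, grad = loss_fn(pred, y_tr[idx])
            if not np.isfinite(l):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (lr={lr}); "
                    "reduce the learning rate"
                )
            net.backward(grad)
            opt.step()
            batch_losses.append(l)
        train_losses.append(float(np.mean(batch_losses)))

        pred_va = net.predict(X_va, batch_size=batch_size)
        val_loss = loss_fn(pred_va, y_va)[0]
        val_losses.append(val_loss)
        mae = float(np.mean(np.abs(pred_va - y_va)))
        val_maes.append(mae)

        if val_loss < best_val - MIN_DELTA:
            best_val = val_loss
            best_epoch = epoch
            best_metric = mae
            best_weights = net.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                stopped_epoch = epoch
                break

    net.set_weights(best_weights)
    report = TrainReport(
        best_epoch=best_epoch,
        stopped_epoch=stopped_epoch,
        train_losses=train_losses,
        val_losses=val_losses,
        val_maes=val_maes,
        best_val_loss=float(best_val),
        best_val_metric=float(best_metric),
        hyperparams={"lr": lr, "batch_size": batch_size, "loss": loss, "seed": int(seed)},
    )
    return net, report


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seed-reproducible disjoint folds covering range(n)."""
    if n < k:
        raise ValueError("need at least k samples for k folds")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 991]))
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def crossvalidate(
    build_fn: Callable[[int], Sequential],
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    lr_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2),
    batch_grid: tuple[int, ...] = (32, 64, 128),
    loss: str = "mse",
    patience: int = 10,
    max_epochs: int = 50,
    seed: int = 0,
) -> dict:
    """Grid-search (lr, batch) by k-fold CV; returns the winner + fold scores.

    The score of a combination is the mean best validation loss over folds
    (lower is better). Ties are broken by lower learning rate, then smaller
    batch size. Fold membership depends only on ``seed``.
    """
    if not lr_grid or not batch_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    X = np.asarray(X, dtype=np.float32)
    y = _as_2d(y)
    folds = kfold_indices(len(X), k, seed)
    results = {}
    for lr in sorted(lr_grid):
        for batch in sorted(batch_grid):
            fold_scores = []
            for fi, va_idx in enumerate(folds):
                tr_idx = np.setdiff1d(np.arange(len(X)), va_idx)
                net = build_fn(int(seed) * 1000 + fi)
                try:
                    _, rep = train_with_early_stopping(
                        net,
                        (X[tr_idx], y[tr_idx]),
                        (X[va_idx], y[va_idx]),
                        loss=loss,
                        patience=patience,
                        max_epochs=max_epochs,
                        lr=lr,
                        batch_size=batch,
                        seed=int(seed) * 1000 + fi,
                    )
                    fold_scores.append(rep.best_val_loss)
                except FloatingPointError:
                    fold_scores.append(np.inf)  # diverged combination
            results[(lr, batch)] = fold_scores
    # argmin of mean fold loss; iteration order already encodes the tie-break
    best = min(results, key=lambda key: (float(np.mean(results[key])), key[0], key[1]))
    return {
        "best_lr": best[0],
        "best_batch_size": best[1],
        "fold_scores": {f"lr={k_[0]:g},batch={k_[1]}": v for k_, v in results.items()},
        "folds": [f.tolist() for f in folds],
    }
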