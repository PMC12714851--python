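"""Seeded training loop and the convergence-cost model."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .network import TSTConfig, TSTModel

__all__ = ["TrainingHistory", "train", "training_time", "REFERENCE_TRAINING_COSTS"]

# Reference convergence benchmarks for the built-in training-cost model:
# model family -> (epochs to convergence, seconds per epoch, published total).
REFERENCE_TRAINING_COSTS: dict[str, tuple[int, float, float]] = {
    "cnn": (25, 1.6, 40.0),
    "cnn_gru": (30, 2.1, 63.0),
    "resnet50_lstm": (35, 2.4, 84.0),
    "tst": (18, 1.2, 21.6),
}


def training_time(epochs: int, per_epoch_s: float) -> float:
    """Total training cost as epochs times per-epoch time (pure arithmetic)."""
    return epochs * per_epoch_s


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    epochs_to_convergence: int | None = None
    converged: bool = False
    time_per_epoch: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accept (X, y) tuples or SegmentSet-likes with .segments/.labels."""
    if isinstance(dataset, tuple):
        X, y = dataset
    else:
        X, y = dataset.segments, dataset.labels
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and labels disagree in length")
    return X, y.astype(int)


def _accuracy(model: TSTModel, X: np.ndarray, y: np.ndarray) -> float:
    return float((model.predict_proba(X).argmax(axis=1) == y).mean())


def train(
    train_set,
    val_set,
    cfg: TSTConfig,
    verbose: bool = False,
    restore_best: bool = True,
) -> tuple[TSTModel, TrainingHistory]:
    """Train a model with Adam on cross-entropy; deterministic given the seed.

    ``train_set``/``val_set`` are ``(X, y)`` pairs with ``X`` of shape
    ``(n, channels, window)`` or objects exposing ``.segments``/``.labels``.
    The convergence epoch is the first whose validation accuracy reaches
    ``cfg.convergence_criterion`` times the best validation accuracy seen
    over the whole run.  With ``restore_best`` (default) the returned model
    carries the parameters of the best validation epoch.
    """
    import time as _time

    Xtr, ytr = _as_xy(train_set)
    Xva, yva = _as_xy(val_set) if val_set is not None else (Xtr, ytr)
    classes = np.unique(ytr)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    if classes.max() >= cfg.n_classes:
        raise ValueError(f"label {classes.max()} out of range for {cfg.n_classes} classes")

    model = TSTModel(cfg, n_input_channels=Xtr.shape[1])
    rng = np.random.default_rng(cfg.seed + 1)
    hist = TrainingHistory()

    # Adam state
    mom = {k: np.zeros_like(v) for k, v in model.params.items()}
    vel = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0

    Xtr_t = np.transpose(Xtr, (0, 2, 1))  # (n, T, C)
    n = len(ytr)
    best_params: dict[str, np.ndarray] | None = None
    best_acc = -1.0
    for epoch in range(1, cfg.max_epochs + 1):
        tic = _time.perf_counter()
        order = rng.permutation(n)
        model._train_mode = True
        losses = []
        for start in range(0, n, cfg.batch):
            idx = order[start : start + cfg.batch]
            loss, grads = model.loss_and_grads(Xtr_t[idx], ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch offset {start}; "
                    "reduce lr or inspect inputs"
                )
            losses.append(loss)
            step += 1
            for k, g in grads.items():
                mom[k] = b1 * mom[k] + (1 - b1) * g
                vel[k] = b2 * vel[k] + (1 - b2) * g * g
                mhat = mom[k] / (1 - b1**step)
                vhat = vel[k] / (1 - b2**step)
                upd = mhat / (np.sqrt(vhat) + eps)
                if cfg.weight_decay > 0 and model.params[k].ndim >= 2:
                    upd = upd + cfg.weight_decay * model.params[k]
                model.params[k] -= cfg.lr * upd
        model._train_mode = False
        acc = _accuracy(model, Xva, yva)
        hist.loss.append(float(np.mean(losses)))
        hist.accuracy.append(acc)
        hist.time_per_epoch.append(_time.perf_counter() - tic)
        if restore_best and acc > best_acc:
            best_acc = acc
            best_params = {k: v.copy() for k, v in model.params.items()}
        if verbose:
            print(f"epoch {epoch:3d}  loss {hist.loss[-1]:.4f}  val_acc {acc:.3f}")

    if restore_best and best_params is not None:
        model.params = best_params
    best = max(hist.accuracy)
    target = cfg.convergence_criterion * best
    for epoch, acc in enumerate(hist.accuracy, start=1):
        if acc >= target:
            hist.epochs_to_convergence = epoch
            hist.converged = True
            break
    return model, hist
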