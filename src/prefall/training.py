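"""Model training: focal loss, the fixed hyperparameters, epoch selection.

All three model families train under identical general hyperparameters —
batch size 64, 200 epochs, Adam at learning rate 0.0005 — with focal loss

    FL(p_t) = -alpha_t * (1 - p_t)**gamma * log(p_t)

averaged over the batch, which down-weights easy examples so the rare
pre-impact class is not swamped by the dominant non-fall windows.  At
``gamma = 0`` and unit alpha the loss reduces exactly to mean cross-entropy.

Epoch selection follows a sensitivity-first rule: among the three epochs
with the highest summed test sensitivity over all three classes, pick the
one maximizing the non-fall + pre-impact sum (earliest epoch on ties).
Because the rule reads test-fold sensitivities, it is optimistic — see
docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    ConfigError,
    DivergenceError,
    SelectionError,
    TrainingDataError,
)
from .nn.core import Adam
from .nn.models import Model
from .windows import WindowSet

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "focal_loss",
    "train_model",
    "select_best_epoch",
    "ChannelScaler",
]

logger = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass
class TrainConfig:
    batch_size: int = 64
    n_epochs: int = 200
    learning_rate: float = 5e-4
    loss: str = "focal"
    focal_gamma: float = 2.0
    # per-class weights; None -> inverse class frequency, normalized to mean 1
    focal_alpha: tuple[float, float, float] | None = None
    optimizer: str = "adam"
    seed: int = 0
    normalize: bool = True   # per-channel standardization with train statistics

    def __post_init__(self) -> None:
        if self.focal_gamma < 0:
            raise ConfigError("focal_gamma must be >= 0")
        if self.focal_alpha is not None and any(a <= 0 for a in self.focal_alpha):
            raise ConfigError("focal alpha weights must be > 0")
        if self.loss != "focal":
            raise ConfigError(f"unknown loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class EpochRecord:
    """Per-epoch learning-curve entry: losses and per-class sensitivities."""

    epoch: int
    train_loss: float
    test_loss: float
    train_sensitivity: tuple[float, float, float]
    test_sensitivity: tuple[float, float, float]
    # one-vs-rest confusion counts on the evaluation set per class:
    # {cls: (tp, fn, tn, fp)}
    test_counts: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)

    @property
    def test_sum(self) -> float:
        return float(sum(self.test_sensitivity))


def focal_loss(
    probs: np.ndarray,
    labels: np.ndarray,
    gamma: float = 2.0,
    alpha: Sequence[float] | float | None = None,
) -> float:
    """Batch-mean focal loss on softmax outputs."""
    loss, _ = _focal_loss_grad(probs, labels, gamma, alpha)
    return loss


def _alpha_vector(alpha, n_classes: int) -> np.ndarray:
    if alpha is None:
        return np.ones(n_classes)
    if np.isscalar(alpha):
        return np.full(n_classes, float(alpha))
    a = np.asarray(alpha, dtype=np.float64)
    if a.shape != (n_classes,):
        raise ConfigError(f"alpha must have {n_classes} entries")
    return a


def _focal_loss_grad(
    probs: np.ndarray,
    labels: np.ndarray,
    gamma: float,
    alpha,
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the probability rows."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    b, k = probs.shape
    a = _alpha_vector(alpha, k)
    p_t = probs[np.arange(b), labels]
    n_clamped = int((p_t < _EPS).sum())
    if n_clamped:
        logger.debug("focal loss clamped %d probabilities at %.0e", n_clamped, _EPS)
    p = np.clip(p_t, _EPS, 1.0)
    a_t = a[labels]
    one_minus = 1.0 - p
    loss = float(np.mean(-a_t * one_minus ** gamma * np.log(p)))
    # d/dp [-a (1-p)^g log p] = a g (1-p)^(g-1) log p - a (1-p)^g / p
    if gamma == 0.0:
        modulating = 0.0
    else:
        modulating = gamma * one_minus ** (gamma - 1.0) * np.log(p)
    dp = a_t * (modulating - one_minus ** gamma / p) / b
    grad = np.zeros_like(probs)
    grad[np.arange(b), labels] = dp
    return loss, grad


def inverse_frequency_alpha(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Per-class weights proportional to 1/frequency, normalized to mean 1."""
    counts = np.bincount(labels, minlength=n_classes).astype(np.float64)
    if (counts == 0).any():
        raise TrainingDataError(
            f"class(es) {np.where(counts == 0)[0].tolist()} absent from training set"
        )
    w = 1.0 / counts
    return w / w.mean()


class ChannelScaler:
    """Per-channel standardization fit on the training windows."""

    def __init__(self, mean: np.ndarray, sd: np.ndarray) -> None:
        self.mean = mean
        self.sd = sd

    @classmethod
    def fit(cls, windows: np.ndarray) -> "ChannelScaler":
        mean = windows.mean(axis=(0, 1))
        sd = windows.std(axis=(0, 1))
        sd = np.where(sd < 1e-12, 1.0, sd)
        return cls(mean, sd)

    def transform(self, windows: np.ndarray) -> np.ndarray:
        return (windows - self.mean) / self.sd


def _per_class_sensitivity(y_true: np.ndarray, y_pred: np.ndarray) -> tuple:
    out = []
    for cls in (0, 1, 2):
        m = y_true == cls
        out.append(float((y_pred[m] == cls).mean()) if m.any() else float("nan"))
    return tuple(out)


def _ovr_counts(y_true: np.ndarray, y_pred: np.ndarray, cls: int) -> tuple:
    pos = y_true == cls
    pred_pos = y_pred == cls
    tp = int((pos & pred_pos).sum())
    fn = int((pos & ~pred_pos).sum())
    fp = int((~pos & pred_pos).sum())
    tn = int((~pos & ~pred_pos).sum())
    return tp, fn, tn, fp


def train_model(
    model: Model,
    train_windows: WindowSet,
    eval_windows: WindowSet,
    config: TrainConfig | None = None,
    on_epoch: Callable[[Model, EpochRecord], None] | None = None,
) -> list[EpochRecord]:
    """Train in place; return one :class:`EpochRecord` per epoch.

    Fully deterministic given ``config.seed`` (initialization is the model
    builder's concern; this reseeds data order and dropout).  ``on_epoch``
    is an optional hook for checkpointing/parameter history.
    """
    cfg = config if config is not None else TrainConfig()
    if len(train_windows) == 0 or len(eval_windows) == 0:
        raise TrainingDataError("window sets must be non-empty")
    y_train = train_windows.labels
    alpha = (np.asarray(cfg.focal_alpha, dtype=np.float64)
             if cfg.focal_alpha is not None
             else inverse_frequency_alpha(y_train, model.config.n_classes))

    x_train = train_windows.windows
    x_eval = eval_windows.windows
    if cfg.normalize:
        scaler = ChannelScaler.fit(x_train)
        x_train = scaler.transform(x_train)
        x_eval = scaler.transform(x_eval)
    y_eval = eval_windows.labels

    rng = np.random.default_rng(cfg.seed)
    model.reseed_dropout(int(rng.integers(2 ** 31)))
    opt = Adam(model.params(), lr=cfg.learning_rate)
    records: list[EpochRecord] = []
    n = len(x_train)
    for epoch in range(cfg.n_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        # train-side learning curve accumulated from the training passes
        # themselves (running metric, dropout active)
        pred_train = np.empty(n, dtype=np.int64)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            probs = model.forward(x_train[idx], training=True)
            loss, dprobs = _focal_loss_grad(probs, y_train[idx], cfg.focal_gamma, alpha)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            pred_train[idx] = probs.argmax(axis=-1)
            model.zero_grad()
            model.backward(dprobs)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        probs_eval = model.predict_proba(x_eval)
        pred_eval = probs_eval.argmax(axis=-1)
        test_loss, _ = _focal_loss_grad(probs_eval, y_eval, cfg.focal_gamma, alpha)
        rec = EpochRecord(
            epoch=epoch,
            train_loss=epoch_loss / max(n_batches, 1),
            test_loss=float(test_loss),
            train_sensitivity=_per_class_sensitivity(y_train, pred_train),
            test_sensitivity=_per_class_sensitivity(y_eval, pred_eval),
            test_counts={c: _ovr_counts(y_eval, pred_eval, c) for c in (0, 1, 2)},
        )
        records.append(rec)
        logger.debug(
            "epoch %d: train loss %.4f, test sens %s",
            epoch, rec.train_loss,
            tuple(round(s, 3) for s in rec.test_sensitivity),
        )
        if on_epoch is not None:
            on_epoch(model, rec)
    return records


def select_best_epoch(records: Sequence[EpochRecord]) -> int:
    """Sensitivity-first epoch selection.

    Among the three epochs with the highest summed test sensitivity over all
    classes, return the one with the highest non-fall + pre-impact sum; ties
    break toward the earliest epoch.
    """
    if not records:
        raise SelectionError("cannot select an epoch from an empty history")
    def total(r: EpochRecord) -> float:
        return float(np.nansum(r.test_sensitivity))
    top3 = sorted(records, key=lambda r: (-total(r), r.epoch))[:3]
    def nonfall_pre(r: EpochRecord) -> float:
        return float(np.nansum(r.test_sensitivity[:2]))
    best = sorted(top3, key=lambda r: (-nonfall_pre(r), r.epoch))[0]
    return best.epoch


def records_to_frame(records: Sequence[EpochRecord]):
    """Epoch history as a DataFrame (one row per epoch), for CSV export."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append({
            "epoch": r.epoch,
            "train_loss": r.train_loss,
            "test_loss": r.test_loss,
            "train_sens_nonfall": r.train_sensitivity[0],
            "train_sens_preimpact": r.train_sensitivity[1],
            "train_sens_fall": r.train_sensitivity[2],
            "test_sens_nonfall": r.test_sensitivity[0],
            "test_sens_preimpact": r.test_sensitivity[1],
            "test_sens_fall": r.test_sensitivity[2],
        })
    return pd.DataFrame(rows)
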