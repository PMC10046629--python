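"""Dataset splitting, normalization, losses and the optimization loop.

Training follows the study's schedules: Adam at learning rate 5e-4 for
at most 30 epochs; if the monitored validation quantity does not improve
for ``plateau_patience`` consecutive epochs the learning rate is scaled
by 0.2, and training stops after ``stop_patience`` consecutive epochs
without improvement. Segmentation monitors validation Dice (batch size
8, Dice loss); classification monitors validation loss (batch size 16,
cross-entropy).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .nn.functional import softmax
from .synthetic_data import LABELS, LabeledSample

__all__ = [
    "FoldSplit",
    "TrainConfig",
    "NormalizationStats",
    "PlateauController",
    "make_folds",
    "compute_stats",
    "zscore_normalize",
    "dice_loss",
    "train_model",
    "samples_to_arrays",
]


# --- splits ----------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    fold_index: int  # 1-based
    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def subset(self, samples: list[LabeledSample], which: str) -> list[LabeledSample]:
        ids = set(getattr(self, f"{which}_ids"))
        return [s for s in samples if s.sample_id in ids]


def make_folds(dataset: list[LabeledSample], k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Stratified k-fold split after a seeded shuffle.

    Per fold: 20% of every class is test; 20% of the remaining training
    portion is validation; the rest is the fitting set. Every sample
    appears in exactly one fold's test set across the k folds.
    """
    by_class = {label: [s.sample_id for s in dataset if s.label == label]
                for label in LABELS}
    counts = {label: len(ids) for label, ids in by_class.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"dataset must be class-balanced, got {counts}")
    n = next(iter(counts.values()))
    if n % k != 0:
        raise ValueError(f"per-class count {n} not divisible by k={k}")
    rng = np.random.default_rng(seed)
    shuffled = {label: [ids[i] for i in rng.permutation(len(ids))]
                for label, ids in by_class.items()}
    chunk = n // k
    n_val = (n - chunk) // 5  # 20% of the training portion, per class
    folds = []
    for f in range(k):
        test, val, train = [], [], []
        for label in LABELS:
            ids = shuffled[label]
            chunks = [ids[c * chunk:(c + 1) * chunk] for c in range(k)]
            test.extend(chunks[f])
            remaining = [sid for c in range(1, k) for sid in chunks[(f + c) % k]]
            val.extend(remaining[:n_val])
            train.extend(remaining[n_val:])
        folds.append(FoldSplit(fold_index=f + 1, train_ids=tuple(train),
                               validation_ids=tuple(val), test_ids=tuple(test)))
    return folds


# --- normalization ---------------------------------------------------------

@dataclass(frozen=True)
class NormalizationStats:
    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.std):
            raise ValueError("per-channel std must be > 0")


def compute_stats(samples: list[LabeledSample]) -> NormalizationStats:
    """Per-channel mean/std over a set of images (training originals only)."""
    stack = np.stack([s.image for s in samples]).astype(np.float64)
    mean = stack.mean(axis=(0, 1, 2))
    std = stack.std(axis=(0, 1, 2))
    if np.any(std == 0):
        raise ValueError("zero per-channel std: cannot z-score a constant channel")
    return NormalizationStats(mean=tuple(mean), std=tuple(std))


def zscore_normalize(images: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """(x - M) / STD per channel on (..., H, W, 3) arrays."""
    mean = np.asarray(stats.mean, dtype=np.float32)
    std = np.asarray(stats.std, dtype=np.float32)
    return (np.asarray(images, dtype=np.float32) - mean) / std


# --- losses ----------------------------------------------------------------

def dice_loss(probabilities: np.ndarray, mask: np.ndarray, eps: float = 1.0) -> float:
    """Soft Dice loss 1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps).

    The smoothing term eps = 1 keeps empty-vs-empty pairs at loss 0
    instead of 0/0. Value lies in [0, 1).
    """
    p = np.asarray(probabilities, dtype=np.float64)
    g = np.asarray(mask, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    num = 2.0 * (p * g).sum() + eps
    den = p.sum() + g.sum() + eps
    return float(1.0 - num / den)


def _dice2_loss_grad(p: np.ndarray, mask: np.ndarray, eps: float = 1.0
                     ) -> tuple[float, np.ndarray]:
    """Two-channel (background + tumor) mean soft Dice loss and gradient.

    Averaging the per-image Dice over both softmax channels keeps a
    useful gradient on empty-mask (non-tumor) images, where the
    tumor-channel term alone vanishes as ~eps/denominator**2 and false
    positives would otherwise go unpenalized.
    """
    g = np.stack([1.0 - mask, mask], axis=1)  # (N, 2, H, W) one-hot
    num = 2.0 * (p * g).sum(axis=(2, 3)) + eps       # (N, 2)
    den = p.sum(axis=(2, 3)) + g.sum(axis=(2, 3)) + eps
    loss = float(np.mean(1.0 - num / den))
    grad = -(2.0 * g * den[..., None, None] - num[..., None, None]) / den[..., None, None] ** 2
    return loss, grad / (p.shape[0] * p.shape[1])


def _softmax_vjp(p: np.ndarray, dp: np.ndarray, axis: int = 1) -> np.ndarray:
    """Back-propagate through softmax: dz = p * (dp - sum_j dp_j p_j)."""
    return p * (dp - (dp * p).sum(axis=axis, keepdims=True))


# --- schedules -------------------------------------------------------------

class PlateauController:
    """Plateau learning-rate decay plus early stopping.

    An epoch "improves" when the monitored value is strictly better than
    the best so far (min-delta 0). After ``plateau_patience`` consecutive
    non-improving epochs the learning rate is multiplied by ``factor``
    (and the plateau counter resets); after ``stop_patience`` consecutive
    non-improving epochs training stops.
    """

    def __init__(self, lr: float, factor: float, plateau_patience: int,
                 stop_patience: int, mode: str = "min"):
        if mode not in ("min", "max"):
            raise ValueError("mode must be 'min' or 'max'")
        self.lr = lr
        self.factor = factor
        self.plateau_patience = plateau_patience
        self.stop_patience = stop_patience
        self.mode = mode
        self.best: float | None = None
        self._plateau = 0
        self._stall = 0

    def update(self, value: float) -> tuple[float, bool]:
        """Record one epoch's monitored value; returns (lr, stop)."""
        improved = (self.best is None
                    or (value < self.best if self.mode == "min" else value > self.best))
        if improved:
            self.best = value
            self._plateau = 0
            self._stall = 0
            return self.lr, False
        self._plateau += 1
        self._stall += 1
        if self._plateau >= self.plateau_patience:
            self.lr *= self.factor
            self._plateau = 0
        return self.lr, self._stall >= self.stop_patience


# --- training loop ---------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    optimizer: str = "adam"
    max_epochs: int = 30
    batch_size: int = 8
    plateau_patience: int = 10
    stop_patience: int = 15
    lr_factor: float = 0.2
    loss: str = "dice"
    folds: int = 5
    seed: int = 0

    @classmethod
    def segmentation(cls, **overrides) -> "TrainConfig":
        return cls(**{**dict(batch_size=8, plateau_patience=10, stop_patience=15,
                             loss="dice"), **overrides})

    @classmethod
    def classification(cls, **overrides) -> "TrainConfig":
        return cls(**{**dict(batch_size=16, plateau_patience=5, stop_patience=10,
                             loss="cross_entropy"), **overrides})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def samples_to_arrays(samples: list[LabeledSample]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack samples into NCHW images, (N, H, W) masks and label indices."""
    x = np.stack([s.image for s in samples]).transpose(0, 3, 1, 2).astype(np.float32)
    masks = np.stack([s.mask for s in samples]).astype(np.float32)
    labels = np.array([LABELS.index(s.label) for s in samples], dtype=np.int64)
    return x, masks, labels


def _eval_segmentation(network, x, masks, batch_size) -> tuple[float, float]:
    """Validation Dice-loss and mean per-image hard Dice, eval mode."""
    from .evaluation import pixel_metrics
    losses, dices = [], []
    for i in range(0, x.shape[0], batch_size):
        xb, gb = x[i:i + batch_size], masks[i:i + batch_size]
        p = softmax(network.forward(xb, training=False), axis=1)
        loss, _ = _dice2_loss_grad(p, gb)
        losses.append(loss * xb.shape[0])
        for j in range(xb.shape[0]):
            pred = (p[j, 1] > 0.5).astype(np.uint8)
            dices.append(pixel_metrics(pred, gb[j].astype(np.uint8)).dice)
    return float(np.sum(losses) / x.shape[0]), float(np.mean(dices))


def _eval_classification(network, x, labels, batch_size) -> tuple[float, float]:
    """Validation cross-entropy and accuracy, eval mode."""
    losses, correct = [], 0
    for i in range(0, x.shape[0], batch_size):
        xb, yb = x[i:i + batch_size], labels[i:i + batch_size]
        p = softmax(network.forward(xb, training=False), axis=1)
        losses.append(-np.log(np.clip(p[np.arange(len(yb)), yb], 1e-12, None)).sum())
        correct += int((p.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / x.shape[0]), correct / x.shape[0]


def train_model(network, train: list[LabeledSample], val: list[LabeledSample],
                config: TrainConfig, task: str) -> pd.DataFrame:
    """Optimize ``network`` in place; returns the per-epoch history.

    ``task`` is "segmentation" (Dice loss, monitors validation Dice,
    maximized) or "classification" (cross-entropy, monitors validation
    loss, minimized). Inputs are expected already normalized. Fully
    seeded and deterministic.
    """
    if task not in ("segmentation", "classification"):
        raise ValueError(f"unknown task {task!r}")
    if not train:
        raise ValueError("empty training set")
    if not val:
        raise ValueError("empty validation set (dataset too small for the split)")
    x_tr, m_tr, y_tr = samples_to_arrays(train)
    x_va, m_va, y_va = samples_to_arrays(val)
    rng = np.random.default_rng(config.seed)
    opt = network.make_optimizer(config.learning_rate)
    monitor = PlateauController(
        lr=config.learning_rate, factor=config.lr_factor,
        plateau_patience=config.plateau_patience, stop_patience=config.stop_patience,
        mode="max" if task == "segmentation" else "min")
    history = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(x_tr.shape[0])
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = x_tr[idx]
            opt.zero_grad()
            logits = network.forward(xb, training=True)
            p = softmax(logits, axis=1)
            if task == "segmentation":
                loss, dp = _dice2_loss_grad(p, m_tr[idx])
                dlogits = _softmax_vjp(p, dp, axis=1)
            else:
                yb = y_tr[idx]
                loss = float(-np.log(
                    np.clip(p[np.arange(len(yb)), yb], 1e-12, None)).mean())
                onehot = np.zeros_like(p)
                onehot[np.arange(len(yb)), yb] = 1.0
                dlogits = (p - onehot) / len(yb)
            network.backward(dlogits.astype(np.float32))
            opt.step()
            epoch_loss += loss * len(idx)
            seen += len(idx)
        if task == "segmentation":
            val_loss, val_metric = _eval_segmentation(network, x_va, m_va,
                                                      config.batch_size)
            monitored = val_metric
        else:
            val_loss, val_metric = _eval_classification(network, x_va, y_va,
                                                        config.batch_size)
            monitored = val_loss
        lr, stop = monitor.update(monitored)
        history.append({"epoch": epoch, "lr": opt.lr,
                        "train_loss": epoch_loss / max(seen, 1),
                        "val_loss": val_loss, "val_metric": val_metric})
        opt.lr = lr
        if stop:
            break
    return pd.DataFrame(history)
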