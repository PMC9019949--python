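"""Training: smooth-L1 loss, length-homogeneous batching, per-batch split.

The regression target (GDT-TS) lives in [0, 1], so residuals are small and
the loss almost always runs in its quadratic branch; the linear branch caps
the influence of outliers.  Difference maps of different proteins have
different side lengths L, so records are grouped into batches of a single L
("length-homogeneous" batches) and, following the training protocol, each
batch is split 80/20 into training and validation members so both splits
cover the full length distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .layers import Adam
from .maps import ModelRecord
from .network import ConfigError, SECNN

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters (Adam, constant learning rate)."""

    learning_rate: float = 5e-5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 16
    epochs: int = 120
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigError("split_fraction must lie strictly in (0, 1)")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be non-negative")
        if self.epochs < 0:
            raise ConfigError("epochs must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**{k: v for k, v in d.items()
                      if k in cls.__dataclass_fields__})


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def smooth_l1(x):
    """Smooth-L1 loss of a residual: 0.5 x^2 for |x| < 1, |x| - 0.5 otherwise.

    Quadratic near zero (differentiable at 0), linear in the tails (robust to
    outliers); the two branches meet continuously at |x| = 1 where both
    evaluate to 0.5.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("smooth_l1 residual must be finite")
    ax = np.abs(x)
    out = np.where(ax < 1.0, 0.5 * x * x, ax - 0.5)
    return out if out.ndim else float(out)


def smooth_l1_derivative(x):
    """d/dx of the smooth-L1 loss: x on (-1, 1), clamped to -1/+1 outside.

    At |x| = 1 both branches agree; the closed-interval convention returns
    the saturated value there.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("smooth_l1 residual must be finite")
    out = np.clip(x, -1.0, 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Batching and splitting
# ---------------------------------------------------------------------------

def make_length_batches(
    records: Sequence[ModelRecord],
    batch_size: int,
    seed: int = 0,
) -> list[list[ModelRecord]]:
    """Partition records into shuffled batches of a single sequence length.

    Every batch holds at most ``batch_size`` records, all with the same L;
    the shuffle (within each length group and of the final batch order) is a
    deterministic function of the seed.
    """
    rng = np.random.default_rng(seed)
    by_length: dict[int, list[ModelRecord]] = {}
    for rec in records:
        by_length.setdefault(rec.length, []).append(rec)
    batches: list[list[ModelRecord]] = []
    for length in sorted(by_length):
        group = by_length[length]
        order = rng.permutation(len(group))
        group = [group[i] for i in order]
        for start in range(0, len(group), batch_size):
            batches.append(group[start : start + batch_size])
    if batches:
        batches = [batches[i] for i in rng.permutation(len(batches))]
    return batches


def split_batches(
    batches: Sequence[Sequence[ModelRecord]],
    split_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[ModelRecord], list[ModelRecord]]:
    """Per-batch random split into training and validation records.

    From each batch, ``round(split_fraction * size)`` randomly chosen records
    (at least 1 whenever the batch has >= 2) join the training set and the
    remainder the validation set.  A singleton batch goes entirely to
    training.  The two sets partition the input exactly.
    """
    if not 0.0 < split_fraction < 1.0:
        raise ConfigError("split_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[ModelRecord] = []
    val: list[ModelRecord] = []
    for batch in batches:
        n = len(batch)
        if n == 1:
            train.extend(batch)
            continue
        k = int(round(split_fraction * n))
        k = min(max(k, 1), n)
        order = rng.permutation(n)
        chosen = set(order[:k].tolist())
        for i, rec in enumerate(batch):
            (train if i in chosen else val).append(rec)
    return train, val


# ---------------------------------------------------------------------------
# The training loop
# ---------------------------------------------------------------------------

@dataclass
class EpochStats:
    epoch: int
    train_loss: float
    val_loss: Optional[float]


@dataclass
class TrainHistory:
    epochs: list[EpochStats] = field(default_factory=list)
    best_epoch: int = 0
    best_val_loss: Optional[float] = None

    def to_rows(self) -> list[dict]:
        return [
            {"epoch": e.epoch, "train_loss": e.train_loss,
             "val_loss": "" if e.val_loss is None else e.val_loss}
            for e in self.epochs
        ]


def _batch_arrays(batch: Sequence[ModelRecord]):
    x = np.stack([r.difference_map.values for r in batch])[:, None, :, :]
    y = np.array([r.true_gdtts for r in batch], dtype=np.float64)
    if np.any([r.true_gdtts is None for r in batch]):
        raise ValueError("training requires a true score on every record")
    return x, y


def dataset_loss(network: SECNN, records: Sequence[ModelRecord],
                 batch_size: int = 16) -> float:
    """Mean smooth-L1 loss over records, evaluation-mode forward pass."""
    batches = make_length_batches(records, batch_size, seed=0)
    total, n = 0.0, 0
    for batch in batches:
        x, y = _batch_arrays(batch)
        pred = network.forward(x, train=False)[:, 0].astype(np.float64)
        total += float(np.sum(smooth_l1(pred - y)))
        n += len(batch)
    return total / n if n else float("nan")


def train(
    network: SECNN,
    train_records: Sequence[ModelRecord],
    val_records: Sequence[ModelRecord],
    config: TrainConfig,
) -> tuple[SECNN, TrainHistory]:
    """Optimize the network with Adam on mean smooth-L1 batch loss.

    Epoch 0 of the history is the pre-training evaluation; each subsequent
    entry is the post-step evaluation-mode loss on both splits.  Batch order
    (not batch membership) is reshuffled each epoch.  The state with the
    lowest validation loss is restored into the returned network.
    """
    if len(train_records) == 0:
        raise ValueError("training set is empty")
    if len(val_records) == 0:
        logger.warning("validation set is empty; history carries train loss only")

    opt = Adam(network.parameters(), config.learning_rate,
               config.adam_beta1, config.adam_beta2)
    batches = make_length_batches(train_records, config.batch_size,
                                  seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    def evaluate_epoch(epoch: int) -> EpochStats:
        tl = dataset_loss(network, train_records, config.batch_size)
        vl = (dataset_loss(network, val_records, config.batch_size)
              if len(val_records) else None)
        return EpochStats(epoch, tl, vl)

    history = TrainHistory()
    stats = evaluate_epoch(0)
    history.epochs.append(stats)
    best_state = network.copy_state()
    best_val = stats.val_loss if stats.val_loss is not None else stats.train_loss
    history.best_epoch, history.best_val_loss = 0, best_val

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(batches))
        running, seen = 0.0, 0
        for bi in order:
            batch = batches[bi]
            x, y = _batch_arrays(batch)
            opt.zero_grad()
            pred = network.forward(x, train=True)[:, 0].astype(np.float64)
            residual = pred - y
            running += float(np.sum(smooth_l1(residual)))
            seen += len(batch)
            grad = (smooth_l1_derivative(residual) / len(batch))[:, None]
            network.backward(grad)
            opt.step()
        vl = (dataset_loss(network, val_records, config.batch_size)
              if len(val_records) else None)
        history.epochs.append(EpochStats(epoch, running / seen, vl))
        monitored = vl if vl is not None else running / seen
        if monitored < best_val:
            best_val = monitored
            best_state = network.copy_state()
            history.best_epoch = epoch
            history.best_val_loss = monitored
    network.load_state_dict(best_state)
    return network, history
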