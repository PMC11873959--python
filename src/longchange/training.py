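"""Task losses, the optimization loop, early stopping and model selection.

Training minimizes binary cross-entropy on sigmoid(r) for the ordering task
and mean squared error of r against the time/target difference for the
regression tasks, with Adam (standard defaults, learning rate 1e-3).
Each unordered pair is presented once per epoch in a freshly randomized
orientation, so order labels stay balanced in expectation.  Early stopping
halts training after ``patience`` consecutive epochs without a new best
validation loss; the best-epoch weights are restored afterwards.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import nn
from .data import LongitudinalPair, minmax_normalize
from .model import ComparisonNetwork

__all__ = ["TrainConfig", "TrainReport", "loss", "train", "early_stop_epoch"]


@dataclass
class TrainConfig:
    task: str = "ordering"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 10
    curriculum: bool = False
    curriculum_start: float = 50.0
    curriculum_step_epochs: int = 2
    curriculum_warmup_epochs: int = 10
    reorient_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TrainReport:
    """Per-epoch traces plus the selected (best validation loss) epoch."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    val_metrics: list[float] = field(default_factory=list)
    metric_name: str = ""
    selected_epoch: int = -1
    stopped_epoch: int = -1


def loss(task: str, outputs: np.ndarray, labels: np.ndarray) -> float:
    """Batch-mean loss: BCE on sigmoid(r) for ordering, else squared error."""
    outputs = np.asarray(outputs, float)
    labels = np.asarray(labels, float)
    if task == "ordering":
        if not np.isin(labels, (0.0, 1.0)).all():
            raise ValueError("ordering labels must be 0/1")
        # numerically stable BCE-with-logits
        value = float(np.mean(
            np.maximum(outputs, 0) - outputs * labels + np.log1p(np.exp(-np.abs(outputs)))))
    elif task in ("interval", "score"):
        if not np.isfinite(labels).all():
            raise ValueError("regression targets must be finite")
        value = float(np.mean((outputs - labels) ** 2))
    else:
        raise ValueError(f"unknown task {task!r}")
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite {task} loss (outputs range "
            f"[{outputs.min():.3g}, {outputs.max():.3g}])")
    return value


def early_stop_epoch(val_losses: list[float], patience: int) -> tuple[int, int]:
    """(best_epoch, stop_epoch) under patience-based early stopping.

    Training halts at the first epoch whose trailing ``patience`` epochs all
    failed to improve on the best validation loss seen so far; ties keep the
    earliest epoch.  ``stop_epoch`` is the last epoch actually run.
    """
    best, best_epoch, since = np.inf, 0, 0
    for e, v in enumerate(val_losses):
        if v < best:
            best, best_epoch, since = v, e, 0
        else:
            since += 1
            if since >= patience:
                return best_epoch, e
    return best_epoch, len(val_losses) - 1


def _pair_tensors(pairs: list[LongitudinalPair], task: str, meta_dim: int):
    """Preload pairs into chronological arrays (early image, late image, dt, dy)."""
    early = np.stack([
        minmax_normalize(sorted([p.first, p.second], key=lambda r: r.time)[0].load())
        for p in pairs])[:, None]
    late = np.stack([
        minmax_normalize(sorted([p.first, p.second], key=lambda r: r.time)[1].load())
        for p in pairs])[:, None]
    dt = np.array([abs(p.delta_time) for p in pairs])
    if task == "score":
        dy = np.array([
            p.delta_target if p.order_label else -p.delta_target for p in pairs])
    else:
        dy = dt.copy()
    if meta_dim:
        dmeta = np.stack([
            np.asarray(sorted([p.first, p.second], key=lambda r: r.time)[1].metadata, float)
            - np.asarray(sorted([p.first, p.second], key=lambda r: r.time)[0].metadata, float)
            for p in pairs])
    else:
        dmeta = None
    return early.astype(np.float32), late.astype(np.float32), dt, dy, dmeta


def _epoch_pass(net: ComparisonNetwork, tensors, idx, orient, task, optimizer):
    """One training pass over the given pair indices.

    ``orient`` holds +1/-1 per pair: +1 presents the pair chronologically
    (order label 1, presented delta = +|dt|), -1 reverses it.
    """
    early, late, dt, dy, dmeta = tensors
    total, count = 0.0, 0
    bs = optimizer.batch_size
    for start in range(0, len(idx), bs):
        sel = idx[start:start + bs]
        s = orient[sel]
        chron = (s > 0).reshape((-1,) + (1,) * (early.ndim - 1))
        first = np.where(chron, early[sel], late[sel])
        second = np.where(chron, late[sel], early[sel])
        dm = None if dmeta is None else dmeta[sel] * s[:, None]
        labels = (s > 0).astype(float) if task == "ordering" else s * dy[sel]
        r, feats = net.batch_logits(first, second, dm, train=True)
        total += loss(task, r, labels) * len(sel)
        count += len(sel)
        B = len(sel)
        if task == "ordering":
            dr = (expit(r) - labels) / B
        else:
            dr = 2.0 * (r - labels) / B
        diff = feats[:B] - feats[B:]
        head_grad = np.zeros_like(net.head.w, dtype=np.float64)
        head_grad[: net.extractor.feature_dim] = dr @ diff
        if dm is not None:
            head_grad[net.extractor.feature_dim:] = dr @ dm
        net.head.grads["w"][...] = head_grad.astype(np.float32)
        w_img = net.head_image_weights.astype(np.float32)
        dfeat = np.concatenate([
            dr[:, None] * w_img[None, :], -dr[:, None] * w_img[None, :]],
            axis=0).astype(np.float32)
        net.extractor.backward(dfeat)
        optimizer.step()
    return total / max(count, 1)


def _val_metric(task: str, r: np.ndarray, labels: np.ndarray) -> tuple[str, float]:
    from . import stats

    if task == "ordering":
        if len(np.unique(labels)) < 2:
            return "auc", float("nan")
        return "auc", stats.auc(labels, r)
    m = stats.regression_metrics(labels, r)
    return "r2", m.r2


def train(net: ComparisonNetwork, train_pairs: list[LongitudinalPair],
          val_pairs: list[LongitudinalPair], config: TrainConfig) -> TrainReport:
    """Fit the comparison network with Adam, curriculum and early stopping."""
    train_subj = {p.subject_id for p in train_pairs}
    val_subj = {p.subject_id for p in val_pairs}
    overlap = train_subj & val_subj
    if overlap:
        raise ValueError(
            f"subject leakage between train and validation: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(config.seed)
    task = config.task
    meta_dim = net.config.metadata_dim
    tensors = _pair_tensors(train_pairs, task, meta_dim)
    val_tensors = _pair_tensors(val_pairs, task, meta_dim)
    train_dt = tensors[2]
    # fixed validation orientation for a stable early-stopping signal
    val_orient = np.where(np.arange(len(val_pairs)) % 2 == 0, 1.0, -1.0)
    val_idx = np.arange(len(val_pairs))

    optimizer = nn.Adam(net.trainable_entries(), lr=config.learning_rate)
    optimizer.batch_size = config.batch_size
    report = TrainReport(metric_name="auc" if task == "ordering" else "r2")
    best_state, best_loss = None, np.inf
    since_improve = 0
    base_orient = np.where(rng.random(len(train_pairs)) < 0.5, 1.0, -1.0)

    for epoch in range(config.max_epochs):
        if config.reorient_each_epoch:
            orient = np.where(rng.random(len(train_pairs)) < 0.5, 1.0, -1.0)
        else:
            orient = base_orient
        idx = np.arange(len(train_pairs))
        if config.curriculum:
            keep = _curriculum_indices(train_dt, epoch, config)
            idx = idx[keep]
        rng.shuffle(idx)
        train_loss = _epoch_pass(net, tensors, idx, orient, task, optimizer)
        # validation in inference mode
        r_val, labels_val = _validate(net, val_tensors, val_orient, task)
        val_loss = loss(task, r_val, labels_val)
        _, metric = _val_metric(task, r_val, labels_val)
        report.train_losses.append(train_loss)
        report.val_losses.append(val_loss)
        report.val_metrics.append(metric)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = copy.deepcopy(net.state())
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break
    report.stopped_epoch = len(report.val_losses) - 1
    report.selected_epoch, _ = early_stop_epoch(report.val_losses, config.patience)
    if best_state is not None:
        net.load_state(best_state)
    return report


def _validate(net: ComparisonNetwork, tensors, orient, task):
    early, late, dt, dy, dmeta = tensors
    rs, labels = [], []
    for start in range(0, len(dt), 64):
        sel = np.arange(start, min(start + 64, len(dt)))
        s = orient[sel]
        chron = (s > 0).reshape((-1,) + (1,) * (early.ndim - 1))
        first = np.where(chron, early[sel], late[sel])
        second = np.where(chron, late[sel], early[sel])
        dm = None if dmeta is None else dmeta[sel] * s[:, None]
        r, _ = net.batch_logits(first, second, dm, train=False)
        rs.append(r)
        if task == "ordering":
            labels.append((s > 0).astype(float))
        else:
            labels.append(s * dy[sel])
    return np.concatenate(rs), np.concatenate(labels)


def _curriculum_indices(dt: np.ndarray, epoch: int, config: TrainConfig) -> np.ndarray:
    frac = min(1.0, (epoch // config.curriculum_step_epochs)
               * config.curriculum_step_epochs / config.curriculum_warmup_epochs)
    threshold = config.curriculum_start * (1.0 - frac)
    keep = dt > threshold
    while not keep.any() and threshold > 0:
        threshold = max(0.0, threshold - config.curriculum_start
                        * config.curriculum_step_epochs / config.curriculum_warmup_epochs)
        warnings.warn(
            f"curriculum produced an empty epoch; relaxing threshold to {threshold:.3g}")
        keep = dt > threshold
    return keep
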