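"""Pairwise comparison network and the single-image regression baseline.

The comparison model is a Siamese design: one shared four-block
convolutional extractor ``f`` maps each image of a within-subject pair to a
flattened feature vector, optional per-timepoint metadata ``M`` is
concatenated to each branch, and a bias-free linear head ``w`` scores the
difference:

    r(I1, I2) = w^T ((f(I1) ++ M1) - (f(I2) ++ M2))

Because the head has no intercept and acts on a difference, the score is
reflexive (r(a,a)=0), antisymmetric (r(a,b)=-r(b,a)) and additively
transitive (r(a,b)+r(b,c)=r(a,c)) by construction.  For the temporal
ordering task the probability that the presented order is chronological is
``sigmoid(r)``; for interval/score regression ``r`` itself is the predicted
change.

The statsmodels-style entry points are :class:`PairwiseChangeModel`
(constructed from records or a manifest; ``fit`` trains the network) and
:class:`PairwiseChangeResults` (prediction, evaluation, saliency,
mixed-model analysis, ``summary()``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import nn
from .data import (ImageRecord, LongitudinalPair, make_pairs, minmax_normalize,
                   read_manifest, split_subjects, max_interval_pairs)

__all__ = [
    "ModelConfig",
    "ComparisonResult",
    "ComparisonNetwork",
    "SingleImageRegressor",
    "PairwiseChangeModel",
    "PairwiseChangeResults",
    "compare",
    "predict_order_probability",
    "sirb_predict",
    "sirb_change",
]

TASKS = ("ordering", "interval", "score")


@dataclass
class ModelConfig:
    """Architecture hyperparameters for the comparison network."""

    spatial_dims: int = 2
    image_size: int = 64
    block_channels: tuple[int, int, int, int] = (8, 16, 32, 32)
    kernel_size: int = 3
    pooling: str = "avg"
    pool_window: int = 2
    metadata_dim: int = 0
    task: str = "ordering"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_channels) != 4:
            raise ValueError("exactly four convolutional blocks are required")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")


@dataclass
class ComparisonResult:
    """Output of one pairwise comparison."""

    logit: float
    probability: float | None
    features_first: np.ndarray
    features_second: np.ndarray


def predict_order_probability(r: float | np.ndarray) -> float | np.ndarray:
    """Sigmoid of the comparison score: P(presented order is chronological)."""
    return expit(r)


def compare(f, w: np.ndarray, image1: np.ndarray, image2: np.ndarray,
            metadata1: np.ndarray | None = None,
            metadata2: np.ndarray | None = None,
            probability: bool = False) -> ComparisonResult:
    """Score a pair with an arbitrary feature extractor ``f`` and head ``w``.

    ``f`` maps one image to a 1-D feature vector.  Metadata must be supplied
    for both images or neither; its length plus the feature length must
    match ``len(w)`` (the head has no bias term).
    """
    if (metadata1 is None) != (metadata2 is None):
        raise ValueError("metadata must be present for both images or neither")
    f1 = np.asarray(f(image1), dtype=float).ravel()
    f2 = np.asarray(f(image2), dtype=float).ravel()
    if metadata1 is not None:
        m1, m2 = np.asarray(metadata1, float).ravel(), np.asarray(metadata2, float).ravel()
        if m1.shape != m2.shape:
            raise ValueError(
                f"metadata length mismatch: {m1.shape} vs {m2.shape}")
        f1, f2 = np.concatenate([f1, m1]), np.concatenate([f2, m2])
    w = np.asarray(w, float).ravel()
    if w.shape != f1.shape:
        raise ValueError(
            f"head length {w.size} does not match feature(+metadata) length {f1.size}")
    r = float(w @ (f1 - f2))
    return ComparisonResult(r, float(expit(r)) if probability else None, f1, f2)


class _Head:
    """Bias-free linear head; holds its weight and gradient like a layer."""

    def __init__(self, dim: int, rng: np.random.Generator, dtype=np.float32) -> None:
        self.params = {"w": (rng.normal(0.0, 1.0 / np.sqrt(dim), dim)).astype(dtype)}
        self.grads = {"w": np.zeros(dim, dtype=dtype)}

    @property
    def w(self) -> np.ndarray:
        return self.params["w"]


class ComparisonNetwork:
    """Shared extractor + bias-free difference head, with training hooks."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.extractor = nn.FeatureExtractor(
            ndim=config.spatial_dims, input_size=config.image_size,
            channels=config.block_channels, kernel=config.kernel_size,
            pool=config.pooling, pool_window=config.pool_window, rng=rng)
        self.head = _Head(self.extractor.feature_dim + config.metadata_dim, rng)

    # -- inference ---------------------------------------------------------
    def features(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        return self.extractor.forward(images, train=train)

    @property
    def head_image_weights(self) -> np.ndarray:
        return self.head.w[: self.extractor.feature_dim]

    def compare_arrays(self, img1: np.ndarray, img2: np.ndarray,
                       meta1: np.ndarray | None = None,
                       meta2: np.ndarray | None = None) -> ComparisonResult:
        """Score one normalized pair in inference mode."""
        if self.config.metadata_dim and meta1 is None:
            raise ValueError("model was built with metadata; none supplied")
        def f(img):
            x = minmax_normalize(np.asarray(img))[None]
            return self.features(x)[0]
        res = compare(f, self.head.w.astype(float), img1, img2, meta1, meta2,
                      probability=self.config.task == "ordering")
        return res

    def compare_pair(self, pair: LongitudinalPair) -> ComparisonResult:
        return self.compare_arrays(pair.first.load(), pair.second.load(),
                                   pair.first.metadata, pair.second.metadata)

    def batch_logits(self, img_first: np.ndarray, img_second: np.ndarray,
                     dmeta: np.ndarray | None = None,
                     train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Scores for a batch of pairs; both branches share one forward pass.

        Returns (r, feats) where feats stacks first-branch then second-branch
        features, as needed by the training backward pass.
        """
        B = img_first.shape[0]
        stacked = np.concatenate([img_first, img_second], axis=0)
        feats = self.features(stacked, train=train)
        diff = feats[:B] - feats[B:]
        r = diff @ self.head_image_weights.astype(feats.dtype)
        if self.config.metadata_dim:
            if dmeta is None:
                raise ValueError("model was built with metadata; none supplied")
            r = r + dmeta.astype(feats.dtype) @ self.head.w[self.extractor.feature_dim:]
        return r.astype(np.float64), feats

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path, card_extra: dict | None = None) -> None:
        """Write weights to <path>.npz and a model-card JSON to <path>.json."""
        path = Path(path)
        state = self.extractor.state_dict()
        state["head.w"] = self.head.w.copy()
        np.savez(Path(str(path) + ".npz"), **state)
        card = {"config": asdict(self.config),
                "n_parameters": self.n_parameters()}
        if card_extra:
            card.update(card_extra)
        Path(str(path) + ".json").write_text(json.dumps(card, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ComparisonNetwork":
        card = json.loads(Path(str(path) + ".json").read_text())
        cfg = card["config"]
        cfg["block_channels"] = tuple(cfg["block_channels"])
        net = cls(ModelConfig(**cfg))
        state = dict(np.load(Path(str(path) + ".npz")))
        net.head.params["w"] = state.pop("head.w").astype(np.float32)
        net.head.grads["w"] = np.zeros_like(net.head.w)
        net.extractor.load_state_dict(state)
        return net

    def state(self) -> dict[str, np.ndarray]:
        s = self.extractor.state_dict()
        s["head.w"] = self.head.w.copy()
        return s

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        state = dict(state)
        self.head.params["w"] = state.pop("head.w").copy()
        self.extractor.load_state_dict(state)

    def trainable_entries(self) -> list[tuple[object, str]]:
        entries = [(layer, name) for _, layer, name, _ in self.extractor.named_params()]
        entries.append((self.head, "w"))
        return entries

    def n_parameters(self) -> int:
        return self.extractor.n_parameters() + self.head.w.size


class SingleImageRegressor:
    """Single-image regression baseline: predict the target per image.

    The same extractor family (max pooling by default) feeds a linear output
    head *with* a bias; the change estimate for a pair is the difference of
    the two single-image predictions, g(I2, M2) - g(I1, M1).
    """

    def __init__(self, config: ModelConfig) -> None:
        if config.pooling == "avg":
            config = ModelConfig(**{**asdict(config), "pooling": "max"})
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.extractor = nn.FeatureExtractor(
            ndim=config.spatial_dims, input_size=config.image_size,
            channels=config.block_channels, kernel=config.kernel_size,
            pool=config.pooling, pool_window=config.pool_window, rng=rng)
        dim = self.extractor.feature_dim + config.metadata_dim
        self.head = _Head(dim, rng)
        self.params = {"b": np.zeros(1, dtype=np.float32)}
        self.grads = {"b": np.zeros(1, dtype=np.float32)}

    def predict(self, image: np.ndarray, metadata: np.ndarray | None = None,
                f=None) -> float:
        return sirb_predict(self._g(f), image, metadata)

    def change(self, image1: np.ndarray, image2: np.ndarray,
               metadata1: np.ndarray | None = None,
               metadata2: np.ndarray | None = None, f=None) -> float:
        return sirb_change(self._g(f), image1, image2, metadata1, metadata2)

    def _g(self, f=None):
        if f is not None:
            return f
        def g(image, metadata=None):
            x = minmax_normalize(np.asarray(image))[None]
            phi = self.extractor.forward(x)[0].astype(float)
            if metadata is not None:
                phi = np.concatenate([phi, np.asarray(metadata, float).ravel()])
            return float(self.head.w.astype(float) @ phi + self.params["b"][0])
        return g

    def trainable_entries(self) -> list[tuple[object, str]]:
        entries = [(layer, name) for _, layer, name, _ in self.extractor.named_params()]
        entries.append((self.head, "w"))
        entries.append((self, "b"))
        return entries


def sirb_predict(g, image: np.ndarray, metadata: np.ndarray | None = None) -> float:
    """Apply a single-image regressor ``g(image[, metadata])``."""
    try:
        return float(g(image, metadata))
    except TypeError:
        return float(g(image))


def sirb_change(g, image1: np.ndarray, image2: np.ndarray,
                metadata1: np.ndarray | None = None,
                metadata2: np.ndarray | None = None) -> float:
    """Baseline change estimate: difference of single-image predictions."""
    if (metadata1 is None) != (metadata2 is None):
        raise ValueError("metadata must be present for both images or neither")
    if metadata1 is not None:
        m1, m2 = np.asarray(metadata1).ravel(), np.asarray(metadata2).ravel()
        if m1.shape != m2.shape:
            raise ValueError(f"metadata length mismatch: {m1.shape} vs {m2.shape}")
    return sirb_predict(g, image2, metadata2) - sirb_predict(g, image1, metadata1)


class PairwiseChangeModel:
    """Pairwise temporal-change model bound to a longitudinal dataset.

    Parameters
    ----------
    records
        All timepoints of all subjects.  They are split subject-wise into
        train/validation/test sets and expanded into within-subject pairs.
    task
        ``"ordering"`` (was the pair presented chronologically?),
        ``"interval"`` (predict the time difference) or ``"score"``
        (predict the target-variable difference, optionally controlling for
        metadata covariates).
    """

    def __init__(self, records: list[ImageRecord], task: str = "ordering",
                 config: ModelConfig | None = None,
                 split_fractions: tuple[float, ...] = (0.6, 0.2, 0.2),
                 seed: int = 0, both_orders: bool = False,
                 max_pairs_per_subject: int | None = None) -> None:
        if task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        self.records = records
        self.task = task
        self.seed = seed
        img = records[0].load()
        meta_dim = 0 if records[0].metadata is None else len(records[0].metadata)
        if config is None:
            config = ModelConfig(spatial_dims=img.ndim, image_size=img.shape[0],
                                 metadata_dim=meta_dim, task=task, seed=seed)
        self.config = config
        self.train_records, self.val_records, self.test_records = split_subjects(
            records, split_fractions, seed=seed)
        rng = np.random.default_rng(seed + 1)
        kw = dict(task=task, rng=rng, both_orders=both_orders,
                  max_pairs_per_subject=max_pairs_per_subject)
        self.train_pairs = make_pairs(self.train_records, **kw)
        self.val_pairs = make_pairs(self.val_records, **kw)
        self.test_pairs = make_pairs(self.test_records, **kw)
        self.network = ComparisonNetwork(config)

    @classmethod
    def from_manifest(cls, path: str | Path, task: str = "ordering",
                      **kwargs) -> "PairwiseChangeModel":
        return cls(read_manifest(path), task=task, **kwargs)

    def fit(self, train_config=None, **kwargs) -> "PairwiseChangeResults":
        """Train the comparison network; returns a results object."""
        from .training import TrainConfig, train

        if train_config is None:
            kwargs.setdefault("task", self.task)
            kwargs.setdefault("seed", self.seed)
            train_config = TrainConfig(**kwargs)
        report = train(self.network, self.train_pairs, self.val_pairs, train_config)
        return PairwiseChangeResults(self, self.network, report)


class PairwiseChangeResults:
    """Fitted comparison model: predictions, metrics, saliency, LME analysis."""

    def __init__(self, model: PairwiseChangeModel, network: ComparisonNetwork,
                 report) -> None:
        self.model = model
        self.network = network
        self.report = report

    # -- prediction --------------------------------------------------------
    def predict(self, pairs: list[LongitudinalPair] | None = None) -> pd.DataFrame:
        """Per-pair comparison scores as a tidy frame."""
        pairs = self.model.test_pairs if pairs is None else pairs
        rows = []
        for p in pairs:
            res = self.network.compare_pair(p)
            rows.append({
                "subject_id": p.subject_id,
                "time_first": p.first.time, "time_second": p.second.time,
                "delta_time": p.delta_time, "delta_target": p.delta_target,
                "order_label": p.order_label, "logit": res.logit,
                "probability": res.probability,
            })
        return pd.DataFrame(rows)

    # -- evaluation --------------------------------------------------------
    def evaluate(self, pairs: list[LongitudinalPair] | None = None,
                 n_boot: int = 1000, seed: int = 0):
        """Task-appropriate metrics with naive baselines; see ``stats``."""
        from . import stats

        pairs = self.model.test_pairs if pairs is None else pairs
        preds = self.predict(pairs)
        if self.model.task == "ordering":
            return stats.evaluate_ordering(
                preds["order_label"].to_numpy(),
                preds["logit"].to_numpy(), n_boot=n_boot, seed=seed)
        truth = preds["delta_time"] if self.model.task == "interval" \
            else preds["delta_target"]
        return stats.evaluate_regression(truth.to_numpy(), preds["logit"].to_numpy())

    def pearson_ordered(self, pairs: list[LongitudinalPair] | None = None
                        ) -> tuple[float, float]:
        """PCC between prediction and truth on chronologically ordered pairs."""
        from . import stats

        pairs = self.model.test_pairs if pairs is None else pairs
        preds = self.predict(pairs)
        preds = preds[preds["delta_time"] > 0]
        truth = preds["delta_time"] if self.model.task != "score" \
            else preds["delta_target"]
        return stats.pearson(truth.to_numpy(), preds["logit"].to_numpy())

    def lme(self, pairs: list[LongitudinalPair] | None = None,
            group: bool = False):
        """No-intercept random-slope mixed model on anchored predicted change.

        Uses, per subject, the pairs anchored at that subject's first
        timepoint; predicted change is regressed on time-from-first with a
        subject random slope (and an optional group fixed effect).
        """
        from . import stats

        pairs = self.model.test_pairs if pairs is None else pairs
        subjects = {p.subject_id for p in pairs}
        first_times = {
            s: min(min(p.first.time, p.second.time)
                   for p in pairs if p.subject_id == s) for s in subjects}
        rows = []
        for p in pairs:
            early, late = sorted([p.first, p.second], key=lambda r: r.time)
            if early.time != first_times[p.subject_id]:
                continue
            res = self.network.compare_arrays(
                late.load(), early.load(), late.metadata, early.metadata)
            row = {"subject": p.subject_id, "time": late.time - early.time,
                   "change": res.logit}
            if group:
                row["group"] = early.group
            rows.append(row)
        return stats.lme_fit(pd.DataFrame(rows), group=group)

    # -- localization ------------------------------------------------------
    def saliency(self, pair: LongitudinalPair, branch: str = "second",
                 upsample: str = "linear"):
        from .saliency import modified_gradcam

        return modified_gradcam(self.network, pair, branch=branch,
                                upsample=upsample)

    def peak_map(self, pairs: list[LongitudinalPair] | None = None,
                 tau_threshold: float = 0.7, branch: str = "second"):
        """Population-average peak-frequency map over max-interval test pairs."""
        from .saliency import modified_gradcam, population_peak_map

        pairs = max_interval_pairs(
            self.model.test_pairs if pairs is None else pairs)
        y_bar = self._train_target_mean()
        results = []
        for p in pairs:
            # change maps are read on the later image of the
            # chronologically presented pair (first-to-last scans)
            sal = modified_gradcam(self.network, p.chronological(),
                                   branch=branch, tau_baseline=y_bar)
            results.append(sal)
        return population_peak_map(results, tau_threshold=tau_threshold)

    def _train_target_mean(self) -> float:
        task = self.model.task
        vals = []
        for p in self.model.train_pairs:
            if task == "ordering":
                vals.append(p.order_label)
            elif task == "interval":
                vals.append(p.delta_time)
            else:
                vals.append(p.delta_target)
        return float(np.mean(vals))

    def summary(self) -> str:
        """Human-readable fit summary."""
        cfg = self.model.config
        rep = self.report
        lines = [
            "Pairwise temporal-change model",
            "=" * 46,
            f"task:               {self.model.task}",
            f"spatial dims:       {cfg.spatial_dims}D, {cfg.image_size}px",
            f"extractor:          4 conv blocks {cfg.block_channels}, "
            f"{cfg.pooling} pool",
            f"parameters:         {self.network.n_parameters():,}",
            f"train/val/test:     {len(self.model.train_pairs)}/"
            f"{len(self.model.val_pairs)}/{len(self.model.test_pairs)} pairs",
            f"epochs run:         {len(rep.train_losses)}",
            f"selected epoch:     {rep.selected_epoch} "
            f"(val loss {rep.val_losses[rep.selected_epoch]:.4f})",
            f"val metric:         {rep.metric_name} = "
            f"{rep.val_metrics[rep.selected_epoch]:.4f}",
        ]
        return "\n".join(lines)
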