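"""Gradient-based localization of the change driving a pairwise prediction.

The comparison head acts on the *flattened* final activation grid, so the
usual Grad-CAM channel-importance averaging is replaced by an element-wise
rule: the gradient of the comparison score r with respect to one branch's
final activation grid is multiplied element-wise with that grid, summed
over channels, and rectified.  The coarse map lives on the last pooled grid
(e.g. 8x8x8 for a 128-voxel cube) and is upsampled to input resolution for
overlays.

Because saliency is only as trustworthy as the prediction it explains, each
case carries an explainability score

    tau = 1 - (y - y_hat)^2 / (y - y_bar)^2,

a per-sample analogue of R^2 (an Efron-style pseudo-score for the binary
ordering task, with y_hat the predicted probability and y_bar the training
label mean).  Population-level peak maps average binarized peak indicators
over the cases with tau above a gate (default 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .data import LongitudinalPair
from .model import ComparisonNetwork

__all__ = [
    "SaliencyResult",
    "modified_gradcam",
    "explainability_score",
    "population_peak_map",
    "upsample_nearest",
]


@dataclass
class SaliencyResult:
    """Saliency for one branch of one pair."""

    coarse_map: np.ndarray  # last-grid spatial map, nonnegative
    upsampled_map: np.ndarray  # input-resolution map
    peak: tuple[int, ...]  # argmax on the coarse grid (ties: lowest index)
    logit: float
    tau: float | None = None
    branch: str = "second"

    @property
    def peak_input_coords(self) -> tuple[int, ...]:
        """Center of the peak's coarse cell in input-pixel coordinates."""
        factors = [u // c for u, c in
                   zip(self.upsampled_map.shape, self.coarse_map.shape)]
        return tuple(int((p + 0.5) * f) for p, f in zip(self.peak, factors))


def upsample_nearest(grid: np.ndarray, full_shape: tuple[int, ...]) -> np.ndarray:
    """Exact block upsampling (each coarse cell becomes a constant block)."""
    factors = [f // c for f, c in zip(full_shape, grid.shape)]
    if any(f * c != s for f, c, s in zip(factors, grid.shape, full_shape)):
        raise ValueError(
            f"full shape {full_shape} is not an integer multiple of {grid.shape}")
    return np.kron(grid, np.ones(tuple(factors), dtype=grid.dtype))


def modified_gradcam(net: ComparisonNetwork, pair: LongitudinalPair,
                     branch: str = "second", upsample: str = "linear",
                     tau_baseline: float | None = None) -> SaliencyResult:
    """Element-wise Grad-CAM for one branch of a comparison.

    The presigmoid score r is differentiated with respect to the chosen
    branch's final activation grid (the other branch held fixed); gradients
    and activations are multiplied element-wise, summed over channels, and
    ReLU-rectified.  ``upsample`` is ``"linear"`` (bi/trilinear) or
    ``"nearest"`` (exact block indicator, used for peak-counting maps).

    When ``tau_baseline`` (the training-set target mean) is given, the
    result carries the explainability score for this pair's prediction.

    ``branch`` may also be ``"later"`` or ``"earlier"``, resolved per pair
    from the timestamps; change maps are conventionally read on the later
    image, where the change has actually occurred.
    """
    if branch == "later":
        branch = "second" if pair.delta_time > 0 else "first"
    elif branch == "earlier":
        branch = "first" if pair.delta_time > 0 else "second"
    if branch not in ("first", "second"):
        raise ValueError("branch must be 'first', 'second', 'later' or 'earlier'")
    from .data import minmax_normalize

    res = net.compare_pair(pair)
    record = pair.first if branch == "first" else pair.second
    x = minmax_normalize(record.load())[None]
    net.features(x)
    acts = net.extractor.last_activation[0]  # (C, *spatial)
    # r = w_img . (flat(A_first) - flat(A_second)) + const in A, so the
    # gradient of r w.r.t. this branch's grid is +/- w_img reshaped.
    sign = 1.0 if branch == "first" else -1.0
    grad = sign * net.head_image_weights.reshape(net.extractor.coarse_shape)
    cam = np.maximum((grad * acts).sum(axis=0), 0.0).astype(np.float64)
    full_shape = record.load().shape
    if upsample == "nearest":
        up = upsample_nearest(cam, full_shape)
    elif upsample == "linear":
        factors = [f / c for f, c in zip(full_shape, cam.shape)]
        up = ndimage.zoom(cam, factors, order=1, grid_mode=True, mode="nearest")
    else:
        raise ValueError(f"unknown upsample mode {upsample!r}")
    peak = tuple(int(i) for i in np.unravel_index(np.argmax(cam), cam.shape))
    tau = None
    if tau_baseline is not None:
        if net.config.task == "ordering":
            tau = explainability_score(pair.order_label, expit(res.logit),
                                       tau_baseline)
        elif net.config.task == "interval":
            tau = explainability_score(pair.delta_time, res.logit, tau_baseline)
        else:
            tau = explainability_score(pair.delta_target, res.logit, tau_baseline)
    return SaliencyResult(cam, up, peak, res.logit, tau=tau, branch=branch)


def explainability_score(y: float, y_hat: float, y_bar_train: float) -> float:
    """Per-case prediction quality, tau = 1 - (y-yhat)^2/(y-ybar)^2.

    1 means a perfect prediction, 0 means no better than the training-mean
    baseline.  Undefined (NaN sentinel) when y equals the baseline mean;
    such cases are excluded from gated outputs.
    """
    denom = (y - y_bar_train) ** 2
    if denom == 0:
        return float("nan")
    return 1.0 - (y - y_hat) ** 2 / denom


def population_peak_map(results: list[SaliencyResult],
                        tau_threshold: float = 0.7) -> np.ndarray:
    """Average of binarized peak-indicator maps over well-explained cases.

    Each surviving case contributes a coarse-grid indicator that is 1 only
    at its saliency peak, block-upsampled to input resolution; cases with
    tau <= threshold (or undefined tau) are excluded.  The caller is
    responsible for using one pair per subject (largest time interval) so
    subjects are weighted equally.
    """
    kept = [r for r in results
            if r.tau is not None and np.isfinite(r.tau) and r.tau > tau_threshold]
    if not kept:
        raise ValueError(
            f"no saliency cases exceed the explainability threshold "
            f"{tau_threshold}")
    shape = kept[0].coarse_map.shape
    full = kept[0].upsampled_map.shape
    acc = np.zeros(full, dtype=np.float64)
    for r in kept:
        if r.coarse_map.shape != shape:
            raise ValueError("saliency results have mismatched grid shapes")
        ind = np.zeros(shape)
        ind[r.peak] = 1.0
        acc += upsample_nearest(ind, full)
    return acc / len(kept)
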