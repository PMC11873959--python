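"""Minimal differentiable network engine for the pairwise-comparison models.

Implements exactly the pieces the comparison network needs — same-padding
convolution (stride 1), batch normalization, leaky-ReLU, non-overlapping
average/max pooling, and the Adam optimizer — for both 2D images and 3D
volumes, in pure numpy.  Convolutions are evaluated as ``tensordot``
contractions over ``sliding_window_view`` windows so the heavy lifting is a
single BLAS call per layer.

Conventions: arrays are ``(N, C, *spatial)``; layers cache what their
backward pass needs, so ``forward`` (with ``train=True``) must precede
``backward`` on the same batch.  Inference (``train=False``) caches nothing
and uses batch-norm running statistics, making it deterministic per image.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv",
    "BatchNorm",
    "LeakyReLU",
    "Pool",
    "ConvBlock",
    "FeatureExtractor",
    "Adam",
]


class Layer:
    """Base class: parameterless layers inherit empty param/grad dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _spatial_axes(ndim: int) -> tuple[int, ...]:
    return tuple(range(2, 2 + ndim))


class Conv(Layer):
    """N-dimensional convolution, stride 1, zero 'same' padding, odd kernel.

    Weight shape ``(out_channels, in_channels, k, ..., k)``; He-initialized
    for the leaky-ReLU nonlinearity that follows it.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, ndim: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError(f"kernel size must be odd, got {kernel}")
        self.ndim = ndim
        self.kernel = kernel
        fan_in = in_ch * kernel ** ndim
        std = np.sqrt(2.0 / fan_in)
        self.params = {
            "W": rng.normal(0.0, std, (out_ch, in_ch) + (kernel,) * ndim).astype(dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        pad = [(0, 0), (0, 0)] + [(p, p)] * self.ndim
        return np.pad(x, pad)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        nd = self.ndim
        win = sliding_window_view(self._pad(x), (self.kernel,) * nd, axis=_spatial_axes(nd))
        # win: (N, Cin, *S, *k); contract Cin and kernel axes against W
        kernel_axes = list(range(2 + nd, 2 + 2 * nd))
        y = np.tensordot(win, self.params["W"],
                         axes=([1] + kernel_axes, [1] + list(range(2, 2 + nd))))
        y = np.moveaxis(y, -1, 1)
        y += self.params["b"].reshape((1, -1) + (1,) * nd)
        if train:
            self._cache = win
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = self.ndim
        win = self._cache
        sp = list(_spatial_axes(nd))
        self.grads["b"][...] = dy.sum(axis=(0, *sp))
        # dW[o,i,*k] = sum over batch+space of window * upstream
        self.grads["W"][...] = np.tensordot(dy, win, axes=([0] + sp, [0] + sp))
        # dx = same-correlation of dy with the kernel flipped on spatial axes
        wf = np.flip(self.params["W"], axis=tuple(range(2, 2 + nd)))
        dwin = sliding_window_view(self._pad(dy), (self.kernel,) * nd, axis=_spatial_axes(nd))
        kernel_axes = list(range(2 + nd, 2 + 2 * nd))
        dx = np.tensordot(dwin, wf, axes=([1] + kernel_axes, [0] + list(range(2, 2 + nd))))
        self._cache = None
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, ndim: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32) -> None:
        super().__init__()
        self.ndim = ndim
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def _bshape(self) -> tuple[int, ...]:
        return (1, -1) + (1,) * self.ndim

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, *_spatial_axes(self.ndim))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(self._bshape())) * ivar.reshape(self._bshape())
        y = self.params["gamma"].reshape(self._bshape()) * xhat \
            + self.params["beta"].reshape(self._bshape())
        if train:
            self._cache = (xhat, ivar)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        axes = (0, *_spatial_axes(self.ndim))
        m = float(np.prod([dy.shape[a] for a in axes]))
        self.grads["gamma"][...] = (dy * xhat).sum(axis=axes)
        self.grads["beta"][...] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"].reshape(self._bshape())
        s1 = dxhat.sum(axis=axes).reshape(self._bshape())
        s2 = (dxhat * xhat).sum(axis=axes).reshape(self._bshape())
        dx = (ivar.reshape(self._bshape()) / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx.astype(dy.dtype)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pos = x > 0
        if train:
            self._mask = pos
        return np.where(pos, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return dx


class Pool(Layer):
    """Non-overlapping average or max pooling with a square window."""

    def __init__(self, ndim: int, window: int = 2, mode: str = "avg") -> None:
        super().__init__()
        if mode not in ("avg", "max"):
            raise ValueError(f"pooling mode must be 'avg' or 'max', got {mode!r}")
        self.ndim = ndim
        self.window = window
        self.mode = mode
        self._cache = None

    def _split(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
        w = self.window
        shape = [x.shape[0], x.shape[1]]
        for s in x.shape[2:]:
            if s % w:
                raise ValueError(
                    f"spatial size {s} not divisible by pooling window {w}")
            shape += [s // w, w]
        xs = x.reshape(shape)
        win_axes = tuple(range(3, 3 + 2 * self.ndim, 2))
        return xs, win_axes

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xs, win_axes = self._split(x)
        if self.mode == "avg":
            y = xs.mean(axis=win_axes)
            if train:
                self._cache = x.shape
        else:
            y = xs.max(axis=win_axes)
            if train:
                self._cache = (x, y)
        return y

    def _upsample(self, y: np.ndarray) -> np.ndarray:
        out = y
        for ax in range(2, 2 + self.ndim):
            out = np.repeat(out, self.window, axis=ax)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.mode == "avg":
            dx = self._upsample(dy) / self.window ** self.ndim
        else:
            x, y = self._cache
            mask = (x == self._upsample(y))
            # split ties evenly so gradient mass is conserved
            ms, win_axes = self._split(mask.astype(dy.dtype))
            counts = self._upsample(ms.sum(axis=win_axes))
            dx = mask * self._upsample(dy) / counts
        self._cache = None
        return dx


class ConvBlock:
    """conv -> batch norm -> leaky ReLU -> pool, the extractor's repeating unit."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, ndim: int,
                 pool: str, pool_window: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.layers = [
            Conv(in_ch, out_ch, kernel, ndim, rng, dtype=dtype),
            BatchNorm(out_ch, ndim, dtype=dtype),
            LeakyReLU(),
            Pool(ndim, pool_window, pool),
        ]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class FeatureExtractor:
    """Four-block convolutional feature extractor shared across both branches.

    Maps an ``(N, 1, *spatial)`` batch to a flattened feature matrix
    ``(N, feature_dim)`` while keeping the final pooled activation grid
    (the flatten input) available for gradient-based localization.
    """

    N_BLOCKS = 4

    def __init__(self, ndim: int, input_size: int,
                 channels: tuple[int, ...] = (8, 16, 32, 32), kernel: int = 3,
                 pool: str = "avg", pool_window: int = 2,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        if len(channels) != self.N_BLOCKS:
            raise ValueError(f"expected {self.N_BLOCKS} channel counts, got {len(channels)}")
        total_pool = pool_window ** self.N_BLOCKS
        if input_size % total_pool:
            raise ValueError(
                f"input size {input_size} is not divisible by the total pooling "
                f"factor {total_pool}")
        rng = rng or np.random.default_rng()
        self.ndim = ndim
        self.input_size = input_size
        self.channels = tuple(channels)
        self.dtype = dtype
        self.blocks = []
        in_ch = 1
        for out_ch in channels:
            self.blocks.append(
                ConvBlock(in_ch, out_ch, kernel, ndim, pool, pool_window, rng, dtype))
            in_ch = out_ch
        side = input_size // total_pool
        self.coarse_shape = (channels[-1],) + (side,) * ndim
        self.feature_dim = int(np.prod(self.coarse_shape))
        self._last_act: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2 + self.ndim - 1:  # no channel axis supplied
            x = x[:, None]
        for block in self.blocks:
            x = block.forward(x, train=train)
        self._last_act = x
        return x.reshape(x.shape[0], -1)

    @property
    def last_activation(self) -> np.ndarray:
        """Final pooled activation grid from the most recent forward pass."""
        if self._last_act is None:
            raise RuntimeError("no forward pass has been run yet")
        return self._last_act

    def backward(self, dfeat: np.ndarray) -> np.ndarray:
        dy = dfeat.reshape((-1,) + self.coarse_shape).astype(self.dtype)
        for block in reversed(self.blocks):
            dy = block.backward(dy)
        return dy

    # -- parameter plumbing -------------------------------------------------
    def named_params(self):
        for bi, block in enumerate(self.blocks):
            for li, layer in enumerate(block.layers):
                for name, value in layer.params.items():
                    yield f"block{bi}.{li}.{name}", layer, name, value

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {key: value.copy() for key, _, _, value in self.named_params()}
        for bi, block in enumerate(self.blocks):
            bn = block.layers[1]
            state[f"block{bi}.running_mean"] = bn.running_mean.copy()
            state[f"block{bi}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name, value in self.named_params():
            layer.params[name] = np.asarray(state[key], dtype=value.dtype).reshape(value.shape)
            layer.grads[name] = np.zeros_like(layer.params[name])
        for bi, block in enumerate(self.blocks):
            bn = block.layers[1]
            bn.running_mean = np.asarray(state[f"block{bi}.running_mean"], dtype=self.dtype)
            bn.running_var = np.asarray(state[f"block{bi}.running_var"], dtype=self.dtype)

    def n_parameters(self) -> int:
        return sum(v.size for _, _, _, v in self.named_params())


class Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[tuple[dict, str]], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        # params: list of (container, key) where container[key] is the array
        # and the matching gradient lives in a parallel dict; we store
        # callables to fetch both so layers stay the single source of truth.
        self.entries = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(self._get(e)) for e in params]
        self.v = [np.zeros_like(self._get(e)) for e in params]

    @staticmethod
    def _get(entry):
        layer, name = entry
        return layer.params[name] if hasattr(layer, "params") else layer[name]

    @staticmethod
    def _get_grad(entry):
        layer, name = entry
        return layer.grads[name] if hasattr(layer, "grads") else layer["grads"][name]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, entry in enumerate(self.entries):
            p = self._get(entry)
            g = self._get_grad(entry)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def coarse_grid_shape(input_size: int, ndim: int, pool_window: int = 2,
                      n_blocks: int = 4) -> tuple[int, ...]:
    """Spatial shape of the final activation grid for a given input size.

    E.g. a 128-voxel cube pooled /2 four times lands on an 8x8x8 grid.
    """
    total = pool_window ** n_blocks
    if input_size % total:
        raise ValueError(f"input size {input_size} not divisible by {total}")
    return (input_size // total,) * ndim
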