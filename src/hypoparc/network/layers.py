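"""Minimal numpy building blocks for the 2D F-CNN, with hand-written backprop.

Arrays follow the (N, C, H, W) convention in float64.  Every layer caches
what its backward pass needs on the instance (one forward in flight at a
time, which matches the training loop).
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from ..lut_io import ParameterError, ShapeError


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = False, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # whether weight decay applies (conv kernels only)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d:
    """3x3 (or 1x1) same-padding convolution via im2col + BLAS matmul."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator, name: str = ""):
        if ksize not in (1, 3):
            raise ParameterError("only 1x1 and 3x3 kernels are supported")
        self.cin, self.cout, self.k = cin, cout, ksize
        fan_in = cin * ksize * ksize
        self.weight = Param(
            _he_init(rng, (cin * ksize * ksize, cout), fan_in), decay=True, name=f"{name}.weight"
        )
        self.bias = Param(np.zeros(cout), name=f"{name}.bias")
        self._cols: Optional[np.ndarray] = None
        self._xshape: Optional[Tuple[int, ...]] = None

    def params(self) -> List[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ShapeError(f"conv expected {self.cin} channels, got {c}")
        if self.k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        out = cols @ self.weight.value + self.bias.value
        self._cols, self._xshape = cols, x.shape
        return np.ascontiguousarray(out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.weight.grad += self._cols.T @ dmat
        self.bias.grad += dmat.sum(axis=0)
        dcols = dmat @ self.weight.value.T
        if self.k == 1:
            dx = dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        else:
            dcols = dcols.reshape(n, h, w, c, 3, 3).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros((n, c, h + 2, w + 2))
            for i in range(3):
                for j in range(3):
                    dxp[:, :, i : i + h, j : j + w] += dcols[..., i, j]
            dx = dxp[:, :, 1 : 1 + h, 1 : 1 + w]
        self._cols = None
        return np.ascontiguousarray(dx)


class BatchNorm2d:
    """Per-channel batch normalization with affine terms and running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, name: str = ""):
        self.channels = channels
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[:, None, None] * inv_std[:, None, None]
        if not train:
            return dout * g
        m = shape[0] * shape[2] * shape[3]
        dxhat = dout * self.gamma.value[:, None, None]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        self._cache = None
        return term * inv_std[:, None, None]


class PReLU:
    """Parametric ReLU with a single learnable slope."""

    def __init__(self, init: float = 0.25, name: str = ""):
        self.slope = Param(np.array(init), name=f"{name}.slope")
        self._x = None

    def params(self) -> List[Param]:
        return [self.slope]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.where(x > 0, x, self.slope.value * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        neg = x <= 0
        self.slope.grad += float((dout * x * neg).sum())
        self._x = None
        return dout * np.where(neg, self.slope.value, 1.0)


def maxout(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Elementwise competitive (max) fusion; returns (out, mask) with ties to ``a``."""
    mask = a >= b
    return np.where(mask, a, b), mask


def maxout_backward(dout: np.ndarray, mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    return dout * mask, dout * ~mask


def maxpool2x2(x: np.ndarray):
    """2x2 max-pool (stride 2, floor on odd sizes) returning argmax indices."""
    n, c, h, w = x.shape
    ho, wo = h // 2, w // 2
    xc = x[:, :, : 2 * ho, : 2 * wo].reshape(n, c, ho, 2, wo, 2)
    flat = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    cache = (idx, (h, w))
    return out, cache


def _pool_positions(idx: np.ndarray, shape: Tuple[int, int]):
    n, c, ho, wo = idx.shape
    di, dj = idx // 2, idx % 2
    ii = (np.arange(ho) * 2)[None, None, :, None] + di
    jj = (np.arange(wo) * 2)[None, None, None, :] + dj
    nn = np.arange(n)[:, None, None, None]
    cc = np.arange(c)[None, :, None, None]
    return nn, cc, ii, jj


def maxpool_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx, (h, w) = cache
    n, c = dout.shape[:2]
    dx = np.zeros((n, c, h, w))
    nn, cc, ii, jj = _pool_positions(idx, (h, w))
    np.add.at(dx, (nn, cc, ii, jj), dout)
    return dx


def maxunpool2x2(y: np.ndarray, cache) -> np.ndarray:
    """Place pooled values back at their argmax positions (index-preserving)."""
    idx, (h, w) = cache
    n, c = y.shape[:2]
    out = np.zeros((n, c, h, w))
    nn, cc, ii, jj = _pool_positions(idx, (h, w))
    out[nn, cc, ii, jj] = y
    return out


def maxunpool_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx, _ = cache
    nn, cc, ii, jj = _pool_positions(idx, dout.shape[:2] + idx.shape[2:])
    return dout[nn, cc, ii, jj]


# ---------------------------------------------------------------------------
# Bilinear resize as an explicit (separable) linear operator
# ---------------------------------------------------------------------------

def _linear_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) bilinear interpolation matrix, half-pixel centers."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i0 = np.minimum(i0, n_in - 2)
    frac = src - i0
    m[np.arange(n_out), i0] += 1.0 - frac
    m[np.arange(n_out), i0 + 1] += frac
    return m


def bilinear_resize(x: np.ndarray, out_hw: Tuple[int, int]):
    """Resize (..., H, W) -> (..., H', W'); returns (y, cache) for backward."""
    h, w = x.shape[-2:]
    oh, ow = out_hw
    rh = _linear_resize_matrix(h, oh)
    rw = _linear_resize_matrix(w, ow)
    y = np.einsum("ph,...hw,qw->...pq", rh, x, rw, optimize=True)
    return y, (rh, rw)


def bilinear_resize_backward(dout: np.ndarray, cache) -> np.ndarray:
    rh, rw = cache
    return np.einsum("ph,...pq,qw->...hw", rh, dout, rw, optimize=True)
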