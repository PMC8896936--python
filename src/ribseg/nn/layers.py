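"""Minimal N-dimensional neural-network layers with explicit backprop.

Everything operates on float32 arrays of shape ``(N, C, *spatial)`` where
spatial is 2-D or 3-D.  Convolutions are "same" convolutions with odd
kernels, realised as an im2col matrix product; the data gradient is the
convolution of the output gradient with the flipped, channel-transposed
kernel, so no dedicated transposed-convolution code is needed.  Layers
cache what their backward pass needs on ``forward`` and release it on
``backward``; the im2col matrix itself is recomputed in backward rather
than cached, trading a little compute for a large memory saving.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray, kernel: tuple[int, ...], pad: int) -> np.ndarray:
    """(N, C, *S) -> (C * prod(kernel), N * prod(S)) patch matrix.

    Row index is c * prod(kernel) + offset, matching
    ``w.reshape(c_out, -1)``.  Built by one shifted-slice copy per kernel
    offset: each copy runs along contiguous memory, which is far cheaper
    than gathering the full patch neighbourhood per voxel.
    """
    ndim = len(kernel)
    if pad:
        width = [(0, 0), (0, 0)] + [(pad, pad)] * ndim
        x = np.pad(x, width)
    n, c = x.shape[:2]
    spatial = tuple(s - k + 1 for s, k in zip(x.shape[2:], kernel))
    vol = math.prod(spatial)
    n_off = math.prod(kernel)
    cols = np.empty((c, n_off, n, vol), dtype=x.dtype)
    for j, offset in enumerate(itertools.product(*[range(k) for k in kernel])):
        window = tuple(slice(o, o + s) for o, s in zip(offset, spatial))
        sl = x[(slice(None), slice(None)) + window]
        cols[:, j] = sl.swapaxes(0, 1).reshape(c, n, vol)
    return cols.reshape(c * n_off, n * vol)


def _conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
               cols: np.ndarray | None = None) -> np.ndarray:
    """Same-padding convolution of (N, C_in, *S) with (C_out, C_in, *k)."""
    kernel = w.shape[2:]
    if cols is None:
        cols = _im2col(x, kernel, kernel[0] // 2)
    y = w.reshape(w.shape[0], -1) @ cols
    if b is not None:
        y += b[:, None]
    y = y.reshape((w.shape[0], x.shape[0]) + x.shape[2:])
    return np.ascontiguousarray(y.swapaxes(0, 1))


class Conv(Layer):
    """Same convolution with odd kernel (3 or 1), stride 1, He-initialised."""

    def __init__(self, ndim: int, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True):
        if kernel % 2 != 1:
            raise ValueError("only odd kernels are supported")
        shape = (c_out, c_in) + (kernel,) * ndim
        fan_in = c_in * kernel**ndim
        self.weight = Parameter(rng.standard_normal(shape).astype(np.float32)
                                * np.sqrt(2.0 / fan_in))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None
        self.ndim = ndim
        self._x: np.ndarray | None = None
        self._cols: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.weight.value
        kernel = w.shape[2:]
        self._x = x
        self._cols = _im2col(x, kernel, kernel[0] // 2)
        return _conv_same(x, w, None if self.bias is None else self.bias.value,
                          cols=self._cols)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self._x = None
        w = self.weight.value
        cols, self._cols = self._cols, None
        dy_mat = np.ascontiguousarray(dy.swapaxes(0, 1)).reshape(w.shape[0], -1)
        self.weight.grad += (dy_mat @ cols.T).reshape(w.shape)
        if self.bias is not None:
            self.bias.grad += dy_mat.sum(axis=1)
        # data gradient: convolve dy with flipped kernel, in/out channels swapped
        w_flip = np.flip(w, axis=tuple(range(2, w.ndim))).swapaxes(0, 1)
        return _conv_same(dy, np.ascontiguousarray(w_flip), None)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over spatial dims, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(2, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        g = self.gamma.value.reshape(self._shape(x))
        b = self.beta.value.reshape(self._shape(x))
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        axes = tuple(range(2, dy.ndim))
        red = (0,) + axes
        self.gamma.grad += (dy * xhat).sum(axis=red)
        self.beta.grad += dy.sum(axis=red)
        g = self.gamma.value.reshape(self._shape(dy))
        dxhat = dy * g
        m = math.prod(dy.shape[2:])
        term = (dxhat
                - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        return inv * term


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        self.slope = negative_slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, dy, self.slope * dy)


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        # clamp logits: beyond +-60 the float output saturates anyway
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y, self._y = self._y, None
        return dy * y * (1.0 - y)


def _to_blocks(x: np.ndarray, factors: tuple[int, ...]) -> np.ndarray:
    """(N, C, *S) -> (N, C, *S_out, prod(factors)) block view (copy)."""
    n_sp = len(factors)
    shape = list(x.shape[:2])
    for s, f in zip(x.shape[2:], factors):
        if s % f:
            raise ValueError(f"spatial size {s} not divisible by pool factor {f}")
        shape += [s // f, f]
    y = x.reshape(shape)
    src = [2 + 2 * i + 1 for i in range(n_sp)]
    dst = [2 + n_sp + i for i in range(n_sp)]
    y = np.moveaxis(y, src, dst)
    out_spatial = tuple(s // f for s, f in zip(x.shape[2:], factors))
    return np.ascontiguousarray(y).reshape(x.shape[:2] + out_spatial + (-1,))


def _from_blocks(blocks: np.ndarray, factors: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`_to_blocks`."""
    n_sp = len(factors)
    out_spatial = blocks.shape[2:2 + n_sp]
    y = blocks.reshape(blocks.shape[:2] + out_spatial + tuple(factors))
    src = [2 + n_sp + i for i in range(n_sp)]
    dst = [2 + 2 * i + 1 for i in range(n_sp)]
    y = np.moveaxis(y, src, dst)
    full = tuple(s * f for s, f in zip(out_spatial, factors))
    return np.ascontiguousarray(y).reshape(blocks.shape[:2] + full)


class MaxPool(Layer):
    """Per-axis pooling by integer factors (1 = no pooling on that axis)."""

    def __init__(self, factors: tuple[int, ...]):
        self.factors = tuple(int(f) for f in factors)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        blocks = _to_blocks(x, self.factors)
        idx = blocks.argmax(axis=-1)
        y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, blocks.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, bshape = self._cache
        self._cache = None
        dblocks = np.zeros(bshape, dtype=dy.dtype)
        np.put_along_axis(dblocks, idx[..., None], dy[..., None], axis=-1)
        return _from_blocks(dblocks, self.factors)


class AvgPool(Layer):
    def __init__(self, factors: tuple[int, ...]):
        self.factors = tuple(int(f) for f in factors)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return _to_blocks(x, self.factors).mean(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m = math.prod(self.factors)
        blocks = np.repeat((dy / m)[..., None], m, axis=-1)
        return _from_blocks(blocks, self.factors)


class Upsample(Layer):
    """Nearest-neighbour upsampling by per-axis integer factors."""

    def __init__(self, factors: tuple[int, ...]):
        self.factors = tuple(int(f) for f in factors)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x
        for ax, f in enumerate(self.factors):
            if f > 1:
                y = np.repeat(y, f, axis=2 + ax)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return _to_blocks(dy, self.factors).sum(axis=-1)


class GlobalAvgPool(Layer):
    """(N, C, *S) -> (N, C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape = self._shape
        self._shape = None
        m = math.prod(shape[2:])
        return np.broadcast_to(
            dy.reshape(dy.shape + (1,) * (len(shape) - 2)), shape
        ).astype(dy.dtype) / m


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Parameter(rng.standard_normal((n_out, n_in)).astype(np.float32)
                                * np.sqrt(2.0 / n_in))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32))
        self._x = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def conv_block(ndim: int, c_in: int, c_out: int, rng: np.random.Generator,
               negative_slope: float = 0.01) -> Sequential:
    """The standard encoder/decoder unit: (conv3 - instance norm - leaky
    ReLU) twice."""
    return Sequential(
        Conv(ndim, c_in, c_out, 3, rng),
        InstanceNorm(c_out),
        LeakyReLU(negative_slope),
        Conv(ndim, c_out, c_out, 3, rng),
        InstanceNorm(c_out),
        LeakyReLU(negative_slope),
    )
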