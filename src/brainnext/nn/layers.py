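"""Layers with explicit forward/backward, symbolic shape trace and parameter
accounting.

Tensor layout is NCHW.  ``forward(x, train=...)`` caches whatever the matching
``backward(dy)`` needs; backward returns the gradient with respect to the
layer input and accumulates parameter gradients on the ``Param`` objects.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable array with its gradient buffer."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return int(self.data.size)


class Layer:
    """Base layer: no parameters, identity shape."""

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        """Non-trainable state (e.g. BN running statistics)."""
        return []

    def param_count(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, shape: tuple[int, int, int]) -> tuple[int, int, int]:
        """Symbolic (C, H, W) -> (C, H, W) shape map."""
        return shape

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _conv_out(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


class Conv2d(Layer):
    """2-D convolution via im2col.

    Supports ordinary (groups=1) and depthwise (groups == in_ch == out_ch)
    convolutions, which are the only two group settings the architecture
    uses; other group counts fall back to a per-group loop.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        if in_ch % groups or out_ch % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad, self.groups = kernel, stride, pad, groups
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch // groups * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch // groups, kernel, kernel))
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(out_ch)) if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def out_shape(self, shape):
        c, h, w = shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        return (self.out_ch,
                _conv_out(h, self.k, self.stride, self.pad),
                _conv_out(w, self.k, self.stride, self.pad))

    def _cols(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        return cols[:, :, ::self.stride, ::self.stride]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        cols = self._cols(x)
        wt = self.w.data
        if self.groups == 1:
            y = np.einsum("nchwij,ocij->nohw", cols, wt, optimize=True)
        elif self.groups == self.in_ch == self.out_ch:
            y = np.einsum("nchwij,cij->nchw", cols, wt[:, 0], optimize=True)
        else:
            cg, og = self.in_ch // self.groups, self.out_ch // self.groups
            parts = [np.einsum("nchwij,ocij->nohw",
                               cols[:, g * cg:(g + 1) * cg],
                               wt[g * og:(g + 1) * og], optimize=True)
                     for g in range(self.groups)]
            y = np.concatenate(parts, axis=1)
        if self.b is not None:
            y = y + self.b.data[None, :, None, None]
        if train:
            self._cache = (x, cols)
        else:
            self._cache = None
        return np.ascontiguousarray(y, dtype=DTYPE)

    def backward(self, dy):
        x, cols = self._cache
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        wt = self.w.data
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        if self.groups == 1:
            self.w.grad += np.einsum("nchwij,nohw->ocij", cols, dy, optimize=True)
            dcols = np.einsum("nohw,ocij->nchwij", dy, wt, optimize=True)
        elif self.groups == self.in_ch == self.out_ch:
            self.w.grad += np.einsum("nchwij,nchw->cij", cols, dy,
                                     optimize=True)[:, None]
            dcols = dy[:, :, :, :, None, None] * wt[:, 0][None, :, None, None]
        else:
            cg, og = self.in_ch // self.groups, self.out_ch // self.groups
            dcols = np.empty_like(cols)
            for g in range(self.groups):
                cs, os_ = slice(g * cg, (g + 1) * cg), slice(g * og, (g + 1) * og)
                self.w.grad[os_] += np.einsum("nchwij,nohw->ocij",
                                              cols[:, cs], dy[:, os_], optimize=True)
                dcols[:, cs] = np.einsum("nohw,ocij->nchwij",
                                         dy[:, os_], wt[os_], optimize=True)
        n, _, h, w = x.shape
        p, s = self.pad, self.stride
        ho, wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running statistics.

    Train mode normalises with batch moments and updates the running
    estimates; eval mode uses the running estimates, making inference
    deterministic for a frozen network.
    """

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Param(f"{name}.gamma", np.ones(ch))
        self.beta = Param(f"{name}.beta", np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [("running_mean", self.running_mean),
                ("running_var", self.running_var)]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean[:] = (1 - m) * self.running_mean + m * mean
            self.running_var[:] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return y.astype(DTYPE, copy=False)

    def backward(self, dy):
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not train:
            return (dy * g * inv[None, :, None, None]).astype(DTYPE, copy=False)
        n = shape[0] * shape[2] * shape[3]
        dxhat = dy * g
        dx = (dxhat
              - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return (dx * inv[None, :, None, None]).astype(DTYPE, copy=False)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x).astype(DTYPE, copy=False)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy).astype(DTYPE, copy=False)


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def out_shape(self, shape):
        c, h, w = shape
        return (c,
                _conv_out(h, self.k, self.stride, self.pad),
                _conv_out(w, self.k, self.stride, self.pad))

    def forward(self, x, train=False):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]
        flat = win.reshape(win.shape[:4] + (self.k * self.k,))
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return np.ascontiguousarray(y, dtype=DTYPE)

    def backward(self, dy):
        idx, shape = self._cache
        n, c, h, w = shape
        p, s = self.pad, self.stride
        ho, wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        ki, kj = idx // self.k, idx % self.k
        oi, oj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = oi[None, None] * s + ki
        cols_ = oj[None, None] * s + kj
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, rows, cols_), dy)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class GlobalAvgPool(Layer):
    """H×W×C map -> length-C vector of per-channel spatial means."""

    def __init__(self):
        self._shape = None

    def out_shape(self, shape):
        return (shape[0], 1, 1)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(DTYPE, copy=False)

    def backward(self, dy):
        n, c, h, w = self._shape
        return (np.broadcast_to(dy[:, :, None, None], (n, c, h, w))
                / (h * w)).astype(DTYPE, copy=False)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int,
                 rng: np.random.Generator | None = None, name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        self.in_f, self.out_f = in_f, out_f
        w = rng.normal(0.0, np.sqrt(2.0 / in_f), size=(out_f, in_f))
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(out_f))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return (x @ self.w.data.T + self.b.data).astype(DTYPE, copy=False)

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return (dy @ self.w.data).astype(DTYPE, copy=False)


class Sequential(Layer):
    def __init__(self, layers: list[Layer], name: str = ""):
        self.layers = list(layers)
        self.name = name

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        out = []
        for i, l in enumerate(self.layers):
            out += [(f"{i}.{n}", b) for n, b in l.buffers()]
        return out

    def out_shape(self, shape):
        for l in self.layers:
            shape = l.out_shape(shape)
        return shape

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class SplitBlock(Layer):
    """Half-width inverted-bottleneck block.

    The input of width C is split into channel halves; the first half passes
    through untouched, the second goes through the bottleneck branch
    (depthwise 7x7 -> BN -> 1x1 expand -> leaky ReLU -> 1x1 project -> BN)
    and the halves are depth-concatenated, conserving channel count.
    """

    def __init__(self, branch: Sequential, half: int):
        self.branch = branch
        self.half = half

    def params(self):
        return self.branch.params()

    def buffers(self):
        return self.branch.buffers()

    def out_shape(self, shape):
        c, h, w = shape
        bc, bh, bw = self.branch.out_shape((self.half, h, w))
        return (c - self.half + bc, bh, bw)

    def forward(self, x, train=False):
        x1, x2 = x[:, :self.half], x[:, self.half:]
        return np.concatenate([x1, self.branch.forward(x2, train=train)], axis=1)

    def backward(self, dy):
        dx1 = dy[:, :self.half]
        dx2 = self.branch.backward(dy[:, self.half:])
        return np.concatenate([dx1, dx2], axis=1)


class Residual(Layer):
    """Full-width block with additive skip: y = x + branch(x)."""

    def __init__(self, branch: Sequential):
        self.branch = branch

    def params(self):
        return self.branch.params()

    def buffers(self):
        return self.branch.buffers()

    def out_shape(self, shape):
        return self.branch.out_shape(shape)

    def forward(self, x, train=False):
        return x + self.branch.forward(x, train=train)

    def backward(self, dy):
        return dy + self.branch.backward(dy)


class CompressionUnit(Layer):
    """Stage-transition downsampler: 3x3/2 max pool depth-concatenated with a
    parallel 1x1 stride-2 convolution branch, doubling the channel count
    while halving the spatial size."""

    def __init__(self, ch: int, rng: np.random.Generator, name: str = "comp"):
        self.ch = ch
        self.pool = MaxPool2d(3, 2, 1)
        self.conv = Sequential([
            Conv2d(ch, ch, 1, stride=2, pad=0, rng=rng, name=f"{name}.conv"),
            BatchNorm2d(ch, name=f"{name}.bn"),
        ])

    def params(self):
        return self.conv.params()

    def buffers(self):
        return self.conv.buffers()

    def out_shape(self, shape):
        c, h, w = shape
        pc, ph, pw = self.pool.out_shape(shape)
        cc, chh, cw = self.conv.out_shape(shape)
        if (ph, pw) != (chh, cw):
            raise ValueError("compression branch size mismatch")
        return (pc + cc, ph, pw)

    def forward(self, x, train=False):
        return np.concatenate([self.pool.forward(x, train=train),
                               self.conv.forward(x, train=train)], axis=1)

    def backward(self, dy):
        d1 = self.pool.backward(dy[:, :self.ch])
        d2 = self.conv.backward(dy[:, self.ch:])
        return d1 + d2


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)
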