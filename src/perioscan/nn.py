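"""Minimal CNN engine: im2col convolutions with manual backprop, in numpy.

Just enough machinery for the two tiny networks in this package (an
encoder-decoder segmenter and a single-stage detector): 2-D convolution,
leaky-ReLU, 2x max-pooling, stride-1 "same" max-pooling (for spatial pyramid
pooling), nearest-neighbour 2x upsampling, and an Adam optimizer.  Tensors
are float32 ``(N, C, H, W)`` arrays; layers cache what backward needs, so one
``forward(train=True)`` must precede each ``backward``.

All parameter initialisation is driven by an explicit ``numpy`` Generator,
which makes model construction bit-reproducible from a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30.0, 30.0)))


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, weights: np.ndarray | float = 1.0
) -> tuple[float, np.ndarray]:
    """Elementwise binary cross-entropy on logits; returns (sum loss, grad)."""
    z = np.clip(logits, -30.0, 30.0)
    p = sigmoid(z)
    loss = np.sum(weights * (np.logaddexp(0.0, z) - targets * z))
    grad = weights * (p - targets)
    return float(loss), grad.astype(np.float32)


class Conv2d:
    """3x3/1x1 convolution via im2col; ``stride`` 1 or 2, "same" padding."""

    def __init__(
        self,
        rng: np.random.Generator,
        in_ch: int,
        out_ch: int,
        k: int = 3,
        stride: int = 1,
    ) -> None:
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = k // 2
        scale = np.sqrt(2.0 / (in_ch * k * k))  # He init for leaky-relu stacks
        self.W = Param(rng.normal(0.0, scale, size=(out_ch, in_ch * k * k)))
        self.b = Param(np.zeros(out_ch))
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        # col layout (C, k, k, N, oh, ow): kernel-position slices are cheap
        # block copies, and W @ col.reshape(C*k*k, -1) needs no further gather
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xpt = xp.transpose(1, 0, 2, 3)
        col = np.empty((c, k, k, n, oh, ow), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                col[:, i, j] = xpt[:, :, i : i + s * oh : s, j : j + s * ow : s]
        out = self.W.value @ col.reshape(c * k * k, n * oh * ow)
        out += self.b.value[:, None]
        if train:
            self._cache = (col, x.shape, oh, ow)
        return out.reshape(self.out_ch, n, oh, ow).transpose(1, 0, 2, 3)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        col, x_shape, oh, ow = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        g = np.ascontiguousarray(grad_out.transpose(1, 0, 2, 3)).reshape(
            self.out_ch, n * oh * ow
        )
        colm = col.reshape(c * k * k, n * oh * ow)
        self.W.grad += g @ colm.T
        self.b.grad += g.sum(axis=1)
        gcol = (self.W.value.T @ g).reshape(c, k, k, n, oh, ow)
        gxp = np.zeros((c, n, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += gcol[:, i, j]
        gx = gxp[:, :, p : p + h, p : p + w] if p else gxp
        return np.ascontiguousarray(gx.transpose(1, 0, 2, 3))


class LeakyReLU:
    def __init__(self, slope: float = 0.1) -> None:
        self.slope = slope
        self._mask: np.ndarray | None = None

    params: list[Param] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, self.slope * grad_out)


class MaxPool2:
    """2x2 max pooling, stride 2; input height/width must be even."""

    params: list[Param] = []

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gflat, idx[..., None], grad_out[..., None], axis=-1)
        return (
            gflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class MaxPoolSame:
    """k x k max pooling with stride 1 and same-size output (SPP branch)."""

    def __init__(self, k: int) -> None:
        self.k = k
        self._cache: tuple | None = None

    params: list[Param] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        out = win.max(axis=(4, 5)).astype(np.float32)
        if train:
            self._cache = (xp, out, x.shape)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xp, out, (n, c, h, w) = self._cache
        p = self.k // 2
        gxp = np.zeros_like(xp, dtype=np.float32)
        unclaimed = np.ones(out.shape, dtype=bool)  # route ties to first match
        for i in range(self.k):
            for j in range(self.k):
                region = xp[:, :, i : i + h, j : j + w]
                hit = (region == out) & unclaimed
                gxp[:, :, i : i + h, j : j + w] += np.where(hit, grad_out, 0.0)
                unclaimed &= ~hit
        return gxp[:, :, p : p + h, p : p + w]


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    params: list[Param] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = grad_out.shape
        return (
            grad_out.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(np.float32)
        )


class Sequential:
    def __init__(self, *layers) -> None:
        self.layers = list(layers)

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


def conv_block(rng: np.random.Generator, in_ch: int, out_ch: int, k: int = 3,
               stride: int = 1) -> Sequential:
    return Sequential(Conv2d(rng, in_ch, out_ch, k=k, stride=stride), LeakyReLU())


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        grad_clip: float = 10.0,
    ) -> None:
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            g = np.clip(p.grad, -self.grad_clip, self.grad_clip)
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def parameter_count(params: list[Param]) -> int:
    return int(sum(p.value.size for p in params))
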