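"""Compact CPU convolutional-network engine.

Implements exactly the layer vocabulary the seed classifier needs — 2-D
convolution, depthwise and separable convolution, batch normalisation,
ReLU, average / global-average pooling, dense layers, the efficient
channel-attention (ECA) gate — each with an explicit, hand-derived
backward pass, plus Adam and SGD optimisers and a softmax cross-entropy
loss.  Arrays are ``float32`` in NCHW layout.

Convolutions use "same" zero padding (``pad = k // 2``); with stride ``s``
the output size is ``floor((H + 2*pad - k) / s) + 1``.  Forward passes are
im2col + BLAS matmul, backward passes scatter window gradients back with a
small loop over the ``k*k`` kernel offsets, so everything stays vectorised
over batch and space.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    """A learnable (or tracked) tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base class: stateless unless it owns Params; single-input graph node."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = math.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def _kernel_pair(kernel: int | tuple[int, int]) -> tuple[int, int]:
    if isinstance(kernel, int):
        return kernel, kernel
    kh, kw = kernel
    return int(kh), int(kw)


def _strided_windows(xpad: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """View of shape (N, C, Ho, Wo, kh, kw) over a padded NCHW array."""
    win = sliding_window_view(xpad, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


class Conv2d(Layer):
    """Standard 2-D convolution, same padding; kernel may be (kh, kw)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int | tuple[int, int] = 3,
        stride: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.kh, self.kw = _kernel_pair(kernel)
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        fan_in = self.kh * self.kw * c_in
        self.weight = Param(he_uniform(rng, (c_out, c_in, self.kh, self.kw), fan_in))
        self.bias = Param(np.zeros(c_out)) if bias else None
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        kh, kw, s = self.kh, self.kw, self.stride
        ph, pw = kh // 2, kw // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = _strided_windows(xpad, kh, kw, s)  # N,C,Ho,Wo,kh,kw
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * kh * kw
        )
        wmat = self.weight.value.reshape(self.c_out, c * kh * kw)
        y = cols @ wmat.T
        if self.bias is not None:
            y += self.bias.value
        y = y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        if training:
            self._cols, self._xshape = cols, x.shape
        else:
            self._cols = None
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cols is not None, "backward requires forward(training=True)"
        n, c, h, w = self._xshape
        kh, kw, s = self.kh, self.kw, self.stride
        ph, pw = kh // 2, kw // 2
        _, _, ho, wo = dy.shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.weight.grad += (dyf.T @ self._cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.weight.value.reshape(self.c_out, -1)).reshape(
            n, ho, wo, c, kh, kw
        )
        dxpad = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=F32)
        for i in range(kh):
            for j in range(kw):
                dxpad[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxpad[:, :, ph : ph + h, pw : pw + w]


class DepthwiseConv2d(Layer):
    """Per-channel spatial convolution: one kh x kw x 1 kernel per channel."""

    def __init__(
        self,
        channels: int,
        kernel: int | tuple[int, int] = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.kh, self.kw = _kernel_pair(kernel)
        self.c, self.stride = channels, stride
        self.weight = Param(
            he_uniform(rng, (channels, self.kh, self.kw), self.kh * self.kw)
        )
        self._xpad: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        s = self.stride
        ph, pw = self.kh // 2, self.kw // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = _strided_windows(xpad, self.kh, self.kw, s)
        y = np.einsum("nchwij,cij->nchw", win, self.weight.value, optimize=True)
        if training:
            self._xpad, self._xshape = xpad, x.shape
        else:
            self._xpad = None
        return np.ascontiguousarray(y.astype(F32, copy=False))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xpad is not None
        n, c, h, w = self._xshape
        s = self.stride
        ph, pw = self.kh // 2, self.kw // 2
        _, _, ho, wo = dy.shape
        win = _strided_windows(self._xpad, self.kh, self.kw, s)
        self.weight.grad += np.einsum("nchw,nchwij->cij", dy, win, optimize=True)
        dxpad = np.zeros_like(self._xpad)
        wv = self.weight.value
        for i in range(self.kh):
            for j in range(self.kw):
                dxpad[:, :, i : i + ho * s : s, j : j + wo * s : s] += (
                    dy * wv[:, i, j][None, :, None, None]
                )
        return dxpad[:, :, ph : ph + h, pw : pw + w]


class BatchNorm2d(Layer):
    """Batch normalisation over (N, H, W) per channel with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.c, self.momentum, self.eps = channels, momentum, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = Param(np.zeros(channels), trainable=False)
        self.running_var = Param(np.ones(channels), trainable=False)
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean.value = (m * self.running_mean.value + (1 - m) * mean).astype(F32)
            self.running_var.value = (m * self.running_var.value + (1 - m) * var).astype(F32)
        else:
            mean, var = self.running_mean.value, self.running_var.value
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        if training:
            self._xhat, self._inv_std = xhat.astype(F32), inv_std.astype(F32)
        return y.astype(F32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xhat is not None
        xhat, inv_std = self._xhat, self._inv_std
        n_eff = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        dx = g * (
            dy
            - dbeta[None, :, None, None] / n_eff
            - xhat * dgamma[None, :, None, None] / n_eff
        )
        return dx.astype(F32, copy=False)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return dy * self._mask


class AvgPool2d(Layer):
    """k x k average pooling, stride 1, same zero padding (zeros counted)."""

    def __init__(self, kernel: int = 3):
        self.k = kernel
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, p = self.k, self.k // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xpad, (k, k), axis=(2, 3))
        if training:
            self._xshape = x.shape
        return win.mean(axis=(-1, -2)).astype(F32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xshape is not None
        n, c, h, w = self._xshape
        k, p = self.k, self.k // 2
        dxpad = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        share = dy / (k * k)
        for i in range(k):
            for j in range(k):
                dxpad[:, :, i : i + h, j : j + w] += share
        return dxpad[:, :, p : p + h, p : p + w]


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def __init__(self) -> None:
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._xshape = x.shape
        return x.mean(axis=(2, 3)).astype(F32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xshape is not None
        n, c, h, w = self._xshape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w)).astype(F32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(he_uniform(rng, (n_out, n_in), n_in))
        self.bias = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class ECA(Layer):
    """Efficient channel attention: GAP -> 1-D conv across channels -> sigmoid gate.

    Global average pooling squeezes (N, C, H, W) to per-channel descriptors
    (N, C); a single shared 1-D convolution of odd kernel size ``k`` (zero
    padded) mixes each channel with its ``k - 1`` neighbours; the sigmoid of
    that response reweights the input channel-by-channel.  No channel
    dimensionality reduction takes place, and the layer owns exactly ``k``
    weights.
    """

    def __init__(self, channels: int, kernel_size: int):
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("ECA kernel size must be odd and >= 1")
        self.c, self.k = channels, kernel_size
        # identity-leaning start: gate ~ sigmoid(z) of the pooled descriptor
        w0 = np.zeros(kernel_size, dtype=F32)
        w0[kernel_size // 2] = 1.0
        self.weight = Param(w0)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight]

    def _conv1d(self, z: np.ndarray) -> np.ndarray:
        p = self.k // 2
        zp = np.pad(z, ((0, 0), (p, p)))
        s = np.zeros_like(z)
        for m in range(self.k):
            s += self.weight.value[m] * zp[:, m : m + self.c]
        return s

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.c:
            raise ValueError(f"expected {self.c} channels, got {x.shape[1]}")
        z = x.mean(axis=(2, 3))  # N, C
        gate = _sigmoid(self._conv1d(z))
        y = x * gate[:, :, None, None]
        if training:
            self._cache = (x, z, gate)
        return y.astype(F32, copy=False)

    def attention(self, x: np.ndarray) -> np.ndarray:
        """Per-channel gate values in (0, 1) for an input batch."""
        z = x.mean(axis=(2, 3))
        return _sigmoid(self._conv1d(z))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x, z, gate = self._cache
        n, c, h, w = x.shape
        p = self.k // 2
        dx = dy * gate[:, :, None, None]
        dgate = (dy * x).sum(axis=(2, 3))  # N, C
        ds = dgate * gate * (1.0 - gate)
        zp = np.pad(z, ((0, 0), (p, p)))
        for m in range(self.k):
            self.weight.grad[m] += float((ds * zp[:, m : m + c]).sum())
        dzp = np.zeros_like(zp)
        for m in range(self.k):
            dzp[:, m : m + c] += self.weight.value[m] * ds
        dz = dzp[:, p : p + c]
        dx += dz[:, :, None, None] / (h * w)
        return dx.astype(F32, copy=False)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def separable_conv(
    c_in: int,
    c_out: int,
    kernel: int | tuple[int, int] = 3,
    stride: int = 1,
    rng: np.random.Generator | None = None,
) -> Sequential:
    """Depthwise kh x kw followed by pointwise 1 x 1, no nonlinearity between.

    Bias-free: a normalisation layer is expected to follow, so the
    trainable weight count is exactly ``kh*kw*c_in + c_in*c_out``.
    """
    return Sequential(
        DepthwiseConv2d(c_in, kernel=kernel, stride=stride, rng=rng),
        Conv2d(c_in, c_out, kernel=1, stride=1, bias=False, rng=rng),
    )


# ---------------------------------------------------------------------------
# loss and optimisers
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), targets] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(F32)


class Optimizer:
    def __init__(self, params: Sequence[Param], lr: float):
        self.params = [p for p in params if p.trainable]
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params: Sequence[Param], lr: float = 0.01, momentum: float = 0.9):
        super().__init__(params, lr)
        self.momentum = momentum
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


class Adam(Optimizer):
    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 0.001,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# parameter bookkeeping / serialisation
# ---------------------------------------------------------------------------


def n_trainable(layer: Layer) -> int:
    return sum(p.size for p in layer.params() if p.trainable)


def n_non_trainable(layer: Layer) -> int:
    return sum(p.size for p in layer.params() if not p.trainable)


def get_state(layer: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in layer.params()]


def set_state(layer: Layer, state: Iterable[np.ndarray]) -> None:
    state = list(state)
    params = layer.params()
    if len(state) != len(params):
        raise ValueError(f"state has {len(state)} arrays, model expects {len(params)}")
    for p, arr in zip(params, state):
        if p.value.shape != arr.shape:
            raise ValueError(f"shape mismatch {p.value.shape} vs {arr.shape}")
        p.value = np.ascontiguousarray(arr, dtype=F32)
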