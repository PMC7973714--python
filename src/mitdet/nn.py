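"""Minimal NumPy layer framework with hand-written backward passes.

Supports exactly what the mitosis pipeline needs: strided convolution,
batch normalization (2-d and 1-d), leaky ReLU, average pooling, adaptive
average pooling, dropout, dense layers, residual blocks with projection
skips, softmax cross-entropy, and SGD with momentum / weight decay / cosine
annealing.  Tensors are NCHW ``float64``-free: everything runs in float32.

The framework is deterministic: all randomness (init, dropout) flows through
``numpy.random.Generator`` objects supplied by the caller.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "BatchNorm1d",
    "LeakyReLU",
    "AvgPool2d",
    "AdaptiveAvgPool2d",
    "Dropout",
    "Flatten",
    "Linear",
    "Crop2d",
    "Sequential",
    "Residual",
    "softmax",
    "softmax_cross_entropy",
    "init_network",
    "SGD",
    "cosine_lr",
]

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[Param]:
        return []

    def out_shape(self, in_shape: tuple) -> tuple:
        return in_shape


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


class Conv2d(Layer):
    """2-d convolution (cross-correlation) via sliding windows + einsum."""

    def __init__(self, in_ch: int, out_ch: int, kernel, stride=1, pad=0):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        self.ph, self.pw = _pair(pad)
        if min(self.kh, self.kw, self.sh, self.sw) <= 0:
            raise ValueError("kernel and stride must be positive")
        self.W = Param(np.zeros((out_ch, in_ch, self.kh, self.kw)))
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.in_ch:
            raise ValueError(f"Conv2d expects {self.in_ch} channels, got {c}")
        ho = (h + 2 * self.ph - self.kh) // self.sh + 1
        wo = (w + 2 * self.pw - self.kw) // self.sw + 1
        if ho <= 0 or wo <= 0:
            raise ValueError("conv output would be empty")
        return (self.out_ch, ho, wo)

    def _window(self, xp):
        cols = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        return cols[:, :, :: self.sh, :: self.sw]  # (N, C, Ho, Wo, kh, kw)

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        cols = self._window(xp)
        out = np.einsum("nchwij,ocij->nohw", cols, self.W.value, optimize=True)
        out += self.b.value[None, :, None, None]
        self._cache = (x.shape, xp)
        return out.astype(DTYPE)

    def backward(self, grad):
        x_shape, xp = self._cache
        grad = np.ascontiguousarray(grad, dtype=DTYPE)
        cols = self._window(xp)
        self.W.grad += np.einsum("nohw,nchwij->ocij", grad, cols, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        _, _, ho, wo = grad.shape
        for i in range(self.kh):
            for j in range(self.kw):
                patch = np.einsum("nohw,oc->nchw", grad, self.W.value[:, :, i, j], optimize=True)
                dxp[:, :, i : i + self.sh * ho : self.sh, j : j + self.sw * wo : self.sw] += patch
        if self.ph or self.pw:
            dxp = dxp[:, :, self.ph : dxp.shape[2] - self.ph or None, self.pw : dxp.shape[3] - self.pw or None]
        return dxp[:, :, : x_shape[2], : x_shape[3]]


class _BatchNorm(Layer):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.n_ch, self.momentum, self.eps = n_ch, momentum, eps
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch, dtype=DTYPE)
        self.running_var = np.ones(n_ch, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _expand(self, v, ndim):
        return v.reshape((1, -1) + (1,) * (ndim - 2))

    def forward(self, x, train=False, rng=None):
        x = np.asarray(x, dtype=DTYPE)
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._expand(mean, x.ndim)) * self._expand(inv, x.ndim)
        self._cache = (xhat, inv, axes, x.ndim, train)
        return (self._expand(self.gamma.value, x.ndim) * xhat + self._expand(self.beta.value, x.ndim)).astype(DTYPE)

    def backward(self, grad):
        xhat, inv, axes, ndim, train = self._cache
        grad = np.asarray(grad, dtype=DTYPE)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self._expand(self.gamma.value, ndim)
        if not train:
            return g * self._expand(inv, ndim)
        m = grad.size // grad.shape[1]
        term = g - self._expand(g.sum(axis=axes) / m, ndim) - xhat * self._expand((g * xhat).sum(axis=axes) / m, ndim)
        return term * self._expand(inv, ndim)


class BatchNorm2d(_BatchNorm):
    pass


class BatchNorm1d(_BatchNorm):
    pass


class LeakyReLU(Layer):
    """f(a) = a for a > 0, else slope * a (default slope 0.01)."""

    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=False, rng=None):
        x = np.asarray(x, dtype=DTYPE)
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class AvgPool2d(Layer):
    """Average pooling; zero padding counts toward the mean (count_include_pad)."""

    def __init__(self, kernel, stride=None, pad=0):
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride if stride is not None else kernel)
        self.ph, self.pw = _pair(pad)
        self._cache = None

    def out_shape(self, in_shape):
        c, h, w = in_shape
        ho = (h + 2 * self.ph - self.kh) // self.sh + 1
        wo = (w + 2 * self.pw - self.kw) // self.sw + 1
        return (c, ho, wo)

    def forward(self, x, train=False, rng=None):
        x = np.asarray(x, dtype=DTYPE)
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        cols = cols[:, :, :: self.sh, :: self.sw]
        self._cache = (x.shape, xp.shape, cols.shape)
        return cols.mean(axis=(4, 5)).astype(DTYPE)

    def backward(self, grad):
        x_shape, xp_shape, cols_shape = self._cache
        grad = np.asarray(grad, dtype=DTYPE) / (self.kh * self.kw)
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        _, _, ho, wo = grad.shape
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + self.sh * ho : self.sh, j : j + self.sw * wo : self.sw] += grad
        if self.ph or self.pw:
            dxp = dxp[:, :, self.ph : dxp.shape[2] - self.ph or None, self.pw : dxp.shape[3] - self.pw or None]
        return dxp[:, :, : x_shape[2], : x_shape[3]]


class AdaptiveAvgPool2d(Layer):
    """Average pool to a fixed output size; bin i spans [floor(i*H/o), ceil((i+1)*H/o))."""

    def __init__(self, output_size):
        self.oh, self.ow = _pair(output_size)
        self._cache = None

    def out_shape(self, in_shape):
        return (in_shape[0], self.oh, self.ow)

    @staticmethod
    def _bins(size, out):
        return [(int(math.floor(i * size / out)), int(math.ceil((i + 1) * size / out))) for i in range(out)]

    def forward(self, x, train=False, rng=None):
        x = np.asarray(x, dtype=DTYPE)
        n, c, h, w = x.shape
        rbins, cbins = self._bins(h, self.oh), self._bins(w, self.ow)
        out = np.empty((n, c, self.oh, self.ow), dtype=DTYPE)
        for i, (r0, r1) in enumerate(rbins):
            for j, (c0, c1) in enumerate(cbins):
                out[:, :, i, j] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
        self._cache = (x.shape, rbins, cbins)
        return out

    def backward(self, grad):
        x_shape, rbins, cbins = self._cache
        dx = np.zeros(x_shape, dtype=DTYPE)
        for i, (r0, r1) in enumerate(rbins):
            for j, (c0, c1) in enumerate(cbins):
                area = (r1 - r0) * (c1 - c0)
                dx[:, :, r0:r1, c0:c1] += grad[:, :, i, j][:, :, None, None] / area
        return dx


class Dropout(Layer):
    def __init__(self, p: float = 0.5):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return np.asarray(x, dtype=DTYPE)
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        return np.asarray(x, dtype=DTYPE) * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return np.asarray(x, dtype=DTYPE).reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int):
        self.n_in, self.n_out = n_in, n_out
        self.W = Param(np.zeros((n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def out_shape(self, in_shape):
        if int(np.prod(in_shape)) != self.n_in:
            raise ValueError(f"Linear expects {self.n_in} inputs, got {in_shape}")
        return (self.n_out,)

    def forward(self, x, train=False, rng=None):
        self._x = np.asarray(x, dtype=DTYPE)
        return self._x @ self.W.value + self.b.value

    def backward(self, grad):
        grad = np.asarray(grad, dtype=DTYPE)
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Crop2d(Layer):
    """Corner crop to a fixed spatial size (used to align projection skips)."""

    def __init__(self, height: int, width: int):
        self.h, self.w = height, width
        self._shape = None

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if h < self.h or w < self.w:
            raise ValueError("cannot crop to a larger size")
        return (c, self.h, self.w)

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return np.asarray(x, dtype=DTYPE)[:, :, : self.h, : self.w]

    def backward(self, grad):
        dx = np.zeros(self._shape, dtype=DTYPE)
        dx[:, :, : self.h, : self.w] = grad
        return dx


class Sequential(Layer):
    def __init__(self, layers: Iterable[Layer], name: str = ""):
        self.layers = list(layers)
        self.name = name

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def out_shape(self, in_shape):
        shape = in_shape
        for l in self.layers:
            shape = l.out_shape(shape)
        return shape

    def forward(self, x, train=False, rng=None):
        for l in self.layers:
            x = l.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Residual(Layer):
    """y = main(x) + skip(x); shapes must agree (declare a projection otherwise)."""

    def __init__(self, main: Layer, skip: Layer | None = None, name: str = ""):
        self.main = main
        self.skip = skip
        self.name = name

    def params(self):
        ps = self.main.params()
        if self.skip is not None:
            ps = ps + self.skip.params()
        return ps

    def out_shape(self, in_shape):
        mo = self.main.out_shape(in_shape)
        so = in_shape if self.skip is None else self.skip.out_shape(in_shape)
        if mo != so:
            raise ValueError(
                f"residual block {self.name or '?'}: main path {mo} != skip path {so}"
            )
        return mo

    def forward(self, x, train=False, rng=None):
        out = self.main.forward(x, train=train, rng=rng)
        identity = x if self.skip is None else self.skip.forward(x, train=train, rng=rng)
        if out.shape != identity.shape:
            raise ValueError(
                f"residual block {self.name or '?'}: shape mismatch {out.shape} vs {identity.shape}"
            )
        return out + identity

    def backward(self, grad):
        dmain = self.main.backward(grad)
        dskip = grad if self.skip is None else self.skip.backward(grad)
        return dmain + dskip


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient with respect to the logits."""
    p = softmax(np.asarray(logits, dtype=DTYPE))
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def _fans(param_shape):
    if len(param_shape) == 4:  # conv OIHW
        o, i, kh, kw = param_shape
        return i * kh * kw, o * kh * kw
    if len(param_shape) == 2:  # linear (in, out)
        return param_shape[0], param_shape[1]
    return param_shape[0], param_shape[0]


def glorot_bound(param_shape, mode: str = "reciprocal") -> float:
    """Uniform init bound.

    ``reciprocal``: 1/z with z the size of the previous layer (fan-in) — the
    literal printed rule.  ``glorot``: sqrt(6 / (fan_in + fan_out)), the
    standard Glorot/Xavier bound.
    """
    fan_in, fan_out = _fans(param_shape)
    if mode == "reciprocal":
        return 1.0 / fan_in
    if mode == "glorot":
        return math.sqrt(6.0 / (fan_in + fan_out))
    raise ValueError(f"unknown init mode {mode!r}")


def init_network(net: Layer, seed: int = 0, mode: str = "reciprocal") -> Layer:
    """Glorot-uniform weights (two bound conventions), zero biases, unit BN gains."""
    rng = np.random.default_rng(seed)
    for layer in iter_layers(net):
        if isinstance(layer, (Conv2d, Linear)):
            bound = glorot_bound(layer.W.value.shape, mode)
            layer.W.value = rng.uniform(-bound, bound, size=layer.W.value.shape).astype(DTYPE)
            layer.b.value = np.zeros_like(layer.b.value)
        elif isinstance(layer, _BatchNorm):
            layer.gamma.value = np.ones_like(layer.gamma.value)
            layer.beta.value = np.zeros_like(layer.beta.value)
            layer.running_mean[:] = 0
            layer.running_var[:] = 1
    return net


def iter_layers(net: Layer):
    yield net
    if isinstance(net, Sequential):
        for l in net.layers:
            yield from iter_layers(l)
    elif isinstance(net, Residual):
        yield from iter_layers(net.main)
        if net.skip is not None:
            yield from iter_layers(net.skip)


def get_state(net: Layer):
    """Deep copy of all trainable values and BN running stats."""
    state = []
    for l in iter_layers(net):
        for p in l.params() if not isinstance(l, (Sequential, Residual)) else []:
            state.append(p.value.copy())
        if isinstance(l, _BatchNorm):
            state.append(l.running_mean.copy())
            state.append(l.running_var.copy())
    return state


def set_state(net: Layer, state) -> None:
    it = iter(state)
    for l in iter_layers(net):
        for p in l.params() if not isinstance(l, (Sequential, Residual)) else []:
            p.value = next(it).copy()
        if isinstance(l, _BatchNorm):
            l.running_mean = next(it).copy()
            l.running_var = next(it).copy()


class SGD:
    """SGD with momentum, decoupled weight decay and an externally set rate."""

    def __init__(self, params: Sequence[Param], lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        for p, v in zip(self.params, self._vel):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value = (p.value - lr * v).astype(DTYPE)


def cosine_lr(base_lr: float, step: int, total_steps: int) -> float:
    """Cosine annealing from base_lr to 0 over total_steps (no restarts)."""
    if total_steps <= 1:
        return base_lr
    t = min(step, total_steps - 1) / (total_steps - 1)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * t))
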