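"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides exactly the operations the conditional wavelet-flow
model needs: broadcasting elementwise arithmetic, exp/log/tanh/leaky-ReLU,
reductions, reshaping/concatenation, channel gather (for permutations),
same-padding 2D convolution, 2x average pooling / nearest upsampling, and an
Adam optimizer with decoupled weight decay.  Tensors hold float64 data; the
graph is built eagerly and freed after ``backward``.

Gradient correctness of every op is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "gather_channels",
    "conv2d",
    "avg_pool2d",
    "upsample_nearest2d",
    "Conv2d",
    "Adam",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(np.asarray(g), self.data.shape)

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                # free graph references as we go
                t._backward = None
                t._parents = ()

    # -- basic arithmetic --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data >= 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope))

        return Tensor._make(np.where(mask, self.data, slope * self.data), (self,), backward)

    def square(self):
        return self * self

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(np.asarray(g).reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        g = np.asarray(g)
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def gather_channels(x: Tensor, index: np.ndarray, axis: int = 1) -> Tensor:
    """Permute/select entries along ``axis`` (scatter-add on backward)."""
    index = np.asarray(index)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            idx = [slice(None)] * x.data.ndim
            idx[axis] = index
            np.add.at(gx, tuple(idx), np.asarray(g))
            x._accum(gx)

    return Tensor._make(np.take(x.data, index, axis=axis), (x,), backward)


# -- convolution -----------------------------------------------------------

def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    kh, kw = w.shape[2], w.shape[3]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    out = np.einsum("nchwij,fcij->nfhw", win, w, optimize=True)
    return out + b[None, :, None, None]


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding, stride-1 2D convolution (cross-correlation convention).

    x: (N, C, H, W); w: (F, C, kh, kw) with odd kh, kw; b: (F,).
    """
    kh, kw = w.data.shape[2], w.data.shape[3]
    ph, pw = kh // 2, kw // 2

    def backward(g):
        g = np.asarray(g)
        if w.requires_grad or x.requires_grad:
            if w.requires_grad:
                xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
                win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
                w._accum(np.einsum("nchwij,nfhw->fcij", win, g, optimize=True))
            if x.requires_grad:
                gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
                gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
                wflip = w.data[:, :, ::-1, ::-1]
                x._accum(np.einsum("nfhwij,fcij->nchw", gwin, wflip, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._make(_conv_forward(x.data, w.data, b.data), (x, w, b), backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError("avg_pool2d requires spatial dims divisible by k")
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            g = np.asarray(g) / (k * k)
            x._accum(np.repeat(np.repeat(g, k, axis=2), k, axis=3))

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest2d(x: Tensor, k: int = 2) -> Tensor:
    def backward(g):
        if x.requires_grad:
            g = np.asarray(g)
            n, c, h, w = g.shape
            x._accum(g.reshape(n, c, h // k, k, w // k, k).sum(axis=(3, 5)))

    return Tensor._make(np.repeat(np.repeat(x.data, k, axis=2), k, axis=3), (x,), backward)


# -- layers / optimizer ----------------------------------------------------


class Conv2d:
    """Convolution layer with He-normal weight init (optionally zero init)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel, kernel))
        else:
            std = np.sqrt(2.0 / (in_ch * kernel * kernel))
            w = rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class Adam:
    """Adam with decoupled weight decay (the Gaussian parameter posterior)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def param_sq_norm(params) -> float:
    return float(sum(np.sum(p.data**2) for p in params))
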