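"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module supplies exactly the primitives the conditional-GAN models in
:mod:`sketchct.networks` need: dense and strided 2-D convolution (via
im2col), style-modulated convolution with weight demodulation, instance
normalisation, nearest-neighbour upsampling, channel concatenation, the
usual pointwise nonlinearities, and Adam/SGD optimisers.  It is a tape-based
design: every op returns a :class:`Tensor` holding the forward value and a
closure that propagates the upstream gradient to its parents.

All gradients are exercised by finite-difference checks in the test suite.
Computation defaults to float32; float64 is available for gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "Linear", "Conv2d", "ModulatedConv2d",
    "InstanceNorm2d", "Adam", "SGD",
    "concat", "upsample_nearest2x", "leaky_relu", "relu", "tanh", "sigmoid",
    "log", "mean", "abs_", "softmax_cross_entropy",
]


# ---------------------------------------------------------------------------
# Tensor and tape

_GRAD_ENABLED = True


class no_grad:
    """Context manager suppressing tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev


class Tensor:
    """An ndarray plus the backward closure that built it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        if _GRAD_ENABLED:
            self.requires_grad = bool(requires_grad) or any(
                p.requires_grad for p in parents)
            self._parents = parents
        else:
            self.requires_grad = False
            self._parents = ()
        self._backward = backward

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):   # keep weak scalar promotion
            out = Tensor(self.data + other, parents=(self,))
            out._backward = lambda g: self._accum(g)
            return out
        other = _wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (
            self._accum(_unbroadcast(g, self.shape)),
            other._accum(_unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, parents=(self,))
            out._backward = lambda g: self._accum(g * other)
            return out
        other = _wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (
            self._accum(_unbroadcast(g * other.data, self.shape)),
            other._accum(_unbroadcast(g * self.data, other.shape)))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        out._backward = lambda g: (
            self._accum(_unbroadcast(g / other.data, self.shape)),
            other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                      other.shape)))
        return out

    def __pow__(self, p):
        assert np.isscalar(p)
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def back(g):
            self._accum(g @ other.data.swapaxes(-1, -2))
            other._accum(self.data.swapaxes(-1, -2) @ g)
        out._backward = back
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))
        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Pointwise ops

def relu(x):
    x = _wrap(x)
    out = Tensor(np.maximum(x.data, 0), parents=(x,))
    out._backward = lambda g: x._accum(g * (x.data > 0))
    return out


def leaky_relu(x, alpha=0.2):
    x = _wrap(x)
    out = Tensor(np.where(x.data > 0, x.data, alpha * x.data), parents=(x,))
    out._backward = lambda g: x._accum(g * np.where(x.data > 0, 1.0, alpha))
    return out


def tanh(x):
    x = _wrap(x)
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: x._accum(g * (1 - y * y))
    return out


def sigmoid(x):
    x = _wrap(x)
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: x._accum(g * y * (1 - y))
    return out


def log(x):
    x = _wrap(x)
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: x._accum(g / x.data)
    return out


def abs_(x):
    x = _wrap(x)
    out = Tensor(np.abs(x.data), parents=(x,))
    out._backward = lambda g: x._accum(g * np.sign(x.data))
    return out


def mean(x, axis=None, keepdims=False):
    return _wrap(x).mean(axis=axis, keepdims=keepdims)


def clip_values(x, lo, hi):
    """Clamp with zero gradient outside [lo, hi] (used for probability eps)."""
    x = _wrap(x)
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))
    out._backward = lambda g: x._accum(
        g * ((x.data >= lo) & (x.data <= hi)))
    return out


# ---------------------------------------------------------------------------
# Structural ops

def concat(tensors, axis=1):
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = back
    return out


def upsample_nearest2x(x):
    x = _wrap(x)
    n, c, h, w = x.shape
    up = np.broadcast_to(x.data[:, :, :, None, :, None],
                         (n, c, h, 2, w, 2)).reshape(n, c, 2 * h, 2 * w)
    out = Tensor(up, parents=(x,))
    out._backward = lambda g: x._accum(
        g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
    return out


# ---------------------------------------------------------------------------
# im2col convolution machinery

def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    # fill per kernel tap: each slice copy is row-contiguous, and the
    # (n, c, kh, kw, oh, ow) buffer reshapes to columns for free
    cols6 = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols6[:, :, i, j] = xp[:, :, i:i + oh * stride:stride,
                                   j:j + ow * stride:stride]
    return cols6.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(cols, x_shape, kh, kw, stride, pad, oh, ow):
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + oh * stride:stride,
               j:j + ow * stride:stride] += cols6[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w]


def conv2d(x, weight, bias=None, stride=1, pad=0):
    """Standard 2-D convolution (cross-correlation), NCHW layout."""
    x, weight = _wrap(x), _wrap(weight)
    o, c, kh, kw = weight.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    w2 = weight.data.reshape(o, c * kh * kw)
    out_data = np.matmul(w2, cols).reshape(x.shape[0], o, oh, ow)
    parents = (x, weight)
    if bias is not None:
        bias = _wrap(bias)
        out_data = out_data + bias.data.reshape(1, o, 1, 1)
        parents = parents + (bias,)
    out = Tensor(out_data, parents=parents)
    if not out.requires_grad:
        return out          # inference: do not retain cols in a closure

    def back(g):
        g2 = g.reshape(g.shape[0], o, oh * ow)
        weight._accum(np.einsum("nol,nkl->ok", g2, cols,
                                optimize=True).reshape(weight.shape))
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3)))
        dcols = np.matmul(w2.T, g2)
        x._accum(_col2im(dcols, x.shape, kh, kw, stride, pad, oh, ow))
    out._backward = back
    return out


def modulated_conv2d(x, weight, scales, bias=None, demodulate=True,
                     eps=1e-8, pad=1):
    """Style-modulated 3x3 convolution with optional weight demodulation.

    The base kernel ``weight[o, i]`` is scaled per input channel by
    ``scales[n, i]`` for each sample, then (optionally) each output
    channel's effective kernel is rescaled to unit L2 norm:
    ``k'' = k' / sqrt(sum k'^2 + eps)``.  With ``scales == 1`` and
    demodulation off this reduces exactly to :func:`conv2d`.
    """
    x, weight, scales = _wrap(x), _wrap(weight), _wrap(scales)
    o, c, kh, kw = weight.shape
    n = x.shape[0]
    if scales.shape != (n, c):
        raise ValueError(
            f"style scales shape {scales.shape} != (batch, in_ch) {(n, c)}")
    # Scaling the kernel per input channel equals scaling the input
    # channels before a shared-kernel convolution, and demodulation is a
    # per-(sample, output-channel) rescale; composing from primitives
    # keeps a single BLAS convolution per call.
    y = conv2d(x * scales.reshape(n, c, 1, 1), weight, None, 1, pad)
    if demodulate:
        w_sq = (weight ** 2).sum(axis=(2, 3))          # (o, c)
        denom_sq = (scales ** 2) @ _transpose2d(w_sq) + eps
        y = y * denom_sq.reshape(n, o, 1, 1) ** -0.5
    if bias is not None:
        y = y + _wrap(bias).reshape(1, o, 1, 1)
    return y


def _transpose2d(t):
    t = _wrap(t)
    out = Tensor(t.data.T, parents=(t,))
    out._backward = lambda g: t._accum(g.T)
    return out


def instance_norm(x, gamma, beta, eps=1e-5):
    """Per-sample, per-channel normalisation over the spatial dimensions."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    n, c, h, w = x.shape
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data.reshape(1, c, 1, 1)
                 + beta.data.reshape(1, c, 1, 1),
                 parents=(x, gamma, beta))
    if not out.requires_grad:
        return out

    def back(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        dxhat = g * gamma.data.reshape(1, c, 1, 1)
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        x._accum(inv * (dxhat - m1 - xhat * m2))
    out._backward = back
    return out


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    logits = _wrap(logits)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    out = Tensor(nll, parents=(logits,))

    def back(g):
        dp = p.copy()
        dp[np.arange(n), labels] -= 1.0
        logits._accum(g * dp / n)
    out._backward = back
    return out


# ---------------------------------------------------------------------------
# Modules

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data))
        self.requires_grad = True  # even if constructed under no_grad


class Module:
    """Tiny container with recursive parameter discovery."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        out.append(item)
                    elif isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def n_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = np.asarray(a, dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in, n_out, rng, w_std=None, bias_init=0.0,
                 dtype=np.float32):
        std = w_std if w_std is not None else 1.0 / np.sqrt(n_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(n_in, n_out)).astype(dtype))
        self.bias = Parameter(np.full(n_out, bias_init, dtype=dtype))

    def forward(self, x):
        return _wrap(x) @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride=1, pad=0, rng=None,
                 w_std=0.02, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(rng.normal(
            0.0, w_std, size=(c_out, c_in, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self.stride, self.pad = stride, pad

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ModulatedConv2d(Module):
    def __init__(self, c_in, c_out, kernel=3, rng=None, w_std=0.02,
                 demodulate=True, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(rng.normal(
            0.0, w_std, size=(c_out, c_in, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self.demodulate = demodulate
        self.pad = kernel // 2

    def forward(self, x, scales):
        return modulated_conv2d(x, self.weight, scales, self.bias,
                                demodulate=self.demodulate, pad=self.pad)


class InstanceNorm2d(Module):
    def __init__(self, c, dtype=np.float32):
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))

    def forward(self, x):
        return instance_norm(x, self.gamma, self.beta)


# ---------------------------------------------------------------------------
# Optimisers

class Adam:
    def __init__(self, params, lr=1e-5, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

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
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, params, lr=1e-4):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad
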