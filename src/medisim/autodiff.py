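"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the record model needs: broadcast-aware
arithmetic, matmul, slicing/concat, softmax, sigmoid/tanh/relu, reductions,
and a numerically stable binary-cross-entropy-with-logits. Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` via topological
sort. A module-level no-grad mode skips graph construction entirely, which
is what the sampling / inference paths use.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._prev: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        g = _unbroadcast(grad, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, pow_(other, -1.0))

    def __rtruediv__(self, other):
        return mul(other, pow_(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return mul(sum_(self, axis=axis, keepdims=keepdims), 1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def swapaxes(self, a, b):
        return swapaxes(self, a, b)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


# -- primitives ------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accum(g)
        b._accum(g)

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accum(g * b.data)
        b._accum(g * a.data)

    return _make(out_data, (a, b), backward)


def pow_(a, p: float):
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        a._accum(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accum(_unbroadcast(ga, a.data.shape))
        b._accum(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def exp(a):
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return _make(out_data, (a,), backward)


def relu(a):
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        a._accum(g * (a.data > 0.0))

    return _make(out_data, (a,), backward)


def tanh(a):
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        a._accum(g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    out_data = _sigmoid(a.data)

    def backward(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # piecewise form avoids overflow in exp for large |x|
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(a, axis=-1):
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accum(out_data * (g - dot))

    return _make(out_data, (a,), backward)


def sum_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a_ % a.data.ndim for a_ in axes):
                g = np.expand_dims(g, ax)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def reshape(a, shape):
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def swapaxes(a, ax1, ax2):
    a = as_tensor(a)
    out_data = np.swapaxes(a.data, ax1, ax2)

    def backward(g):
        a._accum(np.swapaxes(g, ax1, ax2))

    return _make(out_data, (a,), backward)


def getitem(a, idx):
    a = as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accum(full)

    return _make(out_data, (a,), backward)


def concat(tensors, axis=-1):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return _make(out_data, tuple(tensors), backward)


def softplus(a):
    a = as_tensor(a)
    out_data = np.logaddexp(0.0, a.data)

    def backward(g):
        a._accum(g * _sigmoid(a.data))

    return _make(out_data, (a,), backward)


def bce_with_logits(logits, targets, weight=None):
    """Elementwise ``-log Bernoulli(target | sigmoid(logit))``, numerically stable.

    ``targets`` and ``weight`` are constants (plain arrays); only ``logits``
    receives gradient. Returns the elementwise loss tensor.
    """
    logits = as_tensor(logits)
    y = np.asarray(targets, dtype=np.float64)
    loss = np.logaddexp(0.0, logits.data) - y * logits.data
    w = None if weight is None else np.asarray(weight, dtype=np.float64)
    out_data = loss if w is None else loss * w

    def backward(g):
        base = _sigmoid(logits.data) - y
        logits._accum(g * (base if w is None else base * w))

    return _make(out_data, (logits,), backward)


def layer_norm(x, gain, bias, eps: float = 1e-5):
    """Layer normalization over the last axis, composed from primitives."""
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return centred * inv * gain + bias


def log_bernoulli(probs: np.ndarray, outcomes: np.ndarray, eps: float = 1e-12):
    """Plain-NumPy log-likelihood of binary outcomes under given probabilities.

    Probabilities are clamped to ``[eps, 1-eps]``; returns the elementwise
    log-likelihood array and the number of positions where clamping changed
    the realized-outcome likelihood (present code with prob < eps, or absent
    code with prob > 1-eps).
    """
    p = np.clip(probs, eps, 1.0 - eps)
    n_clamped = int(np.sum(np.where(outcomes > 0.5, probs < eps,
                                    probs > 1.0 - eps)))
    ll = np.where(outcomes > 0.5, np.log(p), np.log1p(-p))
    return ll, n_clamped


# -- optimizer -------------------------------------------------------------

class Adam:
    """Adam optimizer over a flat dict of parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
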