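"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tiny tape-based engine sized for the desk-scale transformer in this
package: dense ops with full broadcasting, batched matmul, fused
softmax / sigmoid / gelu / layer normalisation, embedding lookup and
concatenation.  Gradients accumulate into ``Tensor.grad`` after
``Tensor.backward()``; tensors with ``requires_grad=False`` terminate
the tape.

The engine is dtype-agnostic: parameters are float32 for speed, while
tests may build float64 graphs for finite-difference checks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "div", "matmul", "power", "exp", "log",
    "tanh", "sigmoid", "gelu", "softmax", "layer_norm", "embedding",
    "reshape", "transpose", "concat", "take_position", "sum_", "mean_",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, np.ndarray):
            self.data = data
        elif isinstance(data, np.generic):  # numpy scalar: keep its dtype
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return mul(self, _as_tensor(np.asarray(-1.0, dtype=self.data.dtype)))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, k):
        return power(self, k)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# -- arithmetic ---------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    out = _make(out_data, (a, b), backward)
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(-g)

    out = _make(out_data, (a, b), backward)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accumulate(g * b.data)
        if b.requires_grad:
            b._accumulate(g * a.data)

    out = _make(out_data, (a, b), backward)
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accumulate(g / b.data)
        if b.requires_grad:
            b._accumulate(-g * out_data / b.data)

    out = _make(out_data, (a, b), backward)
    return out


def power(a: Tensor, k: float) -> Tensor:
    out_data = a.data ** k

    def backward():
        a._accumulate(out.grad * k * a.data ** (k - 1))

    out = _make(out_data, (a,), backward)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(ga)
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(gb)

    out = _make(out_data, (a, b), backward)
    return out


# -- elementwise nonlinearities ----------------------------------------

def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward():
        a._accumulate(out.grad * out_data)

    out = _make(out_data, (a,), backward)
    return out


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def backward():
        a._accumulate(out.grad / a.data)

    out = _make(out_data, (a,), backward)
    return out


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward():
        a._accumulate(out.grad * (1.0 - out_data * out_data))

    out = _make(out_data, (a,), backward)
    return out


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward():
        a._accumulate(out.grad * out_data * (1.0 - out_data))

    out = _make(out_data, (a,), backward)
    return out


_GELU_C = 0.7978845608028654  # sqrt(2/pi)


def gelu(a: Tensor) -> Tensor:
    # tanh approximation; closed-form gradient
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x ** 3)
    t = np.tanh(inner)
    out_data = 0.5 * x * (1.0 + t)

    def backward():
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * x ** 2)
        da = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
        a._accumulate(out.grad * da)

    out = _make(out_data, (a,), backward)
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward():
        g = out.grad
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot))

    out = _make(out_data, (a,), backward)
    return out


def layer_norm(a: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis to zero mean / unit variance (no affine)."""
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv

    def backward():
        g = out.grad
        gm = g.mean(axis=-1, keepdims=True)
        gx = (g * xhat).mean(axis=-1, keepdims=True)
        a._accumulate(inv * (g - gm - xhat * gx))

    out = _make(xhat, (a,), backward)
    return out


# -- shape ops ----------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward():
        a._accumulate(out.grad.reshape(a.data.shape))

    out = _make(out_data, (a,), backward)
    return out


def transpose(a: Tensor, axes) -> Tensor:
    out_data = a.data.transpose(axes)
    inv_axes = np.argsort(axes)

    def backward():
        a._accumulate(out.grad.transpose(inv_axes))

    out = _make(out_data, (a,), backward)
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward():
        g = out.grad
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out = _make(out_data, tuple(tensors), backward)
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup: out[..., :] = weight[ids[...], :]."""
    out_data = weight.data[ids]

    def backward():
        g = np.zeros_like(weight.data)
        np.add.at(g, ids, out.grad)
        weight._accumulate(g)

    out = _make(out_data, (weight,), backward)
    return out


def take_position(a: Tensor, pos: int) -> Tensor:
    """Select one sequence position from a (B, T, H) tensor -> (B, H)."""
    out_data = a.data[:, pos, :]

    def backward():
        g = np.zeros_like(a.data)
        g[:, pos, :] = out.grad
        a._accumulate(g)

    out = _make(out_data, (a,), backward)
    return out


# -- reductions ---------------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward():
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    out = _make(out_data, (a,), backward)
    return out


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    s = sum_(a, axis=axis, keepdims=keepdims)
    return mul(s, _as_tensor(np.asarray(1.0 / n, dtype=a.data.dtype)))
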