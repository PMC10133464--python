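"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the primitives needed by the segmentation networks and losses are
implemented.  Tensors are float64 throughout; graphs are built eagerly and
freed after ``backward``.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._prev = _prev
        self._backward = _backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph management ----------------------------------------------
    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the closure so intermediate buffers can be collected
            if node is not self:
                node._backward = None
                node._prev = ()

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -astensor(other))

    def __rsub__(self, other):
        return add(astensor(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(astensor(other), self)

    def __pow__(self, c):
        return power(self, c)

    # -- shaped views --------------------------------------------------
    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int)
                       else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def flip(self, axis: int):
        return flip(self, axis)

    def rot90(self, k: int, axes: tuple[int, int]):
        return rot90(self, k, axes)

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def __getitem__(self, idx):
        return getitem(self, idx)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if not (t.requires_grad or t._backward is not None):
        return
    if t.grad is None:
        t.grad = np.array(g)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _make(data, parents: Sequence[Tensor], backward):
    needs = any(p.requires_grad or p._backward is not None for p in parents)
    if needs:
        return Tensor(data, _prev=tuple(parents), _backward=backward)
    return Tensor(data)


# -- primitive ops -----------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd)


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data / b.data

    def bwd(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(out_data, (a, b), bwd)


def power(a, c: float) -> Tensor:
    a = astensor(a)
    out_data = a.data ** c

    def bwd(g):
        _accum(a, g * c * a.data ** (c - 1))

    return _make(out_data, (a,), bwd)


def exp(a) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)

    def bwd(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), bwd)


def log(a) -> Tensor:
    a = astensor(a)
    out_data = np.log(a.data)

    def bwd(g):
        _accum(a, g / a.data)

    return _make(out_data, (a,), bwd)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where unclipped."""
    a = astensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def bwd(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), bwd)


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def bwd(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), bwd)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, slope * a.data)

    def bwd(g):
        _accum(a, g * np.where(mask, 1.0, slope))

    return _make(out_data, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = astensor(a)
    out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

    def bwd(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bwd)


def softplus(a) -> Tensor:
    """log(1 + exp(x)), numerically stable."""
    a = astensor(a)
    x = a.data
    out_data = np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)

    def bwd(g):
        _accum(a, g / (1.0 + np.exp(-np.clip(x, -500, 500))))

    return _make(out_data, (a,), bwd)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        gg = g
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(ax % a.data.ndim for ax in axes):
                gg = np.expand_dims(gg, ax)
        _accum(a, np.broadcast_to(gg, a.data.shape).copy())

    return _make(out_data, (a,), bwd)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def bwd(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(out_data, (a,), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]

    def bwd(g):
        splits = np.cumsum(sizes)[:-1]
        for t, gpart in zip(ts, np.split(g, splits, axis=axis)):
            _accum(t, gpart)

    return _make(out_data, tuple(ts), bwd)


def flip(a, axis: int) -> Tensor:
    a = astensor(a)
    out_data = np.flip(a.data, axis=axis)

    def bwd(g):
        _accum(a, np.flip(g, axis=axis))

    return _make(out_data, (a,), bwd)


def rot90(a, k: int, axes: tuple[int, int]) -> Tensor:
    a = astensor(a)
    out_data = np.rot90(a.data, k=k, axes=axes)

    def bwd(g):
        _accum(a, np.rot90(g, k=-k, axes=axes))

    return _make(out_data, (a,), bwd)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    out_data = a.data[idx]

    def bwd(g):
        buf = np.zeros_like(a.data)
        buf[idx] += g
        _accum(a, buf)

    return _make(out_data, (a,), bwd)


def softmax(logits: Tensor, axis: int = 1) -> Tensor:
    """Softmax along ``axis``; max-shifted for stability (shift is constant)."""
    logits = astensor(logits)
    shift = logits.data.max(axis=axis, keepdims=True)
    e = exp(logits - shift)
    return e / tsum(e, axis=axis, keepdims=True)
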