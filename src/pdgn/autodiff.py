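"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model components in this package (convolutional patch encoder, gated
temporal cell, feed-forward decoder) and every training loss are small
dense computations, so a compact tape-based engine in float64 is adequate:
build a graph of :class:`Tensor` operations, call :meth:`Tensor.backward`
on a scalar, and read gradients from ``.grad``.

All helper functions (:func:`tanh`, :func:`relu`, ...) dispatch on type:
given plain numpy input they compute with numpy and return numpy, so loss
functions written against this module work both as differentiable graph
nodes and as ordinary numerical routines.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "tanh",
    "sigmoid",
    "relu",
    "exp",
    "log",
    "sqrt",
    "clip",
    "maximum",
    "concatenate",
    "stack",
    "softmax",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __array_priority__ = 1000  # make numpy defer to reflected operators

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev
        self.name = name

    # ------------------------------------------------------------------
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

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo, visited = [], set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in visited:
                stack_.pop()
                continue
            pending = [p for p in node._prev if id(p) not in visited]
            if pending:
                stack_.extend(pending)
            else:
                visited.add(id(node))
                topo.append(node)
                stack_.pop()
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(g)
                if other.requires_grad:
                    other._accum(g)
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(g * other.data)
                if other.requires_grad:
                    other._accum(g * self.data)
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(g / other.data)
                if other.requires_grad:
                    other._accum(-g * self.data / other.data ** 2)
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** p, _prev=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))
        if out.requires_grad:
            def _bw(g):
                a, b = self.data, other.data
                if self.requires_grad:
                    if a.ndim == 1 and b.ndim == 1:
                        self._accum(g * b)
                    elif a.ndim == 1:
                        self._accum(g @ b.T)
                    elif b.ndim == 1:
                        self._accum(np.outer(g, b) if a.ndim == 2 else np.einsum("...i,j->...ij", g, b))
                    else:
                        self._accum(g @ np.swapaxes(b, -1, -2))
                if other.requires_grad:
                    if a.ndim == 1 and b.ndim == 1:
                        other._accum(g * a)
                    elif a.ndim == 1:
                        other._accum(np.outer(a, g))
                    elif b.ndim == 1:
                        other._accum((a * g[..., None]).sum(axis=tuple(range(a.ndim - 1))))
                    else:
                        other._accum(np.swapaxes(a, -1, -2) @ g)
            out._backward = _bw
        return out

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # ------------------------------------------------------------------
    # reductions and reshaping
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        if out.requires_grad:
            def _bw(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape))
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, self.data.shape))
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        if out.requires_grad:
            inv = np.argsort(axes) if axes else None
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))
        if out.requires_grad:
            def _bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = _bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_t(x) -> bool:
    return isinstance(x, Tensor)


# ----------------------------------------------------------------------
# elementwise functions, numpy-or-Tensor
def tanh(x):
    if not _is_t(x):
        return np.tanh(x)
    out = Tensor(np.tanh(x.data), _prev=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * (1.0 - out.data ** 2))
    return out


def sigmoid(x):
    if not _is_t(x):
        return 1.0 / (1.0 + np.exp(-x))
    out = Tensor(1.0 / (1.0 + np.exp(-x.data)), _prev=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * out.data * (1.0 - out.data))
    return out


def relu(x):
    if not _is_t(x):
        return np.maximum(x, 0.0)
    out = Tensor(np.maximum(x.data, 0.0), _prev=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * (x.data > 0))
    return out


def exp(x):
    if not _is_t(x):
        return np.exp(x)
    out = Tensor(np.exp(x.data), _prev=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * out.data)
    return out


def log(x):
    if not _is_t(x):
        return np.log(x)
    out = Tensor(np.log(x.data), _prev=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g / x.data)
    return out


def sqrt(x):
    if not _is_t(x):
        return np.sqrt(x)
    out = Tensor(np.sqrt(x.data), _prev=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * 0.5 / out.data)
    return out


def clip(x, lo, hi):
    """Clamp to [lo, hi]; gradient is passed through inside the interval."""
    if not _is_t(x):
        return np.clip(x, lo, hi)
    out = Tensor(np.clip(x.data, lo, hi), _prev=(x,))
    if out.requires_grad:
        mask = (x.data >= lo) & (x.data <= hi)
        out._backward = lambda g: x._accum(g * mask)
    return out


def maximum(x, y):
    """Elementwise max; at ties the gradient goes to the first argument."""
    if not _is_t(x) and not _is_t(y):
        return np.maximum(x, y)
    x, y = as_tensor(x), as_tensor(y)
    out = Tensor(np.maximum(x.data, y.data), _prev=(x, y))
    if out.requires_grad:
        mask = x.data >= y.data
        def _bw(g):
            if x.requires_grad:
                x._accum(g * mask)
            if y.requires_grad:
                y._accum(g * ~mask)
        out._backward = _bw
    return out


def concatenate(parts, axis=0):
    if not any(_is_t(p) for p in parts):
        return np.concatenate(parts, axis=axis)
    parts = [as_tensor(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), _prev=tuple(parts))
    if out.requires_grad:
        sizes = [p.data.shape[axis] for p in parts]
        splits = np.cumsum(sizes)[:-1]
        def _bw(g):
            for p, piece in zip(parts, np.split(g, splits, axis=axis)):
                if p.requires_grad:
                    p._accum(piece)
        out._backward = _bw
    return out


def stack(parts, axis=0):
    if not any(_is_t(p) for p in parts):
        return np.stack(parts, axis=axis)
    parts = [as_tensor(p) for p in parts]
    out = Tensor(np.stack([p.data for p in parts], axis=axis), _prev=tuple(parts))
    if out.requires_grad:
        def _bw(g):
            for i, p in enumerate(parts):
                if p.requires_grad:
                    p._accum(np.take(g, i, axis=axis))
        out._backward = _bw
    return out


def softmax(x, axis=-1):
    """Numerically stable softmax (max-subtracted before exponentiation)."""
    if not _is_t(x):
        m = np.max(x, axis=axis, keepdims=True)
        e = np.exp(x - m)
        return e / e.sum(axis=axis, keepdims=True)
    m = np.max(x.data, axis=axis, keepdims=True)  # constant shift, exact gradient
    e = exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


# ----------------------------------------------------------------------
class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
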