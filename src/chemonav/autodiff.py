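"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides exactly the operator set needed by the policy networks
(dense layers, gated recurrent units, Gaussian log-likelihoods, clipped
surrogate objectives) and by input-gradient attribution.  It is deliberately
small: a :class:`Tensor` wraps an ``ndarray``, records its parents and a
backward closure, and :meth:`Tensor.backward` runs the reverse topological
sweep.  Broadcasting follows numpy semantics; gradients are un-broadcast by
summing over expanded axes.

The free functions (``tanh``, ``sigmoid``, ``softplus``, ``concat``, ...)
accept either :class:`Tensor` or plain arrays and dispatch accordingly, so a
network forward pass can be written once and run both as a cheap inference
path (pure numpy) and as a differentiable path (Tensors).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tanh",
    "sigmoid",
    "softplus",
    "exp",
    "log",
    "square",
    "absolute",
    "clip",
    "minimum",
    "maximum",
    "concat",
    "matmul",
    "mean",
    "total",
    "is_tensor",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # keep numpy from hijacking ndarray (op) Tensor expressions
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # -- autodiff core --------------------------------------------------------

    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` into every upstream leaf."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: self._accum(-g))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(-g)

        return Tensor._from_op(self.data - other.data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    def __rmatmul__(self, other):
        return Tensor(other) @ self

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        return Tensor._from_op(
            self.data.reshape(*shape),
            (self,),
            lambda g: self._accum(g.reshape(self.data.shape)),
        )


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


# -- dispatching elementwise functions ----------------------------------------


def tanh(x):
    if isinstance(x, Tensor):
        y = np.tanh(x.data)
        return Tensor._from_op(y, (x,), lambda g: x._accum(g * (1.0 - y**2)))
    return np.tanh(x)


def sigmoid(x):
    if isinstance(x, Tensor):
        y = 1.0 / (1.0 + np.exp(-x.data))
        return Tensor._from_op(y, (x,), lambda g: x._accum(g * y * (1.0 - y)))
    return 1.0 / (1.0 + np.exp(-x))


def _softplus(z: np.ndarray) -> np.ndarray:
    # overflow-safe log(1 + e^z)
    return np.logaddexp(0.0, z)


def softplus(x):
    if isinstance(x, Tensor):
        y = _softplus(x.data)
        s = 1.0 / (1.0 + np.exp(-x.data))
        return Tensor._from_op(y, (x,), lambda g: x._accum(g * s))
    return _softplus(x)


def exp(x):
    if isinstance(x, Tensor):
        y = np.exp(x.data)
        return Tensor._from_op(y, (x,), lambda g: x._accum(g * y))
    return np.exp(x)


def log(x):
    if isinstance(x, Tensor):
        return Tensor._from_op(np.log(x.data), (x,), lambda g: x._accum(g / x.data))
    return np.log(x)


def square(x):
    if isinstance(x, Tensor):
        return x * x
    return np.square(x)


def absolute(x):
    if isinstance(x, Tensor):
        return Tensor._from_op(
            np.abs(x.data), (x,), lambda g: x._accum(g * np.sign(x.data))
        )
    return np.abs(x)


def clip(x, lo: float, hi: float):
    """Clip to [lo, hi]; gradient is 1 strictly inside the interval, 0 outside."""
    if isinstance(x, Tensor):
        inside = (x.data > lo) & (x.data < hi)
        return Tensor._from_op(
            np.clip(x.data, lo, hi), (x,), lambda g: x._accum(g * inside)
        )
    return np.clip(x, lo, hi)


def minimum(a, b):
    """Elementwise min; ties route the gradient to the first argument."""
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a = a if isinstance(a, Tensor) else Tensor(a)
        b = b if isinstance(b, Tensor) else Tensor(b)
        take_a = a.data <= b.data

        def backward(g):
            if a.requires_grad:
                a._accum(g * take_a)
            if b.requires_grad:
                b._accum(g * ~take_a)

        return Tensor._from_op(np.minimum(a.data, b.data), (a, b), backward)
    return np.minimum(a, b)


def maximum(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a = a if isinstance(a, Tensor) else Tensor(a)
        b = b if isinstance(b, Tensor) else Tensor(b)
        take_a = a.data >= b.data

        def backward(g):
            if a.requires_grad:
                a._accum(g * take_a)
            if b.requires_grad:
                b._accum(g * ~take_a)

        return Tensor._from_op(np.maximum(a.data, b.data), (a, b), backward)
    return np.maximum(a, b)


def concat(parts, axis: int = -1):
    if any(isinstance(p, Tensor) for p in parts):
        parts = [p if isinstance(p, Tensor) else Tensor(p) for p in parts]
        sizes = [p.data.shape[axis] for p in parts]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
                if not p.requires_grad:
                    continue
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p._accum(g[tuple(sl)])

        return Tensor._from_op(
            np.concatenate([p.data for p in parts], axis=axis),
            tuple(parts),
            backward,
        )
    return np.concatenate(parts, axis=axis)


def matmul(a, b):
    """2D matrix product.

    The plain-array (inference) path uses ``einsum``, whose per-element
    reduction order does not depend on the number of rows in the batch, so
    batched policy evaluation is bit-identical however episodes are grouped.
    The Tensor (training) path keeps the faster BLAS product.
    """
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a = a if isinstance(a, Tensor) else Tensor(a)
        return a @ b
    return np.einsum("ij,jk->ik", a, b)


def mean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)


def total(x, axis=None, keepdims=False):
    """Sum (named to avoid shadowing the builtin)."""
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)
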