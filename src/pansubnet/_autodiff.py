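"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the subtype network: broadcast-aware add/mul,
matmul, row softmax, tanh/sigmoid/softplus, reshape/concat/indexing and
reductions.  Gradients are accumulated by a topological-order sweep over the
recorded tape.  Correctness is pinned by finite-difference checks in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=float, copy=True)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    # ---- graph construction helpers -------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, self.requires_grad, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accumulate(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      (self, other), backward)

    @property
    def T(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.T)

        return Tensor(self.data.T, self.requires_grad, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), self.requires_grad, (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor(self.data[idx], self.requires_grad, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, 1.0) * g)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      self.requires_grad, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def sigmoid(self):
        out_data = sigmoid(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def softmax(self, axis: int = -1):
        x = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(x)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accumulate(out_data * (g - dot))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sigmoid(self.data))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    # ---- backprop --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(np.asarray(x, dtype=float))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, any(t.requires_grad for t in tensors),
                  tuple(tensors), backward)


def stack_outer(a: Tensor, b: Tensor) -> Tensor:
    """Row-wise outer products: (k, m), (k, n) -> (k, m*n), rows vec(a_i b_i^T)."""
    k, m = a.shape
    _, n = b.shape
    return (a.reshape(k, m, 1) * b.reshape(k, 1, n)).reshape(k, m * n)
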