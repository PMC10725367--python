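"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the node classifier in this package: broadcasted
elementwise arithmetic, matrix products, reductions, row gathering,
concatenation, the activations the model configures (ELU/ReLU/Tanh plus
sigmoid for gating), a numerically stable softmax and a fused
softmax-cross-entropy loss.  Gradients accumulate into ``Tensor.grad``
after ``Tensor.backward()``.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph traversal -------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative post-order DFS
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for t in order:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # ---- helpers ---------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other, out_data, grad_a, grad_b):
        other = Tensor._wrap(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad_a(g), self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad_b(g), other.data.shape))

        return Tensor(out_data, req, (self, other), backward if req else None)

    def _unary(self, out_data, grad_fn):
        req = self.requires_grad

        def backward(g):
            self._accumulate(_unbroadcast(grad_fn(g), self.data.shape))

        return Tensor(out_data, req, (self,), backward if req else None)

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        o = Tensor._wrap(other)
        return self._binary(o, self.data + o.data, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __neg__(self):
        return self._unary(-self.data, lambda g: -g)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        o = Tensor._wrap(other)
        return self._binary(o, self.data * o.data,
                            lambda g: g * o.data, lambda g: g * self.data)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = self.data ** p
        return self._unary(out, lambda g: g * p * self.data ** (p - 1.0))

    def __matmul__(self, other):
        o = Tensor._wrap(other)
        return self._binary(o, self.data @ o.data,
                            lambda g: g @ o.data.T, lambda g: self.data.T @ g)

    def __getitem__(self, idx):
        out = self.data[idx]

        def grad_fn(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return full

        return self._unary(out, grad_fn)

    # ---- reductions & shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape)

        return self._unary(out, grad_fn)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        return self._unary(self.data.reshape(*shape),
                           lambda g: g.reshape(self.data.shape))

    # ---- nonlinearities --------------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return self._unary(out, lambda g: g * out)

    def log(self):
        return self._unary(np.log(self.data), lambda g: g / self.data)

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out = np.tanh(self.data)
        return self._unary(out, lambda g: g * (1.0 - out**2))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._unary(out, lambda g: g * out * (1.0 - out))

    def relu(self):
        return self._unary(np.maximum(self.data, 0.0),
                           lambda g: g * (self.data > 0))

    def elu(self, alpha: float = 1.0):
        out = np.where(self.data > 0, self.data,
                       alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))
        return self._unary(out, lambda g: g * np.where(self.data > 0, 1.0,
                                                       out + alpha))


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(out, req, tuple(tensors), backward if req else None)


def softmax(logits: Tensor) -> Tensor:
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)

    def grad_fn(g):
        return (g - (g * s).sum(axis=-1, keepdims=True)) * s

    return logits._unary(s, grad_fn)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean sparse categorical cross-entropy over rows of ``logits``."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    n = labels.size
    nll = -np.log(np.clip(s[np.arange(n), labels], 1e-300, None)).mean()

    def grad_fn(g):
        d = s.copy()
        d[np.arange(n), labels] -= 1.0
        return g * d / n

    return logits._unary(np.asarray(nll), grad_fn)
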