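"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This engine exists to power the recurrent cells and classifier heads of the
package: a small set of differentiable operations (affine maps, pointwise
gates, concatenation, embedding lookup, softmax cross-entropy) wired into a
dynamically built computation graph.  Gradients are produced by reverse
traversal in topological order.  The operation set is deliberately closed —
it covers exactly what the model needs — and every gradient is validated
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "concat", "gather_rows", "cross_entropy", "RMSprop"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self._accumulate(np.ones_like(self.data))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def _bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data)
        out._parents = (self, other)

        def _bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data)
        out._parents = (self, other)

        def _bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ other.data.T)
            if other.requires_grad or other._parents:
                other._accumulate(self.data.T @ g)

        out._backward = _bw
        return out

    # -- pointwise nonlinearities -----------------------------------------

    def sigmoid(self):
        y = expit(self.data)
        out = Tensor(y)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def sum(self):
        out = Tensor(self.data.sum())
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(
            np.broadcast_to(g, self.data.shape).copy()
        )
        return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Differentiable concatenation along `axis`."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def gather_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup `table[indices]` with scatter-add backward (embeddings)."""
    indices = np.asarray(indices)
    out = Tensor(table.data[indices])
    out._parents = (table,)

    def _bw(g):
        acc = np.zeros_like(table.data)
        np.add.at(acc, indices, g)
        table._accumulate(acc)

    out._backward = _bw
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of `labels` under softmax(logits).

    `logits` has shape (k, B) — classes along rows, instances along columns —
    and the computation is fused with log-sum-exp for numerical stability.
    """
    labels = np.asarray(labels)
    z = logits.data
    zmax = z.max(axis=0, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=0, keepdims=True))
    log_probs = z - logsumexp
    batch = z.shape[1]
    nll = -log_probs[labels, np.arange(batch)].mean()
    out = Tensor(nll)
    out._parents = (logits,)

    def _bw(g):
        grad = np.exp(log_probs)
        grad[labels, np.arange(batch)] -= 1.0
        logits._accumulate(g * grad / batch)

    out._backward = _bw
    return out


class RMSprop:
    """RMSprop with the usual squared-gradient moving average.

    Smoothing constant 0.9, epsilon 1e-8 — the common library defaults.
    """

    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 rho: float = 0.9, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._cache = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, s in zip(self.params, self._cache):
            if p.grad is None:
                continue
            s *= self.rho
            s += (1.0 - self.rho) * p.grad * p.grad
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
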