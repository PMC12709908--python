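"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Covers exactly the operator set the point-network needs: broadcasted
arithmetic, matmul, ReLU, max/sum/mean reductions, concatenation, row
gathering (with scatter-add backward), reshape/slicing, log-softmax and
smooth-L1.  Tensors form a DAG; ``backward()`` runs a topological sweep
accumulating gradients into every node with ``requires_grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "gather_rows", "stack_list"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))
        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))
        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))
        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))
        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))
        def bwd(g):
            self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))
        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- nonlinearities & reductions ----------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), (self,))
        out._backward = lambda g: self._accum(g * sign)
        return out

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int) -> "Tensor":
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis).squeeze(axis)
        out = Tensor(out_data, (self,))
        def bwd(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(
                full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
            )
            self._accum(full)
        out._backward = bwd
        return out

    def min(self, axis: int) -> "Tensor":
        return -((-self).max(axis))

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], (self,))
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)
        out._backward = bwd
        return out

    # -- softmax / losses ----------------------------------------------------
    def log_softmax(self, axis: int = -1) -> "Tensor":
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        out = Tensor(out_data, (self,))
        def bwd(g):
            soft = np.exp(out_data)
            self._accum(g - soft * g.sum(axis=axis, keepdims=True))
        out._backward = bwd
        return out

    def smooth_l1(self, beta: float = 1.0) -> "Tensor":
        """Elementwise Huber: quadratic inside ``beta``, linear outside."""
        x = self.data
        small = np.abs(x) < beta
        out_data = np.where(small, 0.5 * x**2 / beta, np.abs(x) - 0.5 * beta)
        out = Tensor(out_data, (self,))
        def bwd(g):
            self._accum(g * np.where(small, x / beta, np.sign(x)))
        out._backward = bwd
        return out


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = bwd
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Index axis 0 of ``t`` with an integer array; backward scatter-adds."""
    idx = np.asarray(idx)
    out = Tensor(t.data[idx], (t,))
    def bwd(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        t._accum(full)
    out._backward = bwd
    return out


def stack_list(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))
    def bwd(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))
    out._backward = bwd
    return out
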