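"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's sequence models (recurrent encoders, character convolutions,
attention pooling, CRF objectives) need exact gradients for a few dozen array
primitives and nothing more, so the graph machinery is kept deliberately
small: a :class:`Tensor` records its parents and a closure that routes the
output gradient back to them, and :func:`Tensor.backward` runs a topological
sweep.  All data is float64; determinism is inherited from numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack", "logsumexp", "softmax"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
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
                 parents: tuple = (), backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative topological order (graphs can be deep for long sequences)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            pending = [p for p in node._parents
                       if p.requires_grad and id(p) not in seen]
            if pending:
                stack.append(node)
                stack.extend(pending)
                # mark children first visit by deferring; use a sentinel
                for p in pending:
                    if id(p) in seen:
                        continue
                continue
            seen.add(id(node))
            topo.append(node)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, out_req, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, out_req, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        assert isinstance(other, Tensor)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data @ other.data, out_req, (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bwd
        return out

    # ---------------------------------------------------------- elementwise
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1 - y * y))
        out._backward = bwd
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y * (1 - y))
        out._backward = bwd
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Max along one axis; gradient flows to the first argmax."""
        y = self.data.max(axis=axis, keepdims=True)
        out_data = y if keepdims else y.squeeze(axis)
        out = Tensor(out_data, self.requires_grad, (self,))
        mask = (self.data == y)
        # route gradient only to the first maximal element along the axis
        first = (np.cumsum(mask, axis=axis) == 1) & mask

        def bwd(g):
            if self.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(first * gg)
        out._backward = bwd
        return out

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))
        out._backward = bwd
        return out

    def take(self, idx):
        """Fancy-index gather; `idx` is a tuple of integer index arrays."""
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bwd
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list, axis: int = -1) -> Tensor:
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bwd
    return out


def stack(tensors: list, axis: int = 0) -> Tensor:
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 req, tuple(tensors))

    def bwd(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(p.squeeze(axis))
    out._backward = bwd
    return out


def logsumexp(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp with the softmax gradient."""
    m = x.data.max(axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    s = np.exp(x.data - m).sum(axis=axis, keepdims=True)
    y = m + np.log(s)
    soft = np.exp(x.data - y)
    out_data = y if keepdims else y.squeeze(axis)
    out = Tensor(out_data, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            gg = g if keepdims else np.expand_dims(g, axis)
            x._accum(soft * gg)
    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return (x - logsumexp(x, axis=axis, keepdims=True)).exp()
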