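"""Minimal reverse-mode automatic differentiation over NumPy arrays.

All model training in this package (mean-pooling, convolutional and
recurrent baselines, the attention encoder and its segment-combination
heads) runs on this tape: a :class:`Tensor` wraps a float64 ndarray,
records the operation that produced it, and :meth:`Tensor.backward`
propagates gradients through the recorded graph in reverse topological
order.  The op set is deliberately small — exactly what the models in
this package need — and every op is covered by finite-difference checks
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "tanh",
    "sigmoid",
    "relu",
    "exp",
    "log",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum along axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def _minmax(self, axis, keepdims, fn):
        out_data = fn(self.data, axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            out_k = fn(self.data, axis=axis, keepdims=True)
            mask = (self.data == out_k).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)
            gg = g if keepdims or axis is None else np.expand_dims(g, axis)
            self._accum(mask * gg)

        return self._make(out_data, (self,), backward)

    def max(self, axis=None, keepdims: bool = False):
        return self._minmax(axis, keepdims, np.max)

    def min(self, axis=None, keepdims: bool = False):
        return self._minmax(axis, keepdims, np.min)

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old_shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if not self.requires_grad:
                return
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            # add.at handles repeated integer indices (embedding lookups)
            np.add.at(self.grad, idx, g)

        return self._make(out_data, (self,), backward)

    # -- graph traversal ------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


# ----------------------------------------------------------------------
# elementwise nonlinearities
# ----------------------------------------------------------------------

def tanh(t: Tensor) -> Tensor:
    out_data = np.tanh(t.data)

    def backward(g):
        if t.requires_grad:
            t._accum(g * (1.0 - out_data ** 2))

    return Tensor._make(out_data, (t,), backward)


def sigmoid(t: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-t.data))

    def backward(g):
        if t.requires_grad:
            t._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (t,), backward)


def relu(t: Tensor) -> Tensor:
    out_data = np.maximum(t.data, 0.0)

    def backward(g):
        if t.requires_grad:
            t._accum(g * (t.data > 0.0))

    return Tensor._make(out_data, (t,), backward)


def exp(t: Tensor) -> Tensor:
    out_data = np.exp(t.data)

    def backward(g):
        if t.requires_grad:
            t._accum(g * out_data)

    return Tensor._make(out_data, (t,), backward)


def log(t: Tensor) -> Tensor:
    out_data = np.log(t.data)

    def backward(g):
        if t.requires_grad:
            t._accum(g / t.data)

    return Tensor._make(out_data, (t,), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if t.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            t._accum(out_data * (g - dot))

    return Tensor._make(out_data, (t,), backward)


# ----------------------------------------------------------------------
# joins
# ----------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)
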