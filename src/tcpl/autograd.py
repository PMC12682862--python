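"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set the decoding network needs: broadcasting
arithmetic, (batched) matrix multiplication, shape ops, slicing/padding,
elementwise nonlinearities and axis reductions. Gradients are accumulated by a
topological-order backward sweep over the recorded computation graph.

Everything is float64 and deterministic: the same graph replayed on the same
inputs produces bitwise-identical values and gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ infra

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order via iterative DFS (graphs can be deep)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = np.matmul(a.data, b.data)

        def backward(g):
            if b.data.ndim >= 2:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            else:  # matrix @ vector
                ga = g[..., None] * b.data
            if a.data.ndim >= 2:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            else:
                gb = a.data[..., None] * g
            a._accum(_unbroadcast(ga, a.data.shape))
            b._accum(_unbroadcast(gb, b.data.shape))

        return self._make(out_data, (a, b), backward)

    def pow_const(self, p: float) -> "Tensor":
        a = self

        def backward(g):
            a._accum(g * p * np.power(a.data, p - 1))

        return self._make(np.power(a.data, p), (a,), backward)

    # ----------------------------------------------------------- elementwise

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self) -> "Tensor":
        a = self

        def backward(g):
            a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def sqrt(self) -> "Tensor":
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            a._accum(g * 0.5 / out_data)

        return self._make(out_data, (a,), backward)

    # -------------------------------------------------------------- reductions

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[i] for i in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shape ops

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def backward(g):
            a._accum(g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(np.transpose(g, inv))

        return self._make(np.transpose(a.data, axes), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int) -> "Tensor":
        a = self

        def backward(g):
            a._accum(np.swapaxes(g, ax1, ax2))

        return self._make(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    def __getitem__(self, idx) -> "Tensor":
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accum(full)

        return self._make(a.data[idx], (a,), backward)

    def pad_last(self, left: int, right: int = 0) -> "Tensor":
        """Zero-pad the last axis."""
        a = self
        width = [(0, 0)] * (a.data.ndim - 1) + [(left, right)]

        def backward(g):
            sl = (slice(None),) * (a.data.ndim - 1)
            stop = g.shape[-1] - right if right else None
            a._accum(g[sl + (slice(left, stop),)])

        return self._make(np.pad(a.data, width), (a,), backward)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tuple(tensors), backward)
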