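"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps one
``numpy.ndarray`` and remembers how to push gradients to its parents.
The op set is exactly what the model needs — broadcasting arithmetic,
batched ``matmul``, reductions, the usual activations, a numerically
stable ``softmax`` primitive, ``concat``, reshaping and embedding
lookups. Gradients accumulate in ``Tensor.grad`` (a plain ndarray) after
``backward()`` on a scalar loss.

The engine is dtype-agnostic: it keeps whatever dtype the data carries,
so the same model code runs in float32 for training and float64 for
finite-difference gradient checks.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "embedding_lookup"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # collapse axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to Tensor's reflected operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def as_tensor(x, like: "Tensor | None" = None) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        if like is not None and arr.dtype != like.data.dtype and arr.dtype.kind == "f":
            arr = arr.astype(like.data.dtype)
        return Tensor(arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data: np.ndarray, parents: Iterable["Tensor"], backward) -> "Tensor":
        parents = tuple(parents)
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray, fresh: bool = False) -> None:
        """Accumulate into ``self.grad``.

        ``fresh=True`` promises ``grad`` is a newly allocated array with
        no other live references, so it can be adopted without a copy
        (the dominant cost on large attention tensors otherwise).
        """
        if not self.requires_grad:
            return
        if self.grad is None:
            if fresh and grad.dtype == self.data.dtype:
                self.grad = grad
            else:
                self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other, like=self)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accum(-g, fresh=True)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor.as_tensor(other, like=self))

    def __rsub__(self, other) -> "Tensor":
        return Tensor.as_tensor(other, like=self) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other, like=self)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape), fresh=True)
            other._accum(_unbroadcast(g * self.data, other.data.shape), fresh=True)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other, like=self)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor.as_tensor(other, like=self) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0), fresh=True)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other, like=self)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.outer(g, b) if a.ndim > 1 else g * b
                gb = a.T @ g if a.ndim > 1 else a * g
            elif a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.outer(a, g)
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape), fresh=True)
            other._accum(_unbroadcast(gb, b.shape), fresh=True)

        return self._make(out_data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = np.transpose(self.data, axes)

        def backward(g):
            self._accum(np.transpose(g, inv))

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy(), fresh=True)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy(), fresh=True)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            self._accum(g * mask, fresh=True)

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        pos = self.data > 0
        out_data = np.where(pos, self.data, slope * self.data)

        def backward(g):
            self._accum(g * np.where(pos, 1.0, slope).astype(self.data.dtype), fresh=True)

        return self._make(out_data, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2), fresh=True)

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data), fresh=True)

        return self._make(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data, fresh=True)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data, fresh=True)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1, additive_bias: np.ndarray | None = None) -> "Tensor":
        """Numerically stable softmax along ``axis`` with an exact Jacobian.

        ``additive_bias`` is a constant (non-differentiated) array added to
        the logits before normalization — used for attention masking
        without materializing an extra logits-sized intermediate on the
        tape.
        """
        if additive_bias is None:
            z = self.data - self.data.max(axis=axis, keepdims=True)
        else:
            z = self.data + additive_bias        # fresh buffer
            z -= z.max(axis=axis, keepdims=True)
        out_data = np.exp(z, out=z)
        out_data /= out_data.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot), fresh=True)

        return self._make(out_data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def embedding_lookup(table: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of ``table`` (vocab x dim) at integer ``indices``.

    The backward pass scatter-adds into the table's gradient, so repeated
    ids accumulate correctly.
    """
    idx = np.asarray(indices)
    out_data = table.data[idx]

    out = Tensor(out_data, requires_grad=table.requires_grad)

    def backward(g):
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, idx, g)

    if out.requires_grad:
        out._parents = (table,)
        out._backward = backward
    return out
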