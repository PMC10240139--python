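"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
remembers how it was produced; calling :meth:`Tensor.backward` on a scalar
result walks the graph in reverse topological order and accumulates
gradients into every tensor created with ``requires_grad=True``.  Only the
operations the segmentation network and its losses need are provided.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- introspection ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for big images
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate_grad(self, g: np.ndarray) -> None:
        # grads are never mutated in place, so storing a reference is safe
        self.grad = g if self.grad is None else self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self.accumulate_grad(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other.accumulate_grad(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=back)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def back(g: np.ndarray) -> None:
            self.accumulate_grad(-g)

        return Tensor(-self.data, parents=(self,), backward=back)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self.accumulate_grad(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other.accumulate_grad(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=back)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data / other.data

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self.accumulate_grad(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other.accumulate_grad(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(out_data, parents=(self, other), backward=back)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def back(g: np.ndarray) -> None:
            self.accumulate_grad(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, parents=(self,), backward=back)

    def abs(self) -> "Tensor":
        out_data = np.abs(self.data)

        def back(g: np.ndarray) -> None:
            self.accumulate_grad(g * np.sign(self.data))

        return Tensor(out_data, parents=(self,), backward=back)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g: np.ndarray) -> None:
            if axis is None:
                self.accumulate_grad(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.accumulate_grad(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0)

        def back(g: np.ndarray) -> None:
            self.accumulate_grad(g * (self.data > 0))

        return Tensor(out_data, parents=(self,), backward=back)

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic: exp of a non-positive argument only
        z = np.exp(-np.abs(self.data))
        out_data = np.where(self.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z))

        def back(g: np.ndarray) -> None:
            self.accumulate_grad(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=back)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)

        def back(g: np.ndarray) -> None:
            self.accumulate_grad(g.reshape(self.data.shape))

        return Tensor(out_data, parents=(self,), backward=back)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate_grad(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=back)
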