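"""Reverse-mode automatic differentiation on NumPy arrays.

A small define-by-run tape: every operation returns a new :class:`Tensor`
holding the forward value and a closure that scatters the output gradient
back to its parents.  Gradients are accumulated on any tensor that
``requires_grad``, including intermediate activations (needed for
gradient-weighted class-activation maps).

Everything runs in float64: the models here are deliberately tiny, and the
extra precision makes finite-difference gradient checks and bitwise
determinism contracts unambiguous.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = _backward
        self._parents = tuple(_parents)

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
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

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data / other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = _bw
        return out

    __matmul__ = matmul

    # -- reductions / reshaping ------------------------------------------

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape
        out = Tensor(
            self.data.reshape(shape),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )
        out._backward = lambda g: self._accumulate(g.reshape(src_shape))
        return out

    def take_column(self, indices) -> "Tensor":
        """Select ``self[arange(N), indices]`` from a 2-D tensor."""
        idx = np.asarray(indices)
        rows = np.arange(self.data.shape[0])
        out = Tensor(
            self.data[rows, idx], requires_grad=self.requires_grad, _parents=(self,)
        )

        def _bw(g):
            full = np.zeros_like(self.data)
            full[rows, idx] = g
            self._accumulate(full)

        out._backward = _bw
        return out

    # -- elementwise nonlinearities --------------------------------------

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def square(self) -> "Tensor":
        return self * self

    def sqrt(self) -> "Tensor":
        val = np.sqrt(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / val)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * val)
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only where unclamped."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(
            np.clip(self.data, lo, hi), requires_grad=self.requires_grad, _parents=(self,)
        )
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * factor, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * factor)
        return out

    def softplus(self) -> "Tensor":
        """log(1 + exp(x)), computed overflow-free; gradient is sigmoid(x)."""
        val = np.log1p(np.exp(-np.abs(self.data))) + np.maximum(self.data, 0.0)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out._backward = lambda g: self._accumulate(g * sig)
        return out

    def sigmoid(self) -> "Tensor":
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * val * (1.0 - val))
        return out


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(
        data,
        requires_grad=any(t.requires_grad for t in tensors),
        _parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def stack_rows(arrays: Sequence[np.ndarray]) -> Tensor:
    """Constant tensor from a stack of equally shaped arrays (a data batch)."""
    return Tensor(np.stack([np.asarray(a, dtype=np.float64) for a in arrays]))
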