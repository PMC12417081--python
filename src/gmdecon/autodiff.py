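"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small (a two-layer graph convolutional encoder,
three linear heads, two two-layer perceptrons) and runs on a single CPU, so a
compact tape-based engine is sufficient: every :class:`Tensor` wraps an
ndarray, records its parents and a closure that accumulates gradients into
them, and :meth:`Tensor.backward` walks the tape in reverse topological order.

Only the operations the model and its losses need are provided. Broadcasting
is supported in elementwise ops; gradients of broadcast operands are summed
back to the operand's shape.  The gradient-reversal op (:func:`grl`) is the
identity in the forward pass and multiplies the incoming gradient by ``-alpha``
in the backward pass.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this (typically scalar) tensor through the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: tapes can be deep
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # --------------------------------------------------------------- reshapes
    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x: Union[Tensor, ArrayLike], dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None:
        arr = arr.astype(dtype)
    return Tensor(arr)


def constant(x: ArrayLike, dtype=None) -> Tensor:
    """A tensor that never requires a gradient (tape leaf)."""
    return as_tensor(x, dtype=dtype)


# ------------------------------------------------------------------ operators
def add(a: Union[Tensor, ArrayLike], b: Union[Tensor, ArrayLike]) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Union[Tensor, ArrayLike], b: Union[Tensor, ArrayLike]) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def power(a: Union[Tensor, ArrayLike], p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return Tensor(out_data, parents=(a,), backward=backward)


def matmul(a: Union[Tensor, ArrayLike], b: Union[Tensor, ArrayLike]) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return Tensor(out_data, parents=(a,), backward=backward)


def transpose(a: Tensor, axes=None) -> Tensor:
    a = as_tensor(a)
    out_data = np.transpose(a.data, axes)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            inv = None if axes is None else np.argsort(axes)
            a._accumulate(np.transpose(g, inv))

    return Tensor(out_data, parents=(a,), backward=backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g: np.ndarray) -> None:
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return Tensor(out_data, parents=(a,), backward=backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def exp(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * out_data)

    return Tensor(out_data, parents=(a,), backward=backward)


def log(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g / a.data)

    return Tensor(out_data, parents=(a,), backward=backward)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=backward)


def elu(a: Tensor, alpha: float = 1.0) -> Tensor:
    a = as_tensor(a)
    x = a.data
    neg = alpha * (np.exp(np.minimum(x, 0.0)) - 1.0)
    out_data = np.where(x > 0, x, neg)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * np.where(x > 0, 1.0, neg + alpha))

    return Tensor(out_data, parents=(a,), backward=backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; the gradient is passed through inside [lo, hi] and zeroed outside."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(out_data, parents=(a,), backward=backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

    return Tensor(out_data, parents=(a,), backward=backward)


def grl(a: Tensor, alpha: float = 1.0) -> Tensor:
    """Gradient reversal: identity forward, gradient scaled by -alpha backward."""
    a = as_tensor(a)
    out_data = a.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(-alpha * g)

    return Tensor(out_data, parents=(a,), backward=backward)


def expand_dims(a: Tensor, axis: int) -> Tensor:
    a = as_tensor(a)
    out_data = np.expand_dims(a.data, axis)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(np.squeeze(g, axis=axis))

    return Tensor(out_data, parents=(a,), backward=backward)


# ------------------------------------------------------------------ optimizer
class Adam:
    """Adam with framework-default betas/eps, over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
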