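"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The joint survival-topic objective must be differentiated end to end:
through the survival head, the decoder softmax, the reparameterized
sampling step and the encoder network.  This module provides the small
set of differentiable primitives those losses are built from.  Every
primitive's vector-Jacobian product is exercised against central finite
differences in the test suite.

Design notes
------------
* A :class:`Tensor` wraps a float64 ndarray, its gradient accumulator and
  the closure that propagates an upstream gradient to its parents.
* Graphs are built eagerly and freed after :meth:`Tensor.backward`.
* Broadcasting follows NumPy semantics; gradients are summed back to the
  parent's shape (:func:`_unbroadcast`).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "cumsum",
    "exp",
    "log",
    "sigmoid",
    "softmax",
    "softplus",
    "sqrt",
    "logsumexp",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over broadcast axes so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    value
        The numeric payload, coerced to a float64 ndarray.
    requires_grad
        Whether gradients should be accumulated for this node.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp")

    # make ndarray <op> Tensor defer to the Tensor's reflected operators
    __array_ufunc__ = None
    __array_priority__ = 100

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _vjp: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents)
        self._vjp = _vjp
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every upstream tensor."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        break
                else:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._vjp is not None:
                for parent, pg in zip(node._parents, node._vjp(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.value + other.value,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.value, _parents=(self,), _vjp=lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.value * other.value,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g * other.value, self.shape),
                _unbroadcast(g * self.value, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.value / other.value,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g / other.value, self.shape),
                _unbroadcast(-g * self.value / other.value**2, other.shape),
            ),
        )

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        return Tensor(
            self.value**exponent,
            _parents=(self,),
            _vjp=lambda g: (g * exponent * self.value ** (exponent - 1),),
        )

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        a, b = self.value, other.value

        def vjp(g: np.ndarray):
            if a.ndim == 1 and b.ndim == 1:
                return g * b, g * a
            if a.ndim == 1:  # (d,) @ (d, m) -> (m,)
                return g @ b.T, np.outer(a, g)
            if b.ndim == 1:  # (n, d) @ (d,) -> (n,)
                return np.outer(g, b), a.T @ g
            return g @ b.T, a.T @ g

        return Tensor(a @ b, _parents=(self, other), _vjp=vjp)

    # -- reductions / shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def vjp(g: np.ndarray):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), _parents=(self,), _vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.value.size
        else:
            n = self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        return Tensor(
            self.value.reshape(*shape),
            _parents=(self,),
            _vjp=lambda g: (g.reshape(self.shape),),
        )

    @property
    def T(self) -> "Tensor":
        return Tensor(self.value.T, _parents=(self,), _vjp=lambda g: (g.T,))

    def __getitem__(self, idx) -> "Tensor":
        def vjp(g: np.ndarray):
            out = np.zeros_like(self.value)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(self.value[idx], _parents=(self,), _vjp=vjp)

    def clip_min(self, floor: float) -> "Tensor":
        """Elementwise ``max(x, floor)``; gradient is zero where clipped."""
        mask = self.value >= floor
        return Tensor(
            np.maximum(self.value, floor),
            _parents=(self,),
            _vjp=lambda g: (g * mask,),
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise functions


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.value)
    return Tensor(out, _parents=(x,), _vjp=lambda g: (g * out,))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(np.log(x.value), _parents=(x,), _vjp=lambda g: (g / x.value,))


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.sqrt(x.value)
    return Tensor(out, _parents=(x,), _vjp=lambda g: (g * 0.5 / out,))


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # numerically stable logistic
    out = np.where(x.value >= 0, 1.0 / (1.0 + np.exp(-x.value)),
                   np.exp(x.value) / (1.0 + np.exp(x.value)))
    return Tensor(out, _parents=(x,), _vjp=lambda g: (g * out * (1.0 - out),))


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed without overflow."""
    x = as_tensor(x)
    out = np.maximum(x.value, 0.0) + np.log1p(np.exp(-np.abs(x.value)))
    sig = np.where(x.value >= 0, 1.0 / (1.0 + np.exp(-x.value)),
                   np.exp(x.value) / (1.0 + np.exp(x.value)))
    return Tensor(out, _parents=(x,), _vjp=lambda g: (g * sig,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.value - x.value.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def vjp(g: np.ndarray):
        inner = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - inner),)

    return Tensor(out, _parents=(x,), _vjp=vjp)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    m = x.value.max(axis=axis, keepdims=True)
    e = np.exp(x.value - m)
    s = e.sum(axis=axis, keepdims=True)
    out = m + np.log(s)
    soft = e / s

    def vjp(g: np.ndarray):
        gg = g if keepdims else np.expand_dims(g, axis)
        return (gg * soft,)

    return Tensor(out if keepdims else np.squeeze(out, axis=axis), _parents=(x,), _vjp=vjp)


def cumsum(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)

    def vjp(g: np.ndarray):
        return (np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis),)

    return Tensor(np.cumsum(x.value, axis=axis), _parents=(x,), _vjp=vjp)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g: np.ndarray):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.value for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _vjp=vjp,
    )
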