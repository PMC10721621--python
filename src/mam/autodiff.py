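"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The motor-assessment network is small (a few hundred thousand weights), so a
compact tape-based engine over whole-array operations is sufficient: every
operation builds a node holding its inputs and a closure that maps the output
gradient to input gradients.  Gradients are plain ``numpy`` arrays accumulated
on leaf tensors.  Correctness is established by finite-difference checks in
the test suite.

Only the operations the model needs are implemented; all of them support the
NumPy broadcasting rules (gradients are summed back over broadcast axes).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "affine",
    "concatenate",
    "stack",
    "layer_norm",
    "softmax",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_grad_sink")

    # keep numpy from elementwise-broadcasting over Tensor operands: binary
    # ops with an ndarray on the left must fall back to our reflected ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- backward pass ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("tensor does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        # iterative topological order (graphs can be deep)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                node._grad_sink = grads  # type: ignore[attr-defined]
                try:
                    node._backward(g)
                finally:
                    del node._grad_sink  # type: ignore[attr-defined]
            elif node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            # free graph references as we go
            node._parents = ()
            node._backward = None

    # Backward closures accumulate into the dict owned by the running
    # backward() call via _accum; leaves fall through to .grad there.


def _accum(sink_owner: Tensor, parent: Tensor, g: np.ndarray) -> None:
    grads: dict[int, np.ndarray] = sink_owner._grad_sink  # type: ignore[attr-defined]
    if parent._backward is None and not parent._parents:
        # leaf: accumulate into .grad directly when it terminates the graph
        if parent.requires_grad:
            parent.grad = g.copy() if parent.grad is None else parent.grad + g
        return
    key = id(parent)
    if key in grads:
        grads[key] = grads[key] + g
    else:
        grads[key] = g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _binary(a: Tensor, b: Tensor, data: np.ndarray, da, db) -> Tensor:
    out = Tensor._make(data, (a, b), None)  # type: ignore[arg-type]

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            _accum(out, a, _unbroadcast(da(g), a.data.shape))
        if b.requires_grad:
            _accum(out, b, _unbroadcast(db(g), b.data.shape))

    out._backward = backward if out.requires_grad else None
    return out


def _unary(a: Tensor, data: np.ndarray, da) -> Tensor:
    out = Tensor._make(data, (a,), None)  # type: ignore[arg-type]

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            _accum(out, a, da(g))

    out._backward = backward if out.requires_grad else None
    return out


# -- arithmetic -------------------------------------------------------------

def _add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def _mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data * b.data,
                   lambda g: g * b.data, lambda g: g * a.data)


def _sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def _div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data / b.data,
                   lambda g: g / b.data,
                   lambda g: -g * a.data / (b.data * b.data))


def _swap(x: np.ndarray) -> np.ndarray:
    return np.swapaxes(x, -1, -2)


def _matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = np.matmul(a.data, b.data)

    def da(g):
        ga = np.matmul(g, _swap(b.data))
        return _unbroadcast(ga, a.data.shape)

    def db(g):
        gb = np.matmul(_swap(a.data), g)
        return _unbroadcast(gb, b.data.shape)

    out = Tensor._make(data, (a, b), None)  # type: ignore[arg-type]

    def backward(g):
        if a.requires_grad:
            _accum(out, a, da(g))
        if b.requires_grad:
            _accum(out, b, db(g))

    out._backward = backward if out.requires_grad else None
    return out


Tensor.__add__ = lambda self, o: _add(self, o)
Tensor.__radd__ = lambda self, o: _add(o, self)
Tensor.__sub__ = lambda self, o: _sub(self, o)
Tensor.__rsub__ = lambda self, o: _sub(o, self)
Tensor.__mul__ = lambda self, o: _mul(self, o)
Tensor.__rmul__ = lambda self, o: _mul(o, self)
Tensor.__truediv__ = lambda self, o: _div(self, o)
Tensor.__rtruediv__ = lambda self, o: _div(o, self)
Tensor.__neg__ = lambda self: _mul(self, -1.0)
Tensor.__matmul__ = lambda self, o: _matmul(self, o)


# -- elementwise ------------------------------------------------------------

def _def_unary(name: str, fwd, grad):
    def op(self: Tensor) -> Tensor:
        data = fwd(self.data)
        return _unary(self, data, lambda g, d=data, x=self.data: g * grad(x, d))
    op.__name__ = name
    setattr(Tensor, name, op)


_def_unary("tanh", np.tanh, lambda x, y: 1.0 - y * y)
_def_unary("exp", np.exp, lambda x, y: y)
_def_unary("log", np.log, lambda x, y: 1.0 / x)
_def_unary("sqrt", np.sqrt, lambda x, y: 0.5 / y)
_def_unary("relu", lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(x.dtype))


def _sqrt0(self: Tensor) -> Tensor:
    """Exact square root with subgradient 0 at 0 (for pairwise distances:
    the self-distance stays exactly zero and contributes no gradient)."""
    y = np.sqrt(self.data)
    pos = self.data > 0
    safe = np.where(pos, y, 1.0)
    return _unary(self, y, lambda g: g * np.where(pos, 0.5 / safe, 0.0))


Tensor.sqrt0 = _sqrt0  # type: ignore[attr-defined]


def _square(self: Tensor) -> Tensor:
    return _unary(self, self.data * self.data, lambda g: g * 2.0 * self.data)


Tensor.square = _square  # type: ignore[attr-defined]


def _clip(self: Tensor, lo: float, hi: float) -> Tensor:
    data = np.clip(self.data, lo, hi)
    mask = ((self.data >= lo) & (self.data <= hi)).astype(self.data.dtype)
    return _unary(self, data, lambda g: g * mask)


Tensor.clip = _clip  # type: ignore[attr-defined]


# -- reductions -------------------------------------------------------------

def _sum(self: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = self.data.sum(axis=axis, keepdims=keepdims)

    def da(g):
        if axis is None:
            return np.broadcast_to(g, self.data.shape).copy()
        g2 = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(g2, self.data.shape).copy()

    return _unary(self, data, da)


def _mean(self: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = self.data.size if axis is None else self.data.shape[axis]
    return _sum(self, axis=axis, keepdims=keepdims) * (1.0 / n)


Tensor.sum = _sum  # type: ignore[attr-defined]
Tensor.mean = _mean  # type: ignore[attr-defined]


# -- shape ops --------------------------------------------------------------

def _reshape(self: Tensor, *shape) -> Tensor:
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    orig = self.data.shape
    return _unary(self, self.data.reshape(shape), lambda g: g.reshape(orig))


def _transpose(self: Tensor, *axes) -> Tensor:
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    inv = np.argsort(axes)
    return _unary(self, self.data.transpose(axes), lambda g: g.transpose(inv))


def _getitem(self: Tensor, idx) -> Tensor:
    data = self.data[idx]

    def da(g):
        out = np.zeros_like(self.data)
        np.add.at(out, idx, g)
        return out

    return _unary(self, data, da)


Tensor.reshape = _reshape  # type: ignore[attr-defined]
Tensor.transpose = _transpose  # type: ignore[attr-defined]
Tensor.__getitem__ = _getitem


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor._make(data, tensors, None)  # type: ignore[arg-type]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                _accum(out, t, piece)

    out._backward = backward if out.requires_grad else None
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    expanded = [t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors]
    return concatenate(expanded, axis=axis)


def affine(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fused ``x @ w + b`` for 2-D ``x`` — one output array, one graph node."""
    data = np.matmul(x.data, w.data)
    data += b.data
    out = Tensor._make(data, (x, w, b), None)  # type: ignore[arg-type]

    def backward(g):
        if x.requires_grad:
            _accum(out, x, np.matmul(g, w.data.T))
        if w.requires_grad:
            _accum(out, w, np.matmul(x.data.T, g))
        if b.requires_grad:
            _accum(out, b, g.sum(axis=0))

    out._backward = backward if out.requires_grad else None
    return out


# -- fused numerical primitives ---------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def da(g):
        return (g - (g * y).sum(axis=axis, keepdims=True)) * y

    return _unary(x, y, da)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    data = xhat * gamma.data + beta.data
    out = Tensor._make(data, (x, gamma, beta), None)  # type: ignore[arg-type]

    def backward(g):
        if gamma.requires_grad:
            _accum(out, gamma, _unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            _accum(out, beta, _unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx_hat = g * gamma.data
            m1 = gx_hat.mean(axis=-1, keepdims=True)
            m2 = (gx_hat * xhat).mean(axis=-1, keepdims=True)
            _accum(out, x, inv * (gx_hat - m1 - xhat * m2))

    out._backward = backward if out.requires_grad else None
    return out
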