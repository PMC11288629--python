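"""Minimal reverse-mode automatic differentiation over numpy arrays.

The whole simulation stack (skeleton dynamics, muscle geometry, muscle
force production, environment bookkeeping and the recurrent policy) is
written against this module so that gradients can be propagated through
an entire rollout — through time *and* through the physics — with plain
numpy as the only numerical dependency.

Design notes
------------
* A :class:`Tensor` wraps a float64 ``ndarray`` plus a closure that knows
  how to push an incoming cotangent to its parents.  Graphs are built
  eagerly; :meth:`Tensor.backward` runs a single reverse topological pass.
* Broadcasting follows numpy semantics; cotangents are summed back over
  broadcast axes (:func:`_unbroadcast`).
* Every dispatching helper (:func:`tanh`, :func:`where`, ...) accepts
  either a :class:`Tensor` or anything ``np.asarray`` accepts, and only
  builds graph nodes when at least one argument is a :class:`Tensor`.
  This lets the same physics code run tape-free for plain numpy inputs.
* Non-smooth primitives (``clip``, ``abs``, ``maximum``) use one-sided
  subgradients, which is all gradient training requires.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "data_of",
    "is_tensor",
    "abs",
    "clip",
    "concatenate",
    "cos",
    "exp",
    "log",
    "matmul",
    "maximum",
    "mean",
    "minimum",
    "sigmoid",
    "sin",
    "sqrt",
    "stack",
    "sum",
    "tanh",
    "where",
]

_np_abs = np.abs
_np_sum = np.sum


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node of the reverse-mode graph holding a float64 array."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    # make ndarray <op> Tensor dispatch to our reflected operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        if not requires_grad:
            for p in _parents:
                if p.requires_grad:
                    requires_grad = True
                    break
        self.requires_grad = requires_grad
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def copy(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=self.requires_grad,
                      _parents=(self,), _backward=None if not self.requires_grad
                      else (lambda g, s=self: s._accumulate(g)))

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- reverse pass --------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse accumulation from this node.

        ``grad`` defaults to ones (scalar outputs are the common case).
        """
        if not self.requires_grad:
            raise RuntimeError("called backward() on a non-differentiable tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        seed = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        self._accumulate(seed)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g)
            if b.requires_grad:
                b._accumulate(g)

        return Tensor(self.data + other.data, _parents=(self, other), _backward=backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g)
            if b.requires_grad:
                b._accumulate(-g)

        return Tensor(self.data - other.data, _parents=(self, other), _backward=backward)

    def __rsub__(self, other):
        return as_tensor(other).__sub__(self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g * b.data)
            if b.requires_grad:
                b._accumulate(g * a.data)

        return Tensor(self.data * other.data, _parents=(self, other), _backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g / b.data)
            if b.requires_grad:
                b._accumulate(-g * a.data / (b.data * b.data))

        return Tensor(self.data / other.data, _parents=(self, other), _backward=backward)

    def __rtruediv__(self, other):
        return as_tensor(other).__truediv__(self)

    def __neg__(self):
        def backward(g, a=self):
            a._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=backward)

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g, a=self, p=float(exponent)):
            a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor(self.data ** exponent, _parents=(self,), _backward=backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                if b.data.ndim == 1:
                    a._accumulate(np.outer(g, b.data) if a.data.ndim == 2 else g * b.data)
                else:
                    a._accumulate(g @ b.data.swapaxes(-1, -2))
            if b.requires_grad:
                if a.data.ndim == 1:
                    b._accumulate(np.outer(a.data, g) if b.data.ndim == 2 else g * a.data)
                else:
                    b._accumulate(a.data.swapaxes(-1, -2) @ g)

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=backward)

    def __rmatmul__(self, other):
        return as_tensor(other).__matmul__(self)

    def __getitem__(self, key):
        fancy = any(isinstance(k, (np.ndarray, list)) for k in
                    (key if isinstance(key, tuple) else (key,)))

        def backward(g, a=self, k=key, f=fancy):
            full = np.zeros_like(a.data)
            if f:
                np.add.at(full, k, g)  # duplicate indices must accumulate
            else:
                full[k] += g
            a._accumulate(full)

        return Tensor(self.data[key], _parents=(self,), _backward=backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, a=self):
            a._accumulate(g.reshape(a.data.shape))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=backward)

    def sum(self, axis=None, keepdims: bool = False):
        return sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        return mean(self, axis=axis, keepdims=keepdims)

    # comparisons operate on raw data and return plain boolean arrays
    def __lt__(self, other):
        return self.data < data_of(other)

    def __le__(self, other):
        return self.data <= data_of(other)

    def __gt__(self, other):
        return self.data > data_of(other)

    def __ge__(self, other):
        return self.data >= data_of(other)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def data_of(x) -> np.ndarray:
    """Raw ndarray view of a Tensor or array-like."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def parameter(data, requires_grad: bool = True) -> Tensor:
    """A leaf tensor meant to be optimized."""
    return Tensor(np.array(data, dtype=np.float64), requires_grad=requires_grad)


# ---------------------------------------------------------------------------
# dispatching elementwise / reduction helpers
# ---------------------------------------------------------------------------

def _unary(x, fn, dfn):
    if not isinstance(x, Tensor):
        return fn(np.asarray(x, dtype=np.float64))
    out = fn(x.data)

    def backward(g, a=x, o=out):
        a._accumulate(g * dfn(a.data, o))

    return Tensor(out, _parents=(x,), _backward=backward)


def tanh(x):
    return _unary(x, np.tanh, lambda d, o: 1.0 - o * o)


def sigmoid(x):
    def fn(d):
        return 1.0 / (1.0 + np.exp(-d))

    return _unary(x, fn, lambda d, o: o * (1.0 - o))


def exp(x):
    return _unary(x, np.exp, lambda d, o: o)


def log(x):
    return _unary(x, np.log, lambda d, o: 1.0 / d)


def sqrt(x):
    return _unary(x, np.sqrt, lambda d, o: 0.5 / o)


def sin(x):
    return _unary(x, np.sin, lambda d, o: np.cos(d))


def cos(x):
    return _unary(x, np.cos, lambda d, o: -np.sin(d))


def abs(x):  # noqa: A001 - mirrors numpy's name on purpose
    return _unary(x, _np_abs, lambda d, o: np.sign(d))


def clip(x, lo, hi):
    """Clamp with zero gradient outside [lo, hi] (subgradient convention)."""
    lo = None if lo is None else data_of(lo)
    hi = None if hi is None else data_of(hi)
    if not isinstance(x, Tensor):
        return np.clip(np.asarray(x, dtype=np.float64), lo, hi)
    out = np.clip(x.data, lo, hi)
    inside = np.ones_like(x.data, dtype=bool)
    if lo is not None:
        inside &= x.data >= lo
    if hi is not None:
        inside &= x.data <= hi

    def backward(g, a=x, m=inside):
        a._accumulate(g * m)

    return Tensor(out, _parents=(x,), _backward=backward)


def maximum(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.maximum(data_of(a), data_of(b))
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data >= b.data

    def backward(g, x=a, y=b, m=mask):
        if x.requires_grad:
            x._accumulate(g * m)
        if y.requires_grad:
            y._accumulate(g * ~m)

    return Tensor(np.maximum(a.data, b.data), _parents=(a, b), _backward=backward)


def minimum(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.minimum(data_of(a), data_of(b))
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data <= b.data

    def backward(g, x=a, y=b, m=mask):
        if x.requires_grad:
            x._accumulate(g * m)
        if y.requires_grad:
            y._accumulate(g * ~m)

    return Tensor(np.minimum(a.data, b.data), _parents=(a, b), _backward=backward)


def where(cond, a, b):
    """Select ``a`` where ``cond`` else ``b``; ``cond`` is a plain mask."""
    cond = np.asarray(data_of(cond), dtype=bool)
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.where(cond, data_of(a), data_of(b))
    a, b = as_tensor(a), as_tensor(b)

    def backward(g, x=a, y=b, m=cond):
        if x.requires_grad:
            x._accumulate(np.where(m, g, 0.0))
        if y.requires_grad:
            y._accumulate(np.where(m, 0.0, g))

    return Tensor(np.where(cond, a.data, b.data), _parents=(a, b), _backward=backward)


def sum(x, axis=None, keepdims: bool = False):  # noqa: A001
    if not isinstance(x, Tensor):
        return _np_sum(np.asarray(x, dtype=np.float64), axis=axis, keepdims=keepdims)
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g, a=x, ax=axis, kd=keepdims):
        if ax is not None and not kd:
            g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return Tensor(out, _parents=(x,), _backward=backward)


def mean(x, axis=None, keepdims: bool = False):
    if not isinstance(x, Tensor):
        return np.mean(np.asarray(x, dtype=np.float64), axis=axis, keepdims=keepdims)
    n = x.data.size if axis is None else np.prod([x.data.shape[a] for a in np.atleast_1d(axis)])
    return sum(x, axis=axis, keepdims=keepdims) / float(n)


def matmul(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        return as_tensor(a) @ as_tensor(b)
    return data_of(a) @ data_of(b)


def concatenate(parts: Sequence, axis: int = -1):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate([data_of(p) for p in parts], axis=axis)
    parts = [as_tensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    out = np.concatenate([p.data for p in parts], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g, ps=parts, offs=offsets, ax=axis):
        for p, lo, hi in zip(ps, offs[:-1], offs[1:]):
            if p.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[ax] = slice(lo, hi)
                p._accumulate(g[tuple(idx)])

    return Tensor(out, _parents=tuple(parts), _backward=backward)


def stack(parts: Sequence, axis: int = 0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.stack([data_of(p) for p in parts], axis=axis)
    parts = [as_tensor(p) for p in parts]
    out = np.stack([p.data for p in parts], axis=axis)

    def backward(g, ps=parts, ax=axis):
        slabs = np.moveaxis(g, ax, 0)
        for p, slab in zip(ps, slabs):
            if p.requires_grad:
                p._accumulate(slab)

    return Tensor(out, _parents=tuple(parts), _backward=backward)


def norm2(x, axis=-1, keepdims: bool = False, eps: float = 0.0):
    """Euclidean norm along ``axis`` (optionally stabilized by ``eps``)."""
    s = sum(x * x, axis=axis, keepdims=keepdims)
    return sqrt(s + eps) if eps else sqrt(s)
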