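"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine exists so that forces can be obtained as exact negative gradients
of the predicted energy, and so that training on forces (which differentiates
the force error with respect to the weights) can take a second derivative
through the first one.  To make that possible every primitive's backward pass
is itself expressed in terms of engine ops: calling :func:`grad` with
``create_graph=True`` produces gradient tensors that carry their own graph and
can be differentiated again, to any order.

Only the operations the potential-energy models need are implemented.  All
data lives in numpy arrays (float64 by default, float32 supported); there is
no device abstraction.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "constant",
    "grad",
    "no_grad",
    "add",
    "mul",
    "matmul",
    "concatenate",
    "take",
    "index_add",
    "where_mask",
    "safe_div",
]

_grad_enabled: bool = True
_default_dtype = np.float64


def set_default_dtype(dtype) -> None:
    """Working float type for constants and integer promotions (32/64-bit)."""
    global _default_dtype
    dtype = np.dtype(dtype)
    if dtype not in (np.float32, np.float64):
        raise ValueError("default dtype must be float32 or float64")
    _default_dtype = dtype


def get_default_dtype():
    return _default_dtype


@contextlib.contextmanager
def no_grad():
    """Context in which no computation graph is recorded."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily switch the working float type (precision 32/64 modes)."""
    global _default_dtype
    prev = _default_dtype
    set_default_dtype(dtype)
    try:
        yield
    finally:
        _default_dtype = prev


@contextlib.contextmanager
def _set_grad_enabled(mode: bool):
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = mode
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A numpy array plus an optional backward graph node.

    ``_parents`` holds the tensors this one was computed from and
    ``_backward`` maps the incoming gradient to one gradient (or ``None``)
    per parent.  Leaf tensors have neither.
    """

    __slots__ = ("data", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=_promote_dtype(data))
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable | None = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.shape}{flag})\n{self.data!r}"

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor) or isinstance(other, np.ndarray):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / float(other))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes=None):
        return transpose(self, axes)

    def swapaxes(self, a, b):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return transpose(self, tuple(axes))


class Parameter(Tensor):
    """A leaf tensor that is trainable by default."""

    __slots__ = ()

    def __init__(self, data, requires_grad: bool = True):
        arr = np.array(data, copy=True)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        super().__init__(arr, requires_grad)


def _promote_dtype(data):
    dt = np.asarray(data).dtype
    if dt in (np.float32, np.float64):
        return dt
    return _default_dtype


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    """A tensor that never requires gradients (fixed masks, weights tables)."""
    t = Tensor(x, requires_grad=False)
    if t.data.dtype != _default_dtype:
        t.data = t.data.astype(_default_dtype)
    return t


def _is_scalar(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward: Callable) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    # python scalars stay scalars: keeps float32 graphs float32 and skips a node
    if _is_scalar(b) or _is_scalar(a):
        if _is_scalar(a):
            a, b = b, a
        a = as_tensor(a)
        s = float(b)

        def backward_s(g: Tensor):
            return (g,)

        return _make(a.data + s, (a,), backward_s)
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g: Tensor):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    if _is_scalar(b) or _is_scalar(a):
        if _is_scalar(a):
            a, b = b, a
        a = as_tensor(a)
        s = float(b)

        def backward_s(g: Tensor):
            return (mul(g, s),)

        return _make(a.data * s, (a,), backward_s)
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g: Tensor):
        ga = _unbroadcast(mul(g, b), a.shape) if a.requires_grad else None
        gb = _unbroadcast(mul(g, a), b.shape) if b.requires_grad else None
        return ga, gb

    return _make(data, (a, b), backward)


def power(a, exponent) -> Tensor:
    """Elementwise power with a constant (python scalar) exponent."""
    a = as_tensor(a)
    p = float(exponent)
    data = a.data**p

    def backward(g: Tensor):
        return (mul(g, mul(power(a, p - 1.0), p)),)

    return _make(data, (a,), backward)


def safe_div(a, b) -> Tensor:
    """a / b with the convention 0 where b == 0.

    Used for unit vectors of zero-length edges; differentiable to all orders
    away from b == 0 and defined-zero on it.
    """
    a, b = as_tensor(a), as_tensor(b)
    mask = b.data != 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        data = np.where(mask, a.data / np.where(mask, b.data, 1.0), 0.0)

    def backward(g: Tensor):
        ga = _unbroadcast(safe_div(g, b), a.shape) if a.requires_grad else None
        gb = None
        if b.requires_grad:
            gb = _unbroadcast(mul(safe_div(mul(g, a), mul(b, b)), -1.0), b.shape)
        return ga, gb

    return _make(data, (a, b), backward)


def texp(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.exp(a.data), (a,), None)
    if out.requires_grad:
        # the backward reuses the output tensor, so d(exp)/da = exp(a) keeps
        # its own graph and second derivatives come for free
        def backward(g: Tensor):
            return (mul(g, out),)

        out._backward = backward
    return out


def tlog(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g: Tensor):
        return (mul(g, power(a, -1.0)),)

    return _make(data, (a,), backward)


def tsin(a) -> Tensor:
    a = as_tensor(a)

    def backward(g: Tensor):
        return (mul(g, tcos(a)),)

    return _make(np.sin(a.data), (a,), backward)


def tcos(a) -> Tensor:
    a = as_tensor(a)

    def backward(g: Tensor):
        return (mul(g, mul(tsin(a), -1.0)),)

    return _make(np.cos(a.data), (a,), backward)


def tsqrt(a) -> Tensor:
    """Square root with a defined-zero derivative at 0 (see safe_div)."""
    a = as_tensor(a)
    data = np.sqrt(np.maximum(a.data, 0.0))
    out = _make(data, (a,), None)
    if out.requires_grad:

        def backward(g: Tensor):
            return (safe_div(mul(g, 0.5), out),)

        out._backward = backward
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(data, (a,), None)
    if out.requires_grad:

        def backward(g: Tensor):
            return (mul(g, mul(out, add(constant(1.0), mul(out, -1.0)))),)

        out._backward = backward
    return out


def silu(a) -> Tensor:
    """x * sigmoid(x), the smooth activation used throughout the models."""
    a = as_tensor(a)
    return mul(a, sigmoid(a))


def tanh(a) -> Tensor:
    a = as_tensor(a)
    data = np.tanh(a.data)
    out = _make(data, (a,), None)
    if out.requires_grad:

        def backward(g: Tensor):
            return (mul(g, add(constant(1.0), mul(mul(out, out), -1.0))),)

        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# shape / reduction primitives
# ---------------------------------------------------------------------------


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g: Tensor):
        gd = g
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            shape = list(g.shape)
            for ax in sorted(ax % a.ndim for ax in axes):
                shape.insert(ax, 1)
            gd = reshape(g, tuple(shape))
        elif axis is None and not keepdims:
            gd = reshape(g, (1,) * a.ndim)
        return (broadcast_to(gd, a.shape),)

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    if a.shape == shape:
        return a
    data = np.broadcast_to(a.data, shape).copy()

    def backward(g: Tensor):
        return (_unbroadcast(g, a.shape),)

    return _make(data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    data = a.data.reshape(shape)

    def backward(g: Tensor):
        return (reshape(g, a.shape),)

    return _make(data, (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    data = np.transpose(a.data, axes)
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))

    def backward(g: Tensor):
        return (transpose(g, inv),)

    return _make(data, (a,), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Tensor):
        grads = []
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(lo), int(hi))
            grads.append(getitem(g, tuple(sl)))
        return tuple(grads)

    return _make(data, ts, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    expanded = [reshape(t, t.shape[:axis] + (1,) + t.shape[axis:]) for t in ts]
    return concatenate(expanded, axis=axis)


def getitem(a, key) -> Tensor:
    a = as_tensor(a)
    data = a.data[key]

    def backward(g: Tensor):
        return (_scatter_slice(g, a.shape, key),)

    return _make(data, (a,), backward)


def _scatter_slice(g: Tensor, shape, key) -> Tensor:
    """Inverse of a basic-slice __getitem__: place g into zeros of ``shape``."""
    g = as_tensor(g)
    out = np.zeros(shape, dtype=g.dtype)
    np.add.at(out, key, g.data)

    def backward(gg: Tensor):
        return (getitem(gg, key),)

    return _make(out, (g,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g: Tensor):
        ga = gb = None
        if a.requires_grad:
            ga = matmul(g, _swap_last(b))
            ga = _unbroadcast_batched(ga, a.shape)
        if b.requires_grad:
            gb = matmul(_swap_last(a), g)
            gb = _unbroadcast_batched(gb, b.shape)
        return ga, gb

    return _make(data, (a, b), backward)


def _swap_last(t: Tensor) -> Tensor:
    return t.swapaxes(-1, -2)


def _unbroadcast_batched(g: Tensor, shape) -> Tensor:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(
        i for i in range(max(0, g.ndim - 2)) if shape[i] == 1 and g.shape[i] != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# gather / scatter — the message-passing workhorses
# ---------------------------------------------------------------------------


def take(a, index: np.ndarray) -> Tensor:
    """Gather rows along axis 0 with an integer index array."""
    a = as_tensor(a)
    index = np.asarray(index, dtype=np.int64)
    data = a.data[index]
    n = a.shape[0]

    def backward(g: Tensor):
        return (index_add(g, index, n),)

    return _make(data, (a,), backward)


def index_add(source, index: np.ndarray, n: int) -> Tensor:
    """Scatter-add ``source`` rows into ``n`` output rows (axis 0).

    Uses ``np.add.at``, which accumulates sequentially in index order, giving
    the fixed summation order the padding/ghost-atom contract relies on.
    """
    source = as_tensor(source)
    index = np.asarray(index, dtype=np.int64)
    out = np.zeros((n,) + source.shape[1:], dtype=source.dtype)
    np.add.at(out, index, source.data)

    def backward(g: Tensor):
        return (take(g, index),)

    return _make(out, (source,), backward)


def where_mask(mask: np.ndarray, a, b) -> Tensor:
    """Select with a *constant* boolean mask (not differentiated through)."""
    mask = np.asarray(mask, dtype=bool)
    a, b = as_tensor(a), as_tensor(b)
    data = np.where(mask, a.data, b.data)

    def backward(g: Tensor):
        ga = gb = None
        if a.requires_grad:
            ga = _unbroadcast(mul(g, constant(mask.astype(g.dtype))), a.shape)
        if b.requires_grad:
            gb = _unbroadcast(mul(g, constant((~mask).astype(g.dtype))), b.shape)
        return ga, gb

    return _make(data, (a, b), backward)


# ---------------------------------------------------------------------------
# the engine: reverse-mode sweep
# ---------------------------------------------------------------------------


def _toposort(roots: Sequence[Tensor]) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(r, False) for r in roots]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(
    output: Tensor,
    inputs: Sequence[Tensor] | Tensor,
    grad_output: Tensor | None = None,
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of a scalar (or seeded) output with respect to ``inputs``.

    With ``create_graph=True`` the returned gradients carry their own graph
    and can be differentiated again (forces inside a training loss).
    Inputs that do not influence the output receive zero gradients.
    """
    single = isinstance(inputs, Tensor)
    inputs_list = [inputs] if single else list(inputs)
    if grad_output is None:
        if output.size != 1:
            raise ValueError("grad of a non-scalar output needs grad_output")
        grad_output = constant(np.ones_like(output.data))

    order = _toposort([output])
    grads: dict[int, Tensor] = {id(output): as_tensor(grad_output)}
    with _set_grad_enabled(create_graph):
        for node in reversed(order):
            g = grads.get(id(node))
            if g is None or node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                acc = grads.get(id(p))
                grads[id(p)] = pg if acc is None else add(acc, pg)
        result = []
        for t in inputs_list:
            g = grads.get(id(t))
            if g is None:
                g = constant(np.zeros_like(t.data))
            result.append(g)
    return result
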