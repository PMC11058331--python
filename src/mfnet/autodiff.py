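"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports higher-order gradients: every vector-Jacobian product is itself
built from :class:`Tensor` operations, so ``grad(..., create_graph=True)``
yields gradients that can be differentiated again.  Only the operations
needed for a small convolutional segmentation network are provided.

All data is float64; this trades speed for the tight numeric tolerances
used throughout the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "add",
    "mul",
    "matmul",
    "reshape",
    "transpose",
    "tsum",
    "tmean",
    "broadcast_to",
    "take",
    "scatter_add",
    "concat",
    "exp",
    "log",
    "sigmoid",
    "relu",
    "pad2d",
    "numeric_grad",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff.

    Parameters are created with ``requires_grad=True``; results of
    operations record their parents together with a vector-Jacobian
    product (vjp) closure per parent.
    """

    __slots__ = ("data", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self._parents = _parents  # tuple of (Tensor, vjp) pairs

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    def __radd__(self, other):
        return add(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    def __rmul__(self, other):
        return mul(as_tensor(other), self)

    def __neg__(self):
        return mul(self, as_tensor(-1.0))

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return mul(self, power(as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence) -> Tensor:
    live = tuple((p, f) for p, f in parents if p.requires_grad)
    return Tensor(data, requires_grad=bool(live), _parents=live)


# ---------------------------------------------------------------------------
# broadcasting helper (differentiable: built from tsum/reshape)
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(
        i for i, (a, b) in enumerate(zip(g.shape, shape)) if b == 1 and a != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = _node(
        a.data + b.data,
        [
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(g, b.shape)),
        ],
    )
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _node(
        a.data * b.data,
        [
            (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
            (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
        ],
    )


def power(a: Tensor, p: float) -> Tensor:
    p = float(p)
    return _node(
        a.data**p,
        [(a, lambda g: mul(g, mul(as_tensor(p), power(a, p - 1.0))))],
    )


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)
    out = _node(data, [])
    out._parents = ((a, lambda g: mul(g, out)),) if a.requires_grad else ()
    out.requires_grad = a.requires_grad
    return out


def log(a: Tensor) -> Tensor:
    return _node(np.log(a.data), [(a, lambda g: mul(g, power(a, -1.0)))])


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-a.data))
    out = _node(data, [])
    if a.requires_grad:
        out._parents = ((a, lambda g: mul(g, mul(out, 1.0 - out))),)
        out.requires_grad = True
    return out


def relu(a: Tensor) -> Tensor:
    mask = Tensor((a.data > 0).astype(np.float64))
    return _node(a.data * mask.data, [(a, lambda g: mul(g, mask))])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    # both operands must be >= 2-D; leading dims broadcast like np.matmul
    def _swap(t: Tensor) -> Tensor:
        axes = list(range(t.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return transpose(t, tuple(axes))

    return _node(
        np.matmul(a.data, b.data),
        [
            (a, lambda g: _unbroadcast(matmul(g, _swap(b)), a.shape)),
            (b, lambda g: _unbroadcast(matmul(_swap(a), g), b.shape)),
        ],
    )


def reshape(a: Tensor, shape: tuple) -> Tensor:
    return _node(a.data.reshape(shape), [(a, lambda g: reshape(g, a.shape))])


def transpose(a: Tensor, axes: tuple) -> Tensor:
    inv = tuple(np.argsort(axes))
    return _node(
        np.transpose(a.data, axes), [(a, lambda g: transpose(g, inv))]
    )


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    return _node(
        np.broadcast_to(a.data, shape).copy(),
        [(a, lambda g: _unbroadcast(g, a.shape))],
    )


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    if axis is None:
        kept = (1,) * a.ndim
    else:
        ax = (axis,) if isinstance(axis, int) else tuple(axis)
        ax = tuple(x % a.ndim for x in ax)
        kept = tuple(1 if i in ax else s for i, s in enumerate(a.shape))

    def vjp(g: Tensor) -> Tensor:
        return broadcast_to(reshape(g, kept), a.shape)

    return _node(data, [(a, vjp)])


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    s = tsum(a, axis=axis, keepdims=keepdims)
    return mul(s, as_tensor(s.size / a.size if a.size else 1.0))


def take(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather ``a.ravel()[idx]``; the vjp is a scatter-add back into ``a``."""
    idx = np.asarray(idx)
    size = a.size

    def vjp(g: Tensor) -> Tensor:
        return reshape(scatter_add(g, idx, size), a.shape)

    return _node(a.data.ravel()[idx], [(a, vjp)])


def scatter_add(a: Tensor, idx: np.ndarray, size: int) -> Tensor:
    """Scatter ``a`` into a flat zero vector of length ``size`` at ``idx``.

    ``idx.shape`` must equal ``a.shape``; duplicate indices accumulate.
    """
    idx = np.asarray(idx)
    if idx.shape != a.shape:
        raise ValueError("scatter_add: idx shape must match input shape")
    data = np.bincount(
        idx.ravel(), weights=a.data.ravel(), minlength=size
    ).astype(np.float64)
    return _node(data, [(a, lambda g: reshape(take(g, idx), a.shape))])


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    flat = np.arange(out_data.size).reshape(out_data.shape)
    parents = []
    start = 0
    for t in tensors:
        sl = [slice(None)] * out_data.ndim
        sl[axis] = slice(start, start + t.shape[axis])
        idx = flat[tuple(sl)]
        parents.append((t, lambda g, idx=idx: take(g, idx)))
        start += t.shape[axis]
    return _node(out_data, parents)


# index caches keyed by geometry so repeated conv/pad calls reuse arrays
_PAD_IDX_CACHE: dict = {}


def pad2d(a: Tensor, pad: int) -> Tensor:
    """Zero-pad the last two axes of an N-D tensor by ``pad`` on each side."""
    if pad == 0:
        return a
    key = (a.shape, pad)
    cached = _PAD_IDX_CACHE.get(key)
    if cached is None:
        out_shape = a.shape[:-2] + (
            a.shape[-2] + 2 * pad,
            a.shape[-1] + 2 * pad,
        )
        flat = np.arange(int(np.prod(out_shape))).reshape(out_shape)
        sl = [slice(None)] * (a.ndim - 2) + [slice(pad, -pad), slice(pad, -pad)]
        cached = (flat[tuple(sl)], out_shape)
        _PAD_IDX_CACHE[key] = cached
    idx, out_shape = cached
    return reshape(scatter_add(a, idx, int(np.prod(out_shape))), out_shape)


# ---------------------------------------------------------------------------
# reverse pass
# ---------------------------------------------------------------------------

def grad(
    output: Tensor,
    inputs: Iterable[Tensor],
    create_graph: bool = False,
) -> list:
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned gradients carry their own
    computation graph and can be differentiated again.
    """
    inputs = list(inputs)
    if output.size != 1:
        raise ValueError("grad: output must be a scalar tensor")

    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))

    input_ids = {id(t) for t in inputs}
    grads: dict[int, Tensor] = {
        id(output): Tensor(np.ones(output.shape))
    }
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        for parent, vjp in node._parents:
            pg = vjp(g)
            if not create_graph:
                pg = pg.detach()
            acc = grads.get(id(parent))
            grads[id(parent)] = pg if acc is None else add(acc, pg)
        if id(node) in input_ids:
            grads[id(node)] = g

    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros(t.shape))
        out.append(g)
    return out


def numeric_grad(fn: Callable[[np.ndarray], float], x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function, for gradient checks."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
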