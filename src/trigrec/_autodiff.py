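"""Minimal reverse-mode automatic differentiation over numpy arrays.

The tagger's computation graphs are small (one sentence at a time), so a
scalar-free, array-valued tape is sufficient.  Only the operations the
network needs are provided: affine maps, elementwise nonlinearities,
concatenation/slicing, embedding-row gathers and dropout.  The CRF loss is a
single custom node (see :mod:`trigrec.network`) whose backward pass uses the
analytic forward-backward marginals.

All arithmetic is float64: downstream equivalence checks compare against
enumeration oracles at 1e-8 .. 1e-10 tolerances.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "matmul",
    "add",
    "mul",
    "sigmoid",
    "tanh",
    "relu",
    "concat",
    "narrow",
    "rows",
    "vstack",
    "dropout",
    "backward",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad=False, parents=(), bwd=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._bwd = bwd

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # Small operator sugar; the layer code mostly calls the functions below.
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def constant(data):
    return Tensor(data, requires_grad=False)


def parameter(data):
    return Tensor(data, requires_grad=True)


def _track(*parents):
    return any(p.requires_grad for p in parents)


def _accum(t: Tensor, g):
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g, shape):
    """Sum `g` down to `shape` to undo numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _track(a, b), (a, b))

    def bwd(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g, a.data.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g, b.data.shape))

    out._bwd = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, _track(a, b), (a, b))

    def bwd(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g * a.data, b.data.shape))

    out._bwd = bwd
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _track(a, b), (a, b))

    def bwd(g):
        if a.requires_grad:
            if b.data.ndim == 1:
                _accum(a, np.outer(g, b.data) if a.data.ndim > 1 else g * b.data)
            else:
                _accum(a, np.atleast_2d(g) @ b.data.T if a.data.ndim > 1 else (g @ b.data.T))
        if b.requires_grad:
            if a.data.ndim == 1:
                _accum(b, np.outer(a.data, g) if b.data.ndim > 1 else g * a.data)
            else:
                _accum(b, a.data.T @ np.atleast_2d(g) if b.data.ndim > 1 else a.data.T @ g)

    out._bwd = bwd
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, a.requires_grad, (a,))

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * s * (1.0 - s))

    out._bwd = bwd
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, a.requires_grad, (a,))

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * (1.0 - t * t))

    out._bwd = bwd
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, a.requires_grad, (a,))

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * mask)

    out._bwd = bwd
    return out


def concat(parts: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis),
                 _track(*parts), tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                _accum(p, g[tuple(idx)])

    out._bwd = bwd
    return out


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice `length` entries along `axis` starting at `start`."""
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out = Tensor(a.data[idx], a.requires_grad, (a,))

    def bwd(g):
        if a.requires_grad:
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
            a.grad[idx] += g

    out._bwd = bwd
    return out


def rows(table: Tensor, indices) -> Tensor:
    """Gather rows of an embedding table; backward scatter-adds."""
    indices = np.asarray(indices, dtype=np.intp)
    out = Tensor(table.data[indices], table.requires_grad, (table,))

    def bwd(g):
        if table.requires_grad:
            if table.grad is None:
                table.grad = np.zeros_like(table.data)
            np.add.at(table.grad, indices, g)

    out._bwd = bwd
    return out


def vstack(parts: list[Tensor]) -> Tensor:
    """Stack 1-D (or row) tensors into a (n, d) matrix."""
    out = Tensor(np.stack([np.ravel(p.data) for p in parts]), _track(*parts), tuple(parts))

    def bwd(g):
        for i, p in enumerate(parts):
            if p.requires_grad:
                _accum(p, g[i].reshape(p.data.shape))

    out._bwd = bwd
    return out


def dropout(a: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (inference) or p == 0."""
    if rng is None or p <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= p) / (1.0 - p)
    out = Tensor(a.data * mask, a.requires_grad, (a,))

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * mask)

    out._bwd = bwd
    return out


def backward(loss: Tensor, grad=None):
    """Run reverse-mode accumulation from `loss` through the graph."""
    topo: list[Tensor] = []
    seen = set()
    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not (node.requires_grad or node._parents):
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    loss.grad = np.ones_like(loss.data) if grad is None else np.asarray(grad, dtype=np.float64)
    for node in reversed(topo):
        if node._bwd is not None and node.grad is not None:
            node._bwd(node.grad)
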