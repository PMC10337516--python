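"""Minimal reverse-mode automatic differentiation on numpy arrays.

The adversarial trainer needs gradients of a gradient: the Wasserstein
gradient penalty is a function of ``d s(x)/d x`` and is itself differentiated
with respect to the critic parameters.  To support that, every vector-Jacobian
product here is expressed in terms of :class:`Tensor` operations, so a
backward pass run with ``create_graph=True`` builds a differentiable graph of
its own (the same trick torch uses for double backward).

Only the operations the package needs are implemented; this is not a general
deep-learning framework.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "no_grad",
    "concatenate",
    "logsumexp",
    "log_softmax",
    "softmax",
]

_grad_enabled: bool = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


@contextlib.contextmanager
def _grad_mode(enabled: bool):
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = enabled
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A numpy array plus the recipe that produced it.

    ``parents`` holds ``(parent, vjp)`` pairs, ``vjp`` mapping the incoming
    gradient (a Tensor) to the gradient contribution for that parent.
    """

    __slots__ = ("data", "parents", "requires_grad")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence[tuple["Tensor", Callable[["Tensor"], "Tensor"]]] = (),
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.parents = tuple(parents)

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data.reshape(()) if self.data.size == 1 else self.data)

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    # -- reductions / reshapes ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    @property
    def T(self):
        return transpose(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents) -> Tensor:
    if _grad_enabled:
        parents = [(p, f) for p, f in parents if p.requires_grad or p.parents]
        if parents:
            return Tensor(data, requires_grad=any(p.requires_grad for p, _ in parents), parents=parents)
    return Tensor(data)


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data + b.data,
        [(a, lambda g: _unbroadcast(g, a.shape)), (b, lambda g: _unbroadcast(g, b.shape))],
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data * b.data,
        [
            (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
            (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
        ],
    )


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    if isinstance(exponent, Tensor):
        raise TypeError("only constant exponents are supported")
    e = float(exponent)
    return _node(
        a.data ** e,
        [(a, lambda g: mul(g, mul(power(a, e - 1.0), e)))],
    )


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data @ b.data,
        [
            (a, lambda g: matmul(g, transpose(b))),
            (b, lambda g: matmul(transpose(a), g)),
        ],
    )


def transpose(a) -> Tensor:
    a = as_tensor(a)
    return _node(a.data.T, [(a, lambda g: transpose(g))])


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.shape
    return _node(a.data.reshape(shape), [(a, lambda g: reshape(g, old))])


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.shape
    return _node(np.broadcast_to(a.data, shape).copy(), [(a, lambda g: _unbroadcast(g, old))])


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    shape = a.shape

    def vjp(g: Tensor) -> Tensor:
        if axis is None:
            return broadcast_to(reshape(g, (1,) * len(shape)), shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % len(shape) for ax in axes)
        if not keepdims:
            kd = tuple(1 if i in axes else n for i, n in enumerate(shape))
            g = reshape(g, kd)
        return broadcast_to(g, shape)

    return _node(a.data.sum(axis=axis, keepdims=keepdims), [(a, vjp)])


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        denom = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        denom = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / denom)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)
    out = _node(out_data, [(a, lambda g: mul(g, out))])
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    return _node(np.log(a.data), [(a, lambda g: mul(g, power(a, -1.0)))])


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)
    out = _node(out_data, [(a, lambda g: mul(g, add(1.0, -power(out, 2.0))))])
    return out


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    scale = np.where(a.data > 0, 1.0, slope)  # constant w.r.t. the graph
    return _node(a.data * scale, [(a, lambda g: mul(g, Tensor(scale)))])


def relu(a) -> Tensor:
    return leaky_relu(a, slope=0.0)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    out = _node(out_data, [(a, lambda g: mul(g, mul(out, add(1.0, -out))))])
    return out


def clip_low(a, lo: float) -> Tensor:
    """max(a, lo); gradient passes where a > lo (straight-through at the clamp)."""
    a = as_tensor(a)
    mask = (a.data > lo).astype(np.float64)
    return _node(np.maximum(a.data, lo), [(a, lambda g: mul(g, Tensor(mask)))])


def take(a, idx) -> Tensor:
    a = as_tensor(a)
    shape = a.shape

    def vjp(g: Tensor) -> Tensor:
        return _scatter(g, idx, shape)

    return _node(a.data[idx], [(a, vjp)])


def _scatter(g: Tensor, idx, shape) -> Tensor:
    g = as_tensor(g)
    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, idx, g.data)
    return _node(out, [(g, lambda gg: take(gg, idx))])


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    parents = []
    for i, t in enumerate(tensors):
        sl = [slice(None)] * tensors[0].ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        parents.append((t, lambda g, sl=sl: take(g, sl)))
    return _node(np.concatenate([t.data for t in tensors], axis=axis), parents)


# ---------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------

def logsumexp(a, axis: int = -1, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    c = np.max(a.data, axis=axis, keepdims=True)  # detached shift for stability
    shifted = add(a, Tensor(-c))
    s = log(sum_(exp(shifted), axis=axis, keepdims=True))
    out = add(s, Tensor(c))
    if not keepdims:
        out = reshape(out, tuple(n for i, n in enumerate(out.shape) if i != axis % a.ndim))
    return out


def log_softmax(a, axis: int = -1) -> Tensor:
    return add(a, -logsumexp(a, axis=axis, keepdims=True))


def softmax(a, axis: int = -1) -> Tensor:
    return exp(log_softmax(a, axis=axis))


# ---------------------------------------------------------------------
# backward
# ---------------------------------------------------------------------

def grad(output: Tensor, wrt: Sequence[Tensor], create_graph: bool = False) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``wrt``.

    With ``create_graph=True`` the returned gradients are themselves nodes in
    a differentiable graph, enabling second-order terms.
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")

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
        for parent, _ in node.parents:
            if id(parent) not in seen:
                stack.append((parent, False))

    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    with _grad_mode(create_graph):
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            for parent, vjp in node.parents:
                contrib = vjp(g)
                prev = grads.get(id(parent))
                grads[id(parent)] = contrib if prev is None else add(prev, contrib)
            # keep gradients of requested leaves even if they also have parents
            if any(node is w for w in wrt):
                grads[id(node)] = g

    out = []
    for w in wrt:
        g = grads.get(id(w))
        if g is None:
            g = Tensor(np.zeros_like(w.data))
        out.append(g if create_graph else g.detach())
    return out
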