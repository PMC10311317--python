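"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in :mod:`motifnet.model` is a short, fixed pipeline of dense
linear algebra (batched matrix products, sigmoids, softmaxes, a sliding
window extraction). Rather than hand-deriving and maintaining the adjoint
of the full composite, each primitive below carries its own vector-Jacobian
product and gradients are accumulated by topological traversal of the
expression graph. The primitive set is deliberately closed: it is exactly
what the architecture needs, nothing more.

Gradient correctness of every primitive is pinned down end-to-end by
central-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "sigmoid",
    "softmax",
    "maximum",
    "sliding_windows",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode AD."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp

    # ------------------------------------------------------------------ info
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every upstream tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._vjp is None:
                continue
            for parent, pg in zip(t._parents, t._vjp(g)):
                if pg is None:
                    continue
                pid = id(parent)
                grads[pid] = pg if pid not in grads else grads[pid] + pg

    # ------------------------------------------------------------ operators
    def _needs_graph(self, *others: "Tensor") -> bool:
        return any(t.requires_grad or t._parents for t in (self, *others))

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data
        sa, sb = self.data.shape, other.data.shape
        return _node(
            out_data,
            (self, other),
            lambda g: (_unbroadcast(g, sa), _unbroadcast(g, sb)),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = _as_tensor(other)
        out_data = self.data - other.data
        sa, sb = self.data.shape, other.data.shape
        return _node(
            out_data,
            (self, other),
            lambda g: (_unbroadcast(g, sa), _unbroadcast(-g, sb)),
        )

    def __rsub__(self, other):
        return _as_tensor(other).__sub__(self)

    def __mul__(self, other):
        other = _as_tensor(other)
        a, b = self.data, other.data
        return _node(
            a * b,
            (self, other),
            lambda g: (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return _node(-self.data, (self,), lambda g: (-g,))

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self.data, other.data
        out = a @ b

        def vjp(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return _node(out, (self, other), vjp)

    def sum(self, axis=None, keepdims: bool = False):
        a = self.data
        out = a.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return _node(out, (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return _node(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return _node(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def flip(self, axes):
        return _node(
            np.flip(self.data, axes), (self,), lambda g: (np.flip(g, axes),)
        )


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjp) -> Tensor:
    track = any(p.requires_grad or p._parents for p in parents)
    if not track:
        return Tensor(data)
    return Tensor(data, _parents=parents, _vjp=vjp)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


# ----------------------------------------------------------------- functions
def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _node(s, (x,), lambda g: (g * s * (1.0 - s),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        return (s * (g - (g * s).sum(axis=axis, keepdims=True)),)

    return _node(s, (x,), vjp)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise maximum; ties route the gradient to ``a``."""
    a, b = _as_tensor(a), _as_tensor(b)
    mask = a.data >= b.data
    out = np.where(mask, a.data, b.data)

    def vjp(g):
        return (
            _unbroadcast(np.where(mask, g, 0.0), a.data.shape),
            _unbroadcast(np.where(mask, 0.0, g), b.data.shape),
        )

    return _node(out, (a, b), vjp)


def sliding_windows(x: Tensor, width: int) -> Tensor:
    """Extract all length-``width`` windows from a (n, C, L) tensor.

    Returns a (n, L - width + 1, C * width) tensor whose row j is the
    flattened window x[:, :, j : j + width]; this turns a valid
    cross-correlation with a bank of kernels into a single matrix product.
    """
    x = _as_tensor(x)
    n, C, L = x.data.shape
    if width > L:
        raise ValueError(f"window width {width} exceeds sequence length {L}")
    Lp = L - width + 1
    view = np.lib.stride_tricks.sliding_window_view(x.data, width, axis=2)
    out = view.transpose(0, 2, 1, 3).reshape(n, Lp, C * width)

    def vjp(g):
        g4 = g.reshape(n, Lp, C, width)
        gx = np.zeros((n, C, L))
        for u in range(width):
            gx[:, :, u : u + Lp] += g4[:, :, :, u].transpose(0, 2, 1)
        return (gx,)

    return _node(out, (x,), vjp)
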