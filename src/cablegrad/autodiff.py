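"""Minimal reverse-mode automatic differentiation over numpy arrays.

The simulator's physics code is written once against a small set of
primitives (arithmetic, exp/log, reductions, gather/scatter and a
tree-structured linear solve).  Run with plain ``numpy`` arrays the code is a
fast forward simulation; run with :class:`Tensor` leaves under an active
:class:`Tape` the same code records a linear tape whose reverse sweep yields
exact gradients (backpropagation through time).  The tape is intentionally
simple — creation order *is* a topological order, so the backward pass is a
single reversed loop.

Only ``float64`` values are supported on tapes.  Broadcasting follows numpy;
gradients of broadcast operands are summed back to the operand shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tape",
    "Tensor",
    "value_of",
    "is_tensor",
    "exp",
    "expm1",
    "log",
    "sqrt",
    "absolute",
    "tanh",
    "sigmoid",
    "where",
    "asum",
    "amean",
    "amax",
    "logsumexp",
    "stack",
    "concatenate",
    "reshape",
    "take",
    "put",
    "add_at",
    "stop_gradient",
    "tree_solve",
    "hines_solve",
]

_ACTIVE_TAPE: list["Tape"] = []


class Tape:
    """Records :class:`Tensor` operations for a later reverse sweep."""

    def __init__(self) -> None:
        self._nodes: list[Tensor] = []

    # -- context management -------------------------------------------------
    def __enter__(self) -> "Tape":
        _ACTIVE_TAPE.append(self)
        return self

    def __exit__(self, *exc) -> None:
        _ACTIVE_TAPE.pop()

    def _record(self, t: "Tensor") -> None:
        self._nodes.append(t)

    def leaf(self, value) -> "Tensor":
        t = Tensor(value)
        self._record(t)
        return t

    def __len__(self) -> int:
        return len(self._nodes)

    def backward(self, out: "Tensor", seed=None) -> None:
        """Accumulate ``.grad`` on every tensor reachable from ``out``.

        ``seed`` defaults to 1 (``out`` must then be scalar-like).
        """
        if seed is None:
            seed = np.ones_like(np.asarray(out.value, dtype=float))
        out.grad = np.asarray(seed, dtype=float) + (
            out.grad if out.grad is not None else 0.0
        )
        for node in reversed(self._nodes):
            g = node.grad
            if g is None or node._vjp is None:
                continue
            for parent, contrib in node._vjp(g):
                if parent.grad is None:
                    parent.grad = np.zeros_like(
                        np.asarray(parent.value, dtype=float)
                    )
                parent.grad = parent.grad + _unbroadcast(
                    contrib, np.shape(parent.value)
                )

    def clear_grads(self) -> None:
        for node in self._nodes:
            node.grad = None


def _current_tape() -> Tape | None:
    return _ACTIVE_TAPE[-1] if _ACTIVE_TAPE else None


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    grad = np.asarray(grad, dtype=float)
    if grad.shape == tuple(shape):
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy value plus a backward rule on the active tape."""

    __slots__ = ("value", "grad", "_vjp")
    # make numpy defer to Tensor's reflected operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, value, _vjp=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._vjp = _vjp

    # -- introspection ------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __len__(self):
        return len(self.value)

    def __repr__(self):
        return f"Tensor({self.value!r})"

    def item(self):
        return float(self.value)

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return _binary(other, self, np.subtract, lambda g, a, b: (g, -g))

    def __mul__(self, other):
        return _binary(self, other, np.multiply, lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(
            self, other, np.divide,
            lambda g, a, b: (g / b, -g * a / (b * b)),
        )

    def __rtruediv__(self, other):
        return _binary(
            other, self, np.divide,
            lambda g, a, b: (g / b, -g * a / (b * b)),
        )

    def __neg__(self):
        return _unary(self, np.negative, lambda g, x, y: -g)

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return _unary(
            self, lambda x: np.power(x, p),
            lambda g, x, y: g * p * np.power(x, p - 1),
        )

    def __getitem__(self, idx):
        return take(self, idx)

    # comparisons operate on values and return plain bool arrays
    def __lt__(self, other):
        return self.value < value_of(other)

    def __le__(self, other):
        return self.value <= value_of(other)

    def __gt__(self, other):
        return self.value > value_of(other)

    def __ge__(self, other):
        return self.value >= value_of(other)

    def sum(self, axis=None):
        return asum(self, axis=axis)

    def mean(self, axis=None):
        return amean(self, axis=axis)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def value_of(x):
    """Underlying numpy value of a Tensor, pass-through otherwise."""
    return x.value if isinstance(x, Tensor) else x


def _wrap(value, vjp):
    tape = _current_tape()
    t = Tensor(value, _vjp=vjp)
    if tape is not None:
        tape._record(t)
    return t


def _binary(a, b, fn, grads):
    if not (isinstance(a, Tensor) or isinstance(b, Tensor)):
        return fn(a, b)
    av, bv = value_of(a), value_of(b)
    out = fn(av, bv)

    def vjp(g):
        ga, gb = grads(g, av, bv)
        pairs = []
        if isinstance(a, Tensor):
            pairs.append((a, ga))
        if isinstance(b, Tensor):
            pairs.append((b, gb))
        return pairs

    return _wrap(out, vjp)


def _unary(x, fn, grad):
    if not isinstance(x, Tensor):
        return fn(x)
    xv = x.value
    out = fn(xv)
    return _wrap(out, lambda g: [(x, grad(g, xv, out))])


# -- elementwise functions --------------------------------------------------

def exp(x):
    return _unary(x, np.exp, lambda g, xv, y: g * y)


def expm1(x):
    if not isinstance(x, Tensor) and np.iscomplexobj(x):
        return np.exp(x) - 1.0  # np.expm1 lacks complex support
    return _unary(x, np.expm1, lambda g, xv, y: g * np.exp(xv))


def log(x):
    return _unary(x, np.log, lambda g, xv, y: g / xv)


def sqrt(x):
    return _unary(x, np.sqrt, lambda g, xv, y: g * 0.5 / y)


def absolute(x):
    # subgradient sign(x) at 0
    return _unary(x, np.abs, lambda g, xv, y: g * np.sign(xv))


def tanh(x):
    return _unary(x, np.tanh, lambda g, xv, y: g * (1.0 - y * y))


def sigmoid(x):
    """Numerically stable logistic function 1/(1+exp(-x))."""
    if not isinstance(x, Tensor):
        xv = x
        if np.iscomplexobj(xv):
            return 1.0 / (1.0 + np.exp(-xv))
        with np.errstate(over="ignore"):
            return np.where(
                np.asarray(xv) >= 0,
                1.0 / (1.0 + np.exp(-np.abs(xv))),
                np.exp(-np.abs(xv)) / (1.0 + np.exp(-np.abs(xv))),
            )

    def fn(xv):
        return sigmoid(xv)

    return _unary(x, fn, lambda g, xv, y: g * y * (1.0 - y))


def where(cond, a, b):
    cond = np.asarray(value_of(cond))
    if not (isinstance(a, Tensor) or isinstance(b, Tensor)):
        return np.where(cond, a, b)
    out = np.where(cond, value_of(a), value_of(b))

    def vjp(g):
        pairs = []
        if isinstance(a, Tensor):
            pairs.append((a, np.where(cond, g, 0.0)))
        if isinstance(b, Tensor):
            pairs.append((b, np.where(cond, 0.0, g)))
        return pairs

    return _wrap(out, vjp)


# -- reductions --------------------------------------------------------------

def asum(x, axis=None):
    if not isinstance(x, Tensor):
        return np.sum(x, axis=axis)
    xv = x.value

    def vjp(g):
        if axis is None:
            return [(x, np.broadcast_to(g, xv.shape).copy())]
        gg = np.expand_dims(g, axis)
        return [(x, np.broadcast_to(gg, xv.shape).copy())]

    return _wrap(np.sum(xv, axis=axis), vjp)


def amean(x, axis=None):
    if not isinstance(x, Tensor):
        return np.mean(x, axis=axis)
    n = x.value.size if axis is None else x.value.shape[axis]
    return asum(x, axis=axis) / n


def amax(x, axis=None):
    """Hard max; gradient flows to the (first) argmax positions."""
    if not isinstance(x, Tensor):
        return np.max(x, axis=axis)
    xv = x.value
    out = np.max(xv, axis=axis)

    def vjp(g):
        if axis is None:
            mask = np.zeros_like(xv)
            mask[np.unravel_index(np.argmax(xv), xv.shape)] = 1.0
            return [(x, mask * g)]
        idx = np.argmax(xv, axis=axis)
        mask = np.zeros_like(xv)
        np.put_along_axis(mask, np.expand_dims(idx, axis), 1.0, axis=axis)
        return [(x, mask * np.expand_dims(g, axis))]

    return _wrap(out, vjp)


def logsumexp(x, axis=None):
    """Stable log-sum-exp; the max shift is detached (gradient-exact)."""
    shift = np.max(value_of(x), axis=axis, keepdims=axis is not None)
    shifted = x - shift
    s = log(asum(exp(shifted), axis=axis))
    if axis is not None:
        shift = np.squeeze(shift, axis=axis)
    return s + shift


# -- shape ops ---------------------------------------------------------------

def stack(parts, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.stack(parts, axis=axis)
    vals = [value_of(p) for p in parts]
    out = np.stack(vals, axis=axis)

    def vjp(g):
        pieces = np.moveaxis(g, axis, 0)
        return [
            (p, pieces[i]) for i, p in enumerate(parts) if isinstance(p, Tensor)
        ]

    return _wrap(out, vjp)


def concatenate(parts, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate(parts, axis=axis)
    vals = [np.asarray(value_of(p)) for p in parts]
    out = np.concatenate(vals, axis=axis)
    sizes = [v.shape[axis] for v in vals]
    bounds = np.cumsum([0] + sizes)

    def vjp(g):
        pairs = []
        for i, p in enumerate(parts):
            if isinstance(p, Tensor):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(bounds[i], bounds[i + 1])
                pairs.append((p, g[tuple(sl)]))
        return pairs

    return _wrap(out, vjp)


def reshape(x, shape):
    if not isinstance(x, Tensor):
        return np.reshape(x, shape)
    old = x.value.shape
    return _wrap(
        np.reshape(x.value, shape), lambda g: [(x, np.reshape(g, old))]
    )


def take(x, idx):
    if not isinstance(x, Tensor):
        return np.asarray(x)[idx]
    xv = x.value

    def vjp(g):
        out = np.zeros_like(xv)
        np.add.at(out, idx, g)
        return [(x, out)]

    return _wrap(xv[idx], vjp)


def put(x, idx, values):
    """Out-of-place ``x[idx] = values`` (differentiable scatter-set)."""
    if not (isinstance(x, Tensor) or isinstance(values, Tensor)):
        out = np.array(x, dtype=float, copy=True)
        out[idx] = values
        return out
    xv = np.array(value_of(x), dtype=float, copy=True)
    xv[idx] = value_of(values)

    def vjp(g):
        pairs = []
        if isinstance(x, Tensor):
            gx = np.array(g, copy=True)
            gx[idx] = 0.0
            pairs.append((x, gx))
        if isinstance(values, Tensor):
            pairs.append((values, np.asarray(g)[idx]))
        return pairs

    return _wrap(xv, vjp)


def add_at(x, idx, values):
    """Out-of-place ``np.add.at`` (differentiable scatter-add)."""
    if not (isinstance(x, Tensor) or isinstance(values, Tensor)):
        out = np.array(x, dtype=np.result_type(x, values), copy=True)
        np.add.at(out, idx, values)
        return out
    xv = np.array(value_of(x), dtype=float, copy=True)
    np.add.at(xv, idx, value_of(values))

    def vjp(g):
        pairs = []
        if isinstance(x, Tensor):
            pairs.append((x, g))
        if isinstance(values, Tensor):
            pairs.append((values, np.asarray(g)[idx]))
        return pairs

    return _wrap(xv, vjp)


def stop_gradient(x):
    return Tensor(value_of(x)) if isinstance(x, Tensor) else x


# -- tree-structured linear solve --------------------------------------------

def hines_solve(diag, off, rhs, parent):
    """Solve the symmetric tree-structured system exactly (numpy only).

    ``off[i]`` is the (signed) matrix entry at ``(i, parent[i])`` and, by
    symmetry, at ``(parent[i], i)``; ``diag`` holds the diagonal and
    ``parent[i] < i`` (``off[0]`` is unused).  Elimination runs from leaves
    to root followed by back-substitution — the branch-wise elimination onto
    junction nodes that tree morphologies admit.
    """
    d = np.array(diag, copy=True)
    r = np.array(rhs, copy=True)
    n = d.shape[0]
    for i in range(n - 1, 0, -1):
        p = parent[i]
        f = off[i] / d[i]
        d[p] = d[p] - f * off[i]
        r[p] = r[p] - f * r[i]
    x = np.empty_like(r)
    if d[0] == 0:
        raise np.linalg.LinAlgError("singular tree system (zero root pivot)")
    x[0] = r[0] / d[0]
    for i in range(1, n):
        x[i] = (r[i] - off[i] * x[parent[i]]) / d[i]
    return x


def tree_solve(diag, off, rhs, parent):
    """Differentiable solve of the tree system (custom adjoint).

    The matrix is symmetric, so the adjoint system reuses the same solve:
    with ``x = A^{-1} b`` and incoming cotangent ``v``, ``y = A^{-1} v``
    gives ``db = y``, ``d(diag_i) = -y_i x_i`` and, for the edge entry
    ``off_i`` appearing at ``(i, p)`` and ``(p, i)``,
    ``d(off_i) = -(y_i x_p + y_p x_i)``.
    """
    if not any(isinstance(a, Tensor) for a in (diag, off, rhs)):
        return hines_solve(diag, off, rhs, parent)
    dv, ov, rv = value_of(diag), value_of(off), value_of(rhs)
    x = hines_solve(dv, ov, rv, parent)

    def vjp(g):
        y = hines_solve(dv, ov, rv * 0.0 + g, parent)
        pairs = []
        if isinstance(rhs, Tensor):
            pairs.append((rhs, y))
        if isinstance(diag, Tensor):
            pairs.append((diag, -y * x))
        if isinstance(off, Tensor):
            go = np.zeros_like(ov)
            go[1:] = -(y[1:] * x[parent[1:]] + y[parent[1:]] * x[1:])
            pairs.append((off, go))
        return pairs

    return _wrap(x, vjp)
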