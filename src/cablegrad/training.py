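"""Gradients of trace losses and gradient-based fitting.

``loss_gradient`` differentiates ``loss(simulate(model, params))`` with
respect to the *unconstrained* parameterization of a
:class:`~cablegrad.params.ParameterView` by reverse-mode differentiation
through the time-stepping loop (backpropagation through time).  Memory is
bounded by multilevel checkpointing: the forward pass stores only segment
snapshots and the reverse sweep re-simulates one innermost segment at a time
on a tape, so one gradient costs a small constant multiple of one
simulation, independent of the number of parameters.  Gradient flow can be
severed at fixed intervals (truncated BPTT) without changing the forward
trace.

``finite_difference_gradient`` provides the independent central-difference
oracle against which the reverse-mode path is validated.

Two optimizers are included: a normalized-gradient ("Polyak") variant with
per-group norms, ``step = −γ·∇L/‖∇L‖^β`` with optional multiplication by the
loss value and heavy-ball momentum, and a standard Adam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ag
from .autodiff import value_of
from .morphology import CompartmentTree, branch_parent
from .params import ParameterView
from .solver import (
    CompiledModel,
    SolverState,
    Trace,
    n_steps_for,
    observe,
    simulate,
    step,
)

logger = logging.getLogger("cablegrad")

__all__ = [
    "CheckpointPlan",
    "OptimizerConfig",
    "loss_gradient",
    "finite_difference_gradient",
    "checkpointed_gradient",
    "truncated_gradient",
    "polyak_step",
    "PolyakSGD",
    "Adam",
    "smoothness_penalty",
    "fit",
]


# ---------------------------------------------------------------------------
# checkpoint plans
# ---------------------------------------------------------------------------

@dataclass
class CheckpointPlan:
    """Multilevel checkpointing schedule.

    ``segments_per_level[i]`` is the number of segments the range is split
    into at level ``i``; innermost segments are taped in full.  The product
    over levels must cover the step count; peak stored snapshots are bounded
    by the sum over levels of the segment counts (versus one stored state
    per step for full-storage backprop).
    """

    segments_per_level: list[int]

    def __post_init__(self):
        if not self.segments_per_level or any(
            s < 1 for s in self.segments_per_level
        ):
            raise ValueError("segment counts must be positive")

    @property
    def levels(self) -> int:
        return len(self.segments_per_level)

    def max_snapshots(self) -> int:
        return int(sum(self.segments_per_level))

    def validate_for(self, n_steps: int) -> None:
        cover = int(np.prod(self.segments_per_level))
        # each innermost segment is taped, so s_1·...·s_k segments suffice
        # for any n; nothing further to check beyond positivity, but a plan
        # explicitly sized in steps must cover the run:
        if cover < 1 or n_steps < 0:
            raise ValueError("invalid plan")

    @classmethod
    def for_steps(cls, n_steps: int, levels: int = 2) -> "CheckpointPlan":
        """Balanced plan: ~n^(1/(levels+1)) segments per level."""
        s = max(1, int(np.ceil(n_steps ** (1.0 / (levels + 1)))))
        return cls([s] * levels)


def _split_range(a: int, b: int, k: int) -> list[tuple[int, int]]:
    """Split [a, b) into at most k nearly equal chunks."""
    n = b - a
    k = min(k, n) if n > 0 else 1
    edges = np.linspace(a, b, k + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(k)
            if edges[i + 1] > edges[i]]


# ---------------------------------------------------------------------------
# reverse-mode gradient through the solver
# ---------------------------------------------------------------------------

def _forward_states(compiled, runtime, state, a, b, dt, keep_at):
    """Advance from step a to b (numpy), returning states at ``keep_at``."""
    kept = {}
    if a in keep_at:
        kept[a] = state
    for k in range(a, b):
        state = step(compiled, runtime, state, dt, step_index=k)
        if k + 1 in keep_at:
            kept[k + 1] = state
    return kept, state


def _zeros_like_state(state: SolverState):
    return [np.zeros_like(np.asarray(x)) for x in state.flat_leaves()]


def _backward_segment(compiled, params, uncon, state_a, a, b, dt,
                      trace_bar, adjoint, grads):
    """Tape steps [a, b), seed with trace and state adjoints, backprop.

    Returns the adjoint of the state at step ``a``.
    """
    with ag.Tape() as tape:
        leaves = {name: tape.leaf(np.asarray(u)) for name, u in uncon.items()}
        runtime = compiled.runtime(params, unconstrained=leaves)
        st = state_a.as_leaves(tape)
        start_leaves = st.flat_leaves()
        terms = []
        cur = st
        for k in range(a, b):
            cur = step(compiled, runtime, cur, dt, step_index=k)
            if trace_bar is not None:
                tb = trace_bar[:, k + 1]
                if np.any(tb != 0.0):
                    rec = observe(compiled, cur)
                    terms.append(ag.asum(rec * tb))
        for leaf_t, adj in zip(cur.flat_leaves(), adjoint):
            if np.any(adj != 0.0):
                terms.append(ag.asum(leaf_t * adj))
        if not terms:
            return _zeros_like_state(state_a)
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        tape.backward(total)
        for name, leaf in leaves.items():
            if leaf.grad is not None:
                grads[name] = grads[name] + leaf.grad
        new_adjoint = [
            (lf.grad if lf.grad is not None
             else np.zeros_like(np.asarray(lf.value)))
            for lf in start_leaves
        ]
    return new_adjoint


def _backward_range(compiled, params, uncon, runtime_np, state_a, a, b, dt,
                    trace_bar, adjoint, grads, segments_per_level):
    if a >= b:
        return adjoint if a == b else _zeros_like_state(state_a)
    if not segments_per_level:
        return _backward_segment(compiled, params, uncon, state_a, a, b, dt,
                                 trace_bar, adjoint, grads)
    chunks = _split_range(a, b, segments_per_level[0])
    starts = {c[0] for c in chunks}
    kept, _ = _forward_states(compiled, runtime_np, state_a, a, b, dt, starts)
    for ca, cb in reversed(chunks):
        adjoint = _backward_range(
            compiled, params, uncon, runtime_np, kept[ca], ca, cb, dt,
            trace_bar, adjoint, grads, segments_per_level[1:],
        )
    return adjoint


@dataclass
class GradientResult:
    value: float
    grads: dict[str, np.ndarray]
    trace: Trace


def loss_gradient(
    model,
    loss,
    params: ParameterView,
    t_max: float,
    dt: float = 0.025,
    unconstrained: dict | None = None,
    plan: CheckpointPlan | None = None,
    truncate_ms: float | None = None,
    state0: SolverState | None = None,
) -> GradientResult:
    """Gradient of ``loss(simulate(...))`` wrt unconstrained parameters.

    ``loss`` maps a :class:`Trace` to a scalar and must be composed of
    :mod:`cablegrad.autodiff` primitives.  With ``plan`` given, backprop is
    memory-bounded by multilevel checkpointing (identical gradient).  With
    ``truncate_ms`` given, adjoint state flow is severed at each multiple of
    that interval (truncated BPTT); the forward trace is unchanged.
    """
    compiled = model if isinstance(model, CompiledModel) else model.compile()
    uncon = (
        {k: np.asarray(v, dtype=float) for k, v in unconstrained.items()}
        if unconstrained is not None
        else params.to_unconstrained()
    )
    n = n_steps_for(t_max, dt)
    runtime_np = compiled.runtime(params, unconstrained=uncon)
    state = state0 if state0 is not None else compiled.initial_state()
    state = state.detached()

    # full forward pass with recording (numpy)
    trace = simulate(compiled, params, t_max=t_max, dt=dt,
                     unconstrained=uncon, state0=state)

    # loss and its adjoint with respect to the recorded trace
    with ag.Tape() as tape:
        vals = tape.leaf(np.asarray(trace.values))
        loss_t = loss(Trace(trace.times, vals, trace.labels))
        if not ag.is_tensor(loss_t):  # loss independent of the trace
            loss_value = float(loss_t)
            trace_bar = np.zeros_like(np.asarray(trace.values))
        else:
            tape.backward(loss_t)
            loss_value = float(loss_t.value)
            trace_bar = (
                vals.grad if vals.grad is not None
                else np.zeros_like(vals.value)
            )

    grads = {name: np.zeros_like(np.asarray(u)) for name, u in uncon.items()}
    adjoint = _zeros_like_state(state)

    # truncation boundaries partition the run; checkpointing applies inside
    if truncate_ms is not None:
        if truncate_ms <= 0:
            raise ValueError("truncation interval must be > 0")
        stride = max(1, n_steps_for(truncate_ms, dt))
        cuts = list(range(0, n, stride)) + [n]
    else:
        cuts = [0, n]
    seg_levels = list(plan.segments_per_level) if plan is not None else []
    if plan is not None:
        plan.validate_for(n)

    # snapshots at each truncation-boundary start
    starts = set(cuts[:-1])
    kept, _ = _forward_states(compiled, runtime_np, state, 0, n, dt, starts)
    for i in range(len(cuts) - 2, -1, -1):
        a, b = cuts[i], cuts[i + 1]
        adjoint = _backward_range(
            compiled, params, uncon, runtime_np, kept[a], a, b, dt,
            trace_bar, adjoint, grads, seg_levels,
        )
        adjoint = _zeros_like_state(state) if i > 0 else adjoint

    for name in grads:
        if not np.all(np.isfinite(grads[name])):
            raise FloatingPointError(
                f"non-finite gradient for parameter {name!r}"
            )
    return GradientResult(value=loss_value, grads=grads, trace=trace)


def checkpointed_gradient(model, loss, params, t_max, dt=0.025,
                          plan: CheckpointPlan | None = None, **kw):
    """``loss_gradient`` under a (default two-level) checkpoint plan."""
    if plan is None:
        plan = CheckpointPlan.for_steps(n_steps_for(t_max, dt), levels=2)
    return loss_gradient(model, loss, params, t_max, dt, plan=plan, **kw)


def truncated_gradient(model, loss, params, t_max, dt=0.025,
                       truncation_interval: float = 50.0, **kw):
    """``loss_gradient`` with gradient flow severed every interval (ms)."""
    return loss_gradient(model, loss, params, t_max, dt,
                         truncate_ms=truncation_interval, **kw)


def finite_difference_gradient(
    model,
    loss,
    params: ParameterView,
    t_max: float,
    dt: float = 0.025,
    h: float | None = None,
    unconstrained: dict | None = None,
    state0: SolverState | None = None,
) -> dict[str, np.ndarray]:
    """Central finite differences in unconstrained space (the oracle).

    The default step is ``1e-6 · max(1, |value|)`` per parameter.
    """
    compiled = model if isinstance(model, CompiledModel) else model.compile()
    uncon = (
        {k: np.asarray(v, dtype=float) for k, v in unconstrained.items()}
        if unconstrained is not None
        else params.to_unconstrained()
    )

    def eval_loss(u):
        tr = simulate(compiled, params, t_max=t_max, dt=dt, unconstrained=u,
                      state0=state0)
        return float(value_of(loss(tr)))

    grads = {}
    for name, u in uncon.items():
        g = np.zeros_like(u)
        for i in range(u.size):
            hi = h if h is not None else 1e-6 * max(1.0, abs(u.flat[i]))
            up = {k: v.copy() for k, v in uncon.items()}
            up[name].flat[i] += hi
            um = {k: v.copy() for k, v in uncon.items()}
            um[name].flat[i] -= hi
            g.flat[i] = (eval_loss(up) - eval_loss(um)) / (2 * hi)
        grads[name] = g
    return grads


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

@dataclass
class OptimizerConfig:
    """Settings for the normalized-gradient (Polyak-style) optimizer."""

    gamma: float = 0.1  # learning rate
    beta: float = 0.8  # gradient-norm exponent, typically in [0.8, 0.99]
    momentum: float = 0.0
    multiply_by_loss: bool = False
    loss_multiplier_position: str = "pre"  # "pre" or "post" normalization
    per_group: bool = True

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.loss_multiplier_position not in ("pre", "post"):
            raise ValueError("loss_multiplier_position must be pre|post")


def polyak_step(
    grads: dict[str, np.ndarray],
    cfg: OptimizerConfig,
    loss_value: float = 1.0,
    momentum_state: dict | None = None,
    groups: dict[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """One update ``−γ·g/‖g‖^β`` (per group), optionally loss-scaled.

    ``groups`` maps entry name -> group label; without it all entries share
    one norm.  A zero-norm group yields a zero update (logged).
    """
    g = {k: np.asarray(v, dtype=float) for k, v in grads.items()}
    if cfg.multiply_by_loss and cfg.loss_multiplier_position == "pre":
        g = {k: v * loss_value for k, v in g.items()}
    if cfg.per_group and groups is not None:
        labels = {k: groups.get(k, k) for k in g}
    else:
        labels = {k: "__all__" for k in g}
    norms: dict[str, float] = {}
    for k, v in g.items():
        norms[labels[k]] = norms.get(labels[k], 0.0) + float(np.sum(v * v))
    norms = {lab: np.sqrt(s) for lab, s in norms.items()}
    update = {}
    for k, v in g.items():
        nrm = norms[labels[k]]
        if nrm == 0.0:
            logger.warning("zero-norm gradient for group %r", labels[k])
            update[k] = np.zeros_like(v)
        else:
            update[k] = -cfg.gamma * v / nrm**cfg.beta
    if cfg.multiply_by_loss and cfg.loss_multiplier_position == "post":
        update = {k: v * loss_value for k, v in update.items()}
    if cfg.momentum and momentum_state is not None:
        for k in update:
            buf = momentum_state.get(k)
            buf = (
                cfg.momentum * buf + update[k]
                if buf is not None
                else update[k]
            )
            momentum_state[k] = buf
            update[k] = buf
    return update


class PolyakSGD:
    """Stateful wrapper around :func:`polyak_step`."""

    def __init__(self, cfg: OptimizerConfig, groups=None):
        self.cfg = cfg
        self.groups = groups
        self.momentum_state: dict = {}

    def step(self, uncon, grads, loss_value=1.0):
        upd = polyak_step(grads, self.cfg, loss_value,
                          self.momentum_state, self.groups)
        return {k: uncon[k] + upd[k] for k in uncon}


class Adam:
    """Standard Adam on the unconstrained parameter dictionaries."""

    def __init__(self, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, uncon, grads, loss_value=None):
        self.t += 1
        out = {}
        for k, u in uncon.items():
            g = np.asarray(grads[k], dtype=float)
            self.m[k] = self.beta1 * self.m.get(k, 0.0) + (1 - self.beta1) * g
            self.v[k] = (
                self.beta2 * self.v.get(k, 0.0) + (1 - self.beta2) * g * g
            )
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            out[k] = u - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


# ---------------------------------------------------------------------------
# regularization and fitting
# ---------------------------------------------------------------------------

def smoothness_penalty(values, tree: CompartmentTree, lam: float = 0.001):
    """λ·Σ over non-root branches of (ḡ_b − ḡ_parent(b))².

    Encourages neighboring branches to carry similar conductance values;
    differentiable in ``values`` (one value per branch, tree branch order).
    """
    parents = branch_parent(tree)
    child = np.flatnonzero(parents >= 0)
    if child.size == 0:
        return 0.0 * ag.asum(values) if ag.is_tensor(values) else 0.0
    diff = ag.take(values, child) - ag.take(values, parents[child])
    return lam * ag.asum(diff * diff)


def fit(
    model,
    loss,
    params: ParameterView,
    t_max: float,
    dt: float = 0.025,
    optimizer=None,
    n_iter: int = 100,
    plan: CheckpointPlan | None = None,
    truncate_ms: float | None = None,
    penalty=None,
    callback=None,
):
    """Generic gradient-descent fit loop.

    ``penalty`` is an optional callable of the physical-parameter dict
    (Tensor-valued) added to the loss; returns the fitted
    :class:`ParameterView` (updated in place) and the loss history.
    """
    if optimizer is None:
        optimizer = PolyakSGD(
            OptimizerConfig(),
            groups={e.name: e.group for e in params},
        )
    uncon = params.to_unconstrained()
    history = []

    def total_loss(trace, leaves):
        base = loss(trace)
        if penalty is not None:
            base = base + penalty(params.physical(leaves))
        return base

    for it in range(n_iter):
        res = loss_gradient(model, loss, params, t_max, dt,
                            unconstrained=uncon, plan=plan,
                            truncate_ms=truncate_ms)
        value, grads = res.value, res.grads
        if penalty is not None:
            # add the penalty and its gradient (direct, no simulation)
            with ag.Tape() as tape:
                leaves = {k: tape.leaf(v) for k, v in uncon.items()}
                p = penalty(params.physical(leaves))
                if ag.is_tensor(p):
                    tape.backward(p)
                    for k, lf in leaves.items():
                        if lf.grad is not None:
                            grads[k] = grads[k] + lf.grad
                    value = value + float(p.value)
                else:
                    value = value + float(p)
        history.append(value)
        logger.info("iter %d: loss %.6g", it, value)
        uncon = optimizer.step(uncon, grads, loss_value=value)
        if callback is not None:
            callback(it, value, uncon)
    params.set_unconstrained(uncon)
    return params, np.asarray(history)
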