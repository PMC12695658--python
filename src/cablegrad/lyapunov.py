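"""Maximal Lyapunov exponent of the discrete-time solver map.

One solver step defines a map ``x_{t+1} = f(x_t)`` on the full state vector
(voltages plus gate and synaptic activation variables).  The maximal
Lyapunov exponent is estimated by co-evolving a tangent vector with the step
Jacobian, ``q_{t+1} = Df|_{x_t} q_t``, renormalizing every step and
averaging the log norm growth: λ_max = (1/T)·Σ log r_t.  Positive values
indicate chaotic (trial-to-trial divergent) dynamics.

The Jacobian-vector product is computed by complex-step differentiation:
one complex evaluation ``f(x + i·h·q)`` with h = 1e−100 yields both the next
state (real part) and the directional derivative (imaginary part / h) to
machine precision — an O(1)-cost tangent propagation, never a full Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import CompiledModel, SolverState, n_steps_for, step

__all__ = [
    "LyapunovConfig",
    "LyapunovResult",
    "max_lyapunov_map",
    "max_lyapunov",
    "dense_step_jacobian",
]

_H = 1e-100  # complex-step size; h² underflows, so no truncation error


@dataclass
class LyapunovConfig:
    """Desk-scale defaults: 500 ms discard, 1 s measurement at dt 0.025."""

    discard_ms: float = 500.0
    t_steps: int = 40_000  # measurement steps T
    dt: float = 0.025  # ms
    seed: int = 0

    def __post_init__(self):
        if self.t_steps < 1:
            raise ValueError("need T >= 1 measurement steps")
        if self.discard_ms < 0:
            raise ValueError("discard duration must be >= 0")


@dataclass
class LyapunovResult:
    lambda_per_step: float
    lambda_per_ms: float
    log_r: np.ndarray  # (T,) per-step log norm growth


def max_lyapunov_map(f, x0, n_steps: int, n_discard: int = 0,
                     seed: int = 0, dt: float | None = None,
                     q0=None) -> LyapunovResult:
    """λ_max of an arbitrary map ``f`` (must accept complex arrays)."""
    x = np.asarray(x0, dtype=float)
    for _ in range(n_discard):
        x = np.real(f(x))
    rng = np.random.default_rng(seed)
    q = np.asarray(q0, dtype=float) if q0 is not None \
        else rng.standard_normal(x.shape)
    nq = np.linalg.norm(q)
    if nq == 0:
        raise ValueError("degenerate (zero) initial tangent")
    q = q / nq
    log_r = np.empty(n_steps)
    for t in range(n_steps):
        fx = f(x + 1j * _H * q)
        x = np.real(fx)
        q = np.imag(fx) / _H
        r = np.linalg.norm(q)
        if r == 0 or not np.isfinite(r):
            raise FloatingPointError(
                f"degenerate tangent norm {r} at step {t}"
            )
        log_r[t] = np.log(r)
        q = q / r
    lam = float(np.mean(log_r))
    return LyapunovResult(
        lambda_per_step=lam,
        lambda_per_ms=lam / dt if dt else np.nan,
        log_r=log_r,
    )


# ---------------------------------------------------------------------------
# flattening the solver state
# ---------------------------------------------------------------------------

class _Flattener:
    def __init__(self, template: SolverState):
        self.slices = []
        self.keys = []
        off = 0
        n = len(np.asarray(template.v))
        self.slices.append(slice(0, n))
        self.keys.append(("v", None, None))
        off = n
        for cname, gates in template.gates.items():
            for gname, arr in gates.items():
                k = len(np.asarray(arr))
                self.slices.append(slice(off, off + k))
                self.keys.append(("gate", cname, gname))
                off += k
        k = len(np.asarray(template.syn_s))
        self.slices.append(slice(off, off + k))
        self.keys.append(("syn", None, None))
        off += k
        if template.calcium is not None:
            k = len(np.asarray(template.calcium))
            self.slices.append(slice(off, off + k))
            self.keys.append(("ca", None, None))
            off += k
        self.size = off

    def pack(self, state: SolverState):
        out = np.empty(self.size, dtype=float)
        for sl, key in zip(self.slices, self.keys):
            kind, c, g = key
            if kind == "v":
                out[sl] = np.asarray(state.v)
            elif kind == "gate":
                out[sl] = np.asarray(state.gates[c][g])
            elif kind == "ca":
                out[sl] = np.asarray(state.calcium)
            else:
                out[sl] = np.asarray(state.syn_s)
        return out

    def unpack(self, x, t=0.0) -> SolverState:
        gates: dict = {}
        v = None
        syn = None
        ca = None
        for sl, key in zip(self.slices, self.keys):
            kind, c, g = key
            if kind == "v":
                v = x[sl]
            elif kind == "gate":
                gates.setdefault(c, {})[g] = x[sl]
            elif kind == "ca":
                ca = x[sl]
            else:
                syn = x[sl]
        return SolverState(v=v, gates=gates, syn_s=syn, t=t, calcium=ca)


def _step_map(compiled: CompiledModel, runtime, dt: float):
    template = compiled.initial_state()
    flat = _Flattener(template)

    def f(x):
        state = flat.unpack(x)
        out = step(compiled, runtime, state, dt, step_index=0)
        packed = np.empty(flat.size, dtype=complex
                          if np.iscomplexobj(x) else float)
        for sl, key in zip(flat.slices, flat.keys):
            kind, c, g = key
            if kind == "v":
                packed[sl] = out.v
            elif kind == "gate":
                packed[sl] = out.gates[c][g]
            elif kind == "ca":
                packed[sl] = out.calcium
            else:
                packed[sl] = out.syn_s
        return packed

    return f, flat


def max_lyapunov(model, params=None, cfg: LyapunovConfig | None = None,
                 state0: SolverState | None = None) -> LyapunovResult:
    """λ_max of a network model (per step and per ms).

    The model must be autonomous over the measurement window (constant or
    zero external input); transients are discarded for ``cfg.discard_ms``
    before the T-step tangent evolution.
    """
    cfg = cfg or LyapunovConfig()
    compiled = model if isinstance(model, CompiledModel) else model.compile()
    runtime = compiled.runtime(params)
    f, flat = _step_map(compiled, runtime, cfg.dt)
    state = state0 if state0 is not None else compiled.initial_state()
    x0 = flat.pack(state.detached())
    n_discard = n_steps_for(cfg.discard_ms, cfg.dt)
    return max_lyapunov_map(
        f, x0, n_steps=cfg.t_steps, n_discard=n_discard, seed=cfg.seed,
        dt=cfg.dt,
    )


def dense_step_jacobian(model, params=None, dt: float = 0.025,
                        state0: SolverState | None = None) -> np.ndarray:
    """Dense Jacobian of the one-step map by complex step on each basis
    vector — the independent oracle for small (≤ tens of states) models."""
    compiled = model if isinstance(model, CompiledModel) else model.compile()
    runtime = compiled.runtime(params)
    f, flat = _step_map(compiled, runtime, dt)
    state = state0 if state0 is not None else compiled.initial_state()
    x0 = flat.pack(state.detached())
    n = flat.size
    jac = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        jac[:, j] = np.imag(f(x0 + 1j * _H * e)) / _H
    return jac
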