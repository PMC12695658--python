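"""Channel kinetics and conductance-based synapses.

Ships the canonical squid-axon Hodgkin–Huxley channel set (Na with m³h,
K with n⁴, ohmic leak) in its conventional form: rates in 1/ms as functions
of membrane potential in mV, E_Na = 50 mV, E_K = −77 mV, E_leak = −54.3 mV,
default densities ḡ_Na = 0.12, ḡ_K = 0.036, ḡ_leak = 0.0003 S/cm².  No
temperature scaling is applied.

Gates and synaptic activations are advanced by exponential Euler, which is
exact for frozen voltage and keeps states inside [0, 1] for any step size.

Synapses follow the first-order transmitter–receptor kinetics of Abbott &
Marder: the steady-state activation s̄ is a logistic function of presynaptic
voltage, and the relaxation time constant is (1 − s̄)/k₋ where k₋ (1/ms) is
the transmitter–receptor dissociation rate.  The postsynaptic current is
I = g_syn · s · (V_post − E_syn) in nA (g_syn in nS), i.e. positive I is an
outward (hyperpolarizing) contribution at the post site; the solver moves it
to the other side of the equation so that E_syn above rest depolarizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ag
from .autodiff import value_of

__all__ = [
    "ChannelSpec",
    "SynapseSpec",
    "MechanismState",
    "CalciumPoolSpec",
    "calcium_pool_step",
    "hh_rates",
    "gate_steady_state",
    "gate_step_exponential",
    "channel_current_density",
    "channel_open_fraction",
    "synapse_steady_state",
    "synapse_step",
    "synapse_current",
    "standard_hh_channels",
    "CHANNEL_REGISTRY",
]


@dataclass
class ChannelSpec:
    """A voltage-gated (or leak) channel.

    ``rates`` maps gate name -> callable V -> (alpha, beta) in 1/ms;
    ``exponents`` maps gate name -> non-negative integer power.
    """

    name: str
    gbar: float  # S/cm², default density
    e_rev: float  # mV
    exponents: dict[str, int] = field(default_factory=dict)
    rates: dict = field(default_factory=dict)
    # optional: one call evaluating α/β for *all* gates (shared across
    # channels on the same compartments, e.g. the Na/K pair)
    rate_fn: object = None

    def __post_init__(self):
        if self.gbar < 0:
            raise ValueError(f"{self.name}: gbar must be >= 0")
        for gate, p in self.exponents.items():
            if not (isinstance(p, (int, np.integer)) and p >= 0):
                raise ValueError(f"{self.name}:{gate}: bad exponent {p}")

    @property
    def gates(self) -> list[str]:
        return list(self.exponents)


@dataclass
class SynapseSpec:
    """Conductance-based synapse parameters (Abbott–Marder kinetics)."""

    g_syn: float = 1.0  # nS, maximal conductance
    e_syn: float = 0.0  # mV, reversal
    k_minus: float = 1.0  # 1/ms, transmitter–receptor dissociation rate
    v_th: float = -35.0  # mV, presynaptic activation threshold
    v_slope: float = 10.0  # mV, activation slope

    def __post_init__(self):
        if value_of(self.g_syn) is not None and np.any(
            np.asarray(value_of(self.g_syn)) < 0
        ):
            raise ValueError("g_syn must be >= 0")
        if np.any(np.asarray(value_of(self.k_minus)) <= 0):
            raise ValueError("k_minus must be > 0")


@dataclass
class MechanismState:
    """Gate values per channel and synaptic activations (all in [0, 1])."""

    gates: dict[str, dict[str, object]]  # channel -> gate -> array
    syn_s: object  # (n_syn,) array
    calcium: object | None = None  # optional intracellular pool (mM)


@dataclass
class CalciumPoolSpec:
    """Minimal exponentially decaying intracellular calcium pool.

    The pool is driven by the inward current of a named channel:
    d[Ca]/dt = −([Ca] − ca_rest)/τ + scale·(−i_chan), with i_chan the
    channel's current density (mA/cm²) and ``scale`` converting it to a
    concentration flux (mM·cm²/(mA·ms)).  No calcium channel ships with the
    default kit; any conductance-based :class:`ChannelSpec` can drive the
    pool.
    """

    channel: str
    tau: float = 50.0  # ms
    scale: float = 0.01  # mM per (mA/cm²·ms)
    ca_rest: float = 1e-4  # mM

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("calcium pool tau must be > 0")


def calcium_pool_step(ca, i_drive, spec: CalciumPoolSpec, dt):
    """Exponential-Euler update of the pool for frozen drive current."""
    target = spec.ca_rest + spec.scale * spec.tau * (-i_drive)
    return target + (ca - target) * ag.exp(-dt / spec.tau)


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------

def _linoid(x, scale):
    """x / (1 - exp(-x/scale)), with the removable singularity at x = 0
    replaced by its Taylor expansion (both branches finite, so reverse-mode
    gradients stay defined)."""
    u = x / scale
    near = np.abs(np.real(value_of(u))) < 1e-4
    u_safe = ag.where(near, 1.0, u)
    raw = scale * u_safe / (-ag.expm1(-u_safe))
    series = scale * (1.0 + u / 2.0 + u * u / 12.0)
    return ag.where(near, series, raw)


def hh_rates(v):
    """Classic Hodgkin–Huxley α/β rates (1/ms) for gates m, h, n at V (mV)."""
    alpha_m = 0.1 * _linoid(v + 40.0, 10.0)
    beta_m = 4.0 * ag.exp(-(v + 65.0) / 18.0)
    alpha_h = 0.07 * ag.exp(-(v + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + ag.exp(-(v + 35.0) / 10.0))
    alpha_n = 0.01 * _linoid(v + 55.0, 10.0)
    beta_n = 0.125 * ag.exp(-(v + 65.0) / 80.0)
    return {
        "m": (alpha_m, beta_m),
        "h": (alpha_h, beta_h),
        "n": (alpha_n, beta_n),
    }


def standard_hh_channels() -> dict[str, ChannelSpec]:
    """The default Na/K/leak channel kit."""

    def na_rates(gate):
        def f(v):
            return hh_rates(v)[gate]

        return f

    na = ChannelSpec(
        "na", gbar=0.12, e_rev=50.0,
        exponents={"m": 3, "h": 1},
        rates={"m": na_rates("m"), "h": na_rates("h")},
        rate_fn=hh_rates,
    )
    k = ChannelSpec(
        "k", gbar=0.036, e_rev=-77.0,
        exponents={"n": 4}, rates={"n": na_rates("n")},
        rate_fn=hh_rates,
    )
    leak = ChannelSpec("leak", gbar=0.0003, e_rev=-54.3)
    return {"na": na, "k": k, "leak": leak}


CHANNEL_REGISTRY = standard_hh_channels


# ---------------------------------------------------------------------------
# gate integration
# ---------------------------------------------------------------------------

def gate_steady_state(spec: ChannelSpec, v, rate_table=None):
    """x_inf and tau per gate at voltage ``v``.

    ``rate_table`` lets callers reuse an already-evaluated α/β table
    (from ``spec.rate_fn``) instead of per-gate evaluation.
    """
    if rate_table is None and spec.rate_fn is not None:
        rate_table = spec.rate_fn(v)
    out = {}
    for gate in spec.gates:
        alpha, beta = (
            rate_table[gate] if rate_table is not None
            else spec.rates[gate](v)
        )
        total = alpha + beta
        out[gate] = (alpha / total, 1.0 / total)
    return out


def gate_step_exponential(x, x_inf, tau, dt):
    """Exponential-Euler update x' = x_inf + (x - x_inf)·exp(-dt/tau)."""
    if np.any(np.real(np.asarray(value_of(tau))) <= 0):
        raise ValueError("tau must be > 0")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return x_inf + (x - x_inf) * ag.exp(-dt / tau)


def channel_open_fraction(spec: ChannelSpec, gates):
    """∏ gate^exponent (1.0 for gateless channels such as leak)."""
    open_frac = 1.0
    for gate, p in spec.exponents.items():
        if p == 0:
            continue
        g = gates[gate]
        term = g
        for _ in range(p - 1):
            term = term * g
        open_frac = open_frac * term
    return open_frac


def channel_current_density(spec: ChannelSpec, gates, v):
    """Membrane current density i = ḡ·(∏ gate^p)·(V − E) in mA/cm²
    (ḡ in S/cm², V in mV: S/cm²·mV = mA/cm²)."""
    return spec.gbar * channel_open_fraction(spec, gates) * (v - spec.e_rev)


# ---------------------------------------------------------------------------
# synapses
# ---------------------------------------------------------------------------

def synapse_steady_state(v_pre, spec: SynapseSpec):
    """Saturating logistic steady-state activation s̄(V_pre)."""
    return ag.sigmoid((v_pre - spec.v_th) / spec.v_slope)


def synapse_step(s, v_pre, spec: SynapseSpec, dt, k_minus=None):
    """Advance the activation by exponential Euler of the Abbott–Marder
    kinetics ds/dt = (s̄ − s)/τ_s with τ_s = (1 − s̄)/k₋."""
    km = spec.k_minus if k_minus is None else k_minus
    if np.any(np.real(np.asarray(value_of(km))) <= 0):
        raise ValueError("k_minus must be > 0")
    s_bar = synapse_steady_state(v_pre, spec)
    tau = (1.0 - s_bar) / km
    # the logistic keeps s̄ < 1, so tau > 0; guard against underflow anyway
    tau = ag.where(np.real(np.asarray(value_of(tau))) < 1e-12, 1e-12, tau)
    return s_bar + (s - s_bar) * ag.exp(-dt / tau)


def synapse_current(s, v_post, spec: SynapseSpec, g_syn=None):
    """I = g_syn·s·(V_post − E_syn) in nA (g_syn in nS, V in mV)."""
    g = spec.g_syn if g_syn is None else g_syn
    return g * 1e-3 * s * (v_post - spec.e_syn)
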