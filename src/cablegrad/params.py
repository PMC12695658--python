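"""Named, bounded, trainable parameter collections.

Optimization never happens on physical values directly: every entry carries
box bounds ``(l, u)`` and is optimized in unconstrained space through the
inverse-sigmoid transform

    T(θ) = -log(1/((θ - l)/(u - l)) - 1),

whose inverse maps all reals back into ``(l, u)``, so gradient steps can
never produce out-of-bounds biophysics.  Entries carry a *group* label; the
normalized-gradient optimizer computes its norm per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ag
from .autodiff import value_of

__all__ = [
    "to_unconstrained",
    "from_unconstrained",
    "ParamEntry",
    "ParameterView",
]

QUANTITIES = {
    "channel_gbar",  # S/cm², per channel node
    "g_syn",  # nS, per synapse
    "k_minus",  # 1/ms, per synapse
    "radius",  # μm, per node
    "length",  # μm, per node
    "ra",  # Ω·cm, per node
    "input_weight",  # dimensionless, per stimulus
}


def to_unconstrained(theta, lower, upper):
    """Inverse-sigmoid transform of θ ∈ (l, u) to the real line."""
    theta_v = np.asarray(value_of(theta), dtype=float)
    if np.any(theta_v <= lower) or np.any(theta_v >= upper):
        raise ValueError(
            "parameter value on or outside its bounds; initialize strictly "
            "inside (l, u)"
        )
    frac = (theta - lower) / (upper - lower)
    return -ag.log(1.0 / frac - 1.0)


def from_unconstrained(t, lower, upper):
    """Map any real t back into (l, u): θ = l + (u - l)·σ(t)."""
    return lower + (upper - lower) * ag.sigmoid(t)


@dataclass
class ParamEntry:
    name: str
    quantity: str
    target: np.ndarray  # indices (meaning depends on quantity/channel)
    value: np.ndarray  # physical values, one per trainable scalar
    lower: np.ndarray
    upper: np.ndarray
    group: str
    channel: str | None = None  # for channel_gbar
    tie: np.ndarray | None = None  # target i takes value[tie[i]]; default 1:1

    def __post_init__(self):
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        self.target = np.atleast_1d(np.asarray(self.target, dtype=int))
        if self.tie is None:
            self.tie = np.arange(self.target.size)
            n_par = self.target.size
        else:
            self.tie = np.asarray(self.tie, dtype=int)
            if self.tie.shape != self.target.shape:
                raise ValueError(f"{self.name}: tie must match target shape")
            n_par = int(self.tie.max()) + 1
        self.value = np.broadcast_to(
            np.asarray(self.value, dtype=float), (n_par,)
        ).copy()
        self.lower = np.broadcast_to(
            np.asarray(self.lower, dtype=float), (n_par,)
        ).copy()
        self.upper = np.broadcast_to(
            np.asarray(self.upper, dtype=float), (n_par,)
        ).copy()
        if np.any(self.lower >= self.upper):
            raise ValueError(f"{self.name}: need l < u")
        if np.any(self.value <= self.lower) or np.any(self.value >= self.upper):
            raise ValueError(f"{self.name}: values must lie strictly in (l, u)")

    def spread(self, val):
        """Per-target values (applies the tie map)."""
        from . import autodiff as _ag

        return _ag.take(val, self.tie)


class ParameterView:
    """An ordered collection of bounded parameter entries."""

    def __init__(self):
        self.entries: dict[str, ParamEntry] = {}

    def add(self, name, quantity, target, value, bounds, group=None,
            channel=None, tie=None) -> "ParameterView":
        if name in self.entries:
            raise ValueError(f"duplicate entry {name!r}")
        lower, upper = bounds
        self.entries[name] = ParamEntry(
            name=name, quantity=quantity, target=target, value=value,
            lower=lower, upper=upper, group=group or name, channel=channel,
            tie=tie,
        )
        return self

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self):
        return len(self.entries)

    @property
    def n_parameters(self) -> int:
        return int(sum(e.value.size for e in self))

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for e in self:
            out.setdefault(e.group, []).append(e.name)
        return out

    # -- transforms ---------------------------------------------------------
    def to_unconstrained(self) -> dict[str, np.ndarray]:
        return {
            e.name: np.asarray(
                value_of(to_unconstrained(e.value, e.lower, e.upper))
            )
            for e in self
        }

    def physical(self, unconstrained: dict) -> dict:
        """Physical values (Tensor-valued if inputs are Tensors)."""
        out = {}
        for e in self:
            out[e.name] = from_unconstrained(
                unconstrained[e.name], e.lower, e.upper
            )
        return out

    def set_unconstrained(self, unconstrained: dict) -> None:
        """Write optimized unconstrained values back as physical values."""
        for e in self:
            e.value = np.asarray(
                value_of(from_unconstrained(
                    unconstrained[e.name], e.lower, e.upper
                )),
                dtype=float,
            )

    def copy(self) -> "ParameterView":
        pv = ParameterView()
        for e in self:
            pv.add(e.name, e.quantity, e.target.copy(), e.value.copy(),
                   (e.lower.copy(), e.upper.copy()), group=e.group,
                   channel=e.channel, tie=e.tie.copy())
        return pv

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            e.name: {
                "quantity": e.quantity,
                "channel": e.channel,
                "target": e.target.tolist(),
                "tie": e.tie.tolist(),
                "value": e.value.tolist(),
                "lower": e.lower.tolist(),
                "upper": e.upper.tolist(),
                "group": e.group,
            }
            for e in self
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterView":
        pv = cls()
        for name, e in d.items():
            pv.add(name, e["quantity"], np.asarray(e["target"]),
                   np.asarray(e["value"]),
                   (np.asarray(e["lower"]), np.asarray(e["upper"])),
                   group=e["group"], channel=e.get("channel"),
                   tie=np.asarray(e["tie"]) if e.get("tie") is not None
                   else None)
        return pv
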