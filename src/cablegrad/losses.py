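"""Differentiable losses between simulated and target traces.

All losses are composed of :mod:`cablegrad.autodiff` primitives so they can
seed backpropagation through the solver.  Included:

* windowed mean/std summary statistics with fixed standardization divisors
  (means by 8.0, standard deviations by 4.0) and a mean-absolute-error loss
  on the standardized vector — the smooth substitute for non-differentiable
  spike features when fitting somatic recordings;
* a soft dynamic-time-warping discrepancy with cost
  ``c(x_i, y_j) = |x_i − y_j| + |i − j|`` over a sliding-window-max-reduced
  time axis, for spiking traces where small temporal misalignment should
  not be over-penalized;
* a cross-entropy readout loss on window-mean voltages for task training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ag
from .autodiff import value_of

__all__ = [
    "WindowSpec",
    "SoftDTWConfig",
    "window_summary_stats",
    "mae_loss",
    "sliding_window_max",
    "soft_dtw",
    "readout_cross_entropy",
    "rescale_to_unit",
    "LOSS_REGISTRY",
]


@dataclass
class WindowSpec:
    """Time windows (ms) plus the fixed standardization divisors."""

    windows: list[tuple[float, float]]
    mean_divisor: float = 8.0
    std_divisor: float = 4.0


def window_summary_stats(trace, spec: WindowSpec):
    """Standardized (mean, std) per window, concatenated in window order.

    Means are divided by ``spec.mean_divisor`` (8.0), standard deviations by
    ``spec.std_divisor`` (4.0); the result has length 2 × n_windows per
    recorded site and is differentiable in the trace.
    """
    times = np.asarray(trace.times)
    vals = trace.values
    out = []
    for (a, b) in spec.windows:
        sel = np.flatnonzero((times >= a - 1e-9) & (times <= b + 1e-9))
        if sel.size == 0:
            raise ValueError(f"empty window ({a}, {b}) ms")
        seg = ag.take(vals, (slice(None), sel)) if ag.is_tensor(vals) \
            else vals[:, sel]
        mu = ag.amean(seg, axis=1)
        var = ag.amean((seg - ag.reshape(mu, (-1, 1))) ** 2, axis=1)
        sd = ag.sqrt(var + 1e-24)
        out.append(mu / spec.mean_divisor)
        out.append(sd / spec.std_divisor)
    return ag.concatenate(out)


def mae_loss(a, b):
    """Mean absolute error between equal-length vectors/arrays."""
    av, bv = value_of(a), value_of(b)
    if np.shape(av) != np.shape(bv):
        raise ValueError(
            f"shape mismatch {np.shape(av)} vs {np.shape(bv)}"
        )
    return ag.amean(ag.absolute(a - b))


def rescale_to_unit(reference, *others):
    """Affine-map ``reference`` to [0, 1]; apply the *same* factors to all.

    The scaling provenance is shared: min/max come from ``reference`` only,
    so simulated and observed traces are compared on a common scale.
    """
    ref = np.asarray(value_of(reference), dtype=float)
    lo, hi = float(ref.min()), float(ref.max())
    span = hi - lo if hi > lo else 1.0
    scaled = [(reference - lo) / span] + [(o - lo) / span for o in others]
    return scaled if others else scaled[0]


def sliding_window_max(series, window: int, stride: int, smooth_temp=None):
    """Windowed maximum reduction: element k = max over
    [k·stride, k·stride + window); output length floor((n−window)/stride)+1.

    With ``smooth_temp`` set, a log-sum-exp soft maximum at that temperature
    is used instead of the hard max (useful when gradients must pass through
    the reduction without the argmax subgradient).
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    n = int(np.shape(value_of(series))[-1])
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    starts = range(0, n - window + 1, stride)
    cols = []
    for s in starts:
        seg = series[s:s + window] if not ag.is_tensor(series) \
            else ag.take(series, np.arange(s, s + window))
        if smooth_temp is None:
            cols.append(ag.amax(seg))
        else:
            cols.append(smooth_temp * ag.logsumexp(seg / smooth_temp))
    return ag.stack(cols)


@dataclass
class SoftDTWConfig:
    """Soft-DTW smoothing and preprocessing settings.

    Defaults follow the spiking-trace recipe: window-max reduction with
    window 50 steps / stride 30 steps, shared rescale to the unit interval,
    and the cost ``|x_i − y_j| + |i − j|`` on the reduced index axis.
    """

    gamma: float = 1.0
    window: int = 50
    stride: int = 30
    rescale: bool = True
    index_penalty: float = 1.0
    smooth_temp: float | None = None  # soft max for the simulated trace

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("soft-DTW smoothing gamma must be > 0")
        if self.window < self.stride or self.stride < 1:
            raise ValueError("need window >= stride >= 1")


def _softmin3(a, b, c, gamma):
    stacked = ag.stack([a, b, c])
    return -gamma * ag.logsumexp(-stacked / gamma)


def soft_dtw(x, y, cfg: SoftDTWConfig | None = None, preprocess=False):
    """Soft dynamic-time-warping discrepancy between two 1D sequences.

    DP recursion R_{i,j} = c(x_i, y_j) + softmin_γ(R_{i−1,j}, R_{i,j−1},
    R_{i−1,j−1}) with softmin_γ(a, …) = −γ·log Σ exp(−a/γ) and cost
    c = |x_i − y_j| + |i − j|.  With ``preprocess`` the sliding-window-max
    reduction and shared unit-interval rescaling are applied first (``y`` is
    treated as the observation: hard max and scaling reference).
    """
    cfg = cfg or SoftDTWConfig()
    if preprocess:
        y = sliding_window_max(y, cfg.window, cfg.stride)
        x = sliding_window_max(x, cfg.window, cfg.stride,
                               smooth_temp=cfg.smooth_temp)
        y, x = rescale_to_unit(y, x)
    n = int(np.shape(value_of(x))[-1])
    m = int(np.shape(value_of(y))[-1])
    if n == 0 or m == 0:
        raise ValueError("soft_dtw needs non-empty sequences")
    big = 1e10
    prev = [None] * (m + 1)  # R_{i-1, :}
    for j in range(m + 1):
        prev[j] = 0.0 if j == 0 else big
    for i in range(1, n + 1):
        cur = [big] * (m + 1)
        xi = x[i - 1]
        for j in range(1, m + 1):
            cost = ag.absolute(xi - y[j - 1]) + cfg.index_penalty * abs(i - j)
            cur[j] = cost + _softmin3(prev[j], cur[j - 1], prev[j - 1],
                                      cfg.gamma)
        prev = cur
    return prev[m]


def readout_cross_entropy(trace, label: int, window: tuple[float, float],
                          sites=None, affine=(0.0, 1.0)):
    """Cross-entropy of softmax readout logits against a class label.

    Logits are the window-mean voltages of the readout sites, passed through
    the affine map ``(v + shift) · scale`` (e.g. shift 65, scale 1/3 for the
    (v+65)/3 convention); loss = −log softmax(logits)[label].
    """
    times = np.asarray(trace.times)
    a, b = window
    sel = np.flatnonzero((times >= a - 1e-9) & (times <= b + 1e-9))
    if sel.size == 0:
        raise ValueError(f"response window ({a}, {b}) ms outside trace")
    vals = trace.values
    rows = np.arange(np.shape(value_of(vals))[0]) if sites is None \
        else np.asarray(sites)
    if rows.size < 2:
        raise ValueError("need at least two readout sites")
    if not (0 <= label < rows.size):
        raise ValueError(f"label {label} out of range for {rows.size} classes")
    seg = ag.take(vals, (rows[:, None], sel[None, :]))
    shift, scale = affine
    logits = (ag.amean(seg, axis=1) + shift) * scale
    return ag.logsumexp(logits) - logits[label]


LOSS_REGISTRY = {
    "mae": mae_loss,
    "summary_mae": window_summary_stats,
    "soft_dtw": soft_dtw,
    "readout_cross_entropy": readout_cross_entropy,
}
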