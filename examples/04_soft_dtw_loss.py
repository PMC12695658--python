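"""Soft dynamic-time-warping discrepancy between spiking traces.

Soft-DTW aligns two voltage traces in time before measuring pointwise
differences, so a small spike-timing shift costs little compared with the
pointwise error.  The example compares a trace against a time-shifted copy
under both losses, using the sliding-window-max preprocessing (window 50
steps, stride 30 steps) and shared unit-interval rescaling.
"""

import numpy as np

from cablegrad import SoftDTWConfig, mae_loss, soft_dtw
from cablegrad.autodiff import value_of

# two synthetic "spike trains": same shape, 25-step timing shift
t = np.arange(1200) * 0.025
spike = lambda mu: -65.0 + 100.0 * np.exp(-0.5 * ((t - mu) / 0.4) ** 2)
x = spike(10.0) + spike(20.0)
y = spike(10.625) + spike(20.625)

cfg = SoftDTWConfig(gamma=1.0, window=50, stride=30)
d_aligned = float(value_of(soft_dtw(x, y, cfg, preprocess=True)))
d_self = float(value_of(soft_dtw(x, x, cfg, preprocess=True)))
pointwise = float(value_of(mae_loss(x, y)))

print(f"pointwise MAE (raw traces)      : {pointwise:.3f} mV")
print(f"soft-DTW discrepancy (shifted)  : {d_aligned:.4f}")
print(f"soft-DTW discrepancy (identical): {d_self:.4f}")
print(f"soft-DTW excess over self-floor : {d_aligned - d_self:.4f}")
print("At this smoothing the soft minimum carries a negative entropic")
print("offset, so the meaningful number is the excess over the")
print("self-discrepancy floor: it stays small because soft-DTW warps the")
print("misaligned spikes onto each other, while the pointwise error is")
print("large — the property that makes it a robust loss for spiking")
print("recordings.")
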