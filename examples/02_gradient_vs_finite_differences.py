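"""Differentiate a simulation and check it against finite differences.

The loss is the somatic voltage at the end of a passive simulation; its
gradient with respect to the (bounded) leak conductance is computed by
reverse-mode differentiation through the implicit-Euler solver and compared
against the central-difference oracle.
"""

import numpy as np

from cablegrad import (
    ChannelSpec,
    NetworkModel,
    ParameterView,
    StepCurrent,
    Section,
    build_cell_from_sections,
    finite_difference_gradient,
    loss_gradient,
)

model = NetworkModel()
model.add_cell(build_cell_from_sections([Section("soma", 20.0, 10.0, 1)]))
model.insert_channel(0, ChannelSpec("leak", gbar=0.0003, e_rev=-54.3))
model.stimulate(StepCurrent(0, 0, 0.0, 50.0, 0.05))
model.record(0, 0)

params = ParameterView()
params.add("g_leak", "channel_gbar", target=[0], value=0.0003,
           bounds=(1e-5, 1e-2), channel="leak")


def loss(trace):
    return trace.values[0, -1]  # V_soma(t_max)


res = loss_gradient(model, loss, params, t_max=10.0, dt=0.025)
fd = finite_difference_gradient(model, loss, params, t_max=10.0, dt=0.025)

rel = abs(res.grads["g_leak"][0] - fd["g_leak"][0]) / abs(fd["g_leak"][0])
print(f"loss (V at 10 ms)        : {res.value:.4f} mV")
print(f"reverse-mode gradient    : {res.grads['g_leak'][0]:.6f}")
print(f"finite-difference oracle : {fd['g_leak'][0]:.6f}")
print(f"relative error           : {rel:.2e}")
print("Both numbers are d(loss)/d(unconstrained leak): agreement to ~1e-9")
print("confirms the hand-written adjoint of the solver.")
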