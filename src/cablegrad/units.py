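"""Unit system and conversion constants.

Fixed conventions used throughout the package (validated by the passive
analytic tests in the suite):

================  =========  ==========================================
quantity          unit       notes
================  =========  ==========================================
voltage           mV
time              ms
length / radius   μm
membrane ḡ        S/cm²      specific conductance
capacitance Cm    μF/cm²     specific capacitance
axial Ra          Ω·cm       intracellular resistivity
injected current  nA         also synaptic currents
synaptic g        nS
axial resistance  MΩ         1/MΩ = μS
================  =========  ==========================================

With these choices the discrete cable equation is expressed with per-node
capacitance in nF and conductances in μS, so that ``μS × mV = nA`` and
``nF / ms = μS`` hold without further factors.
"""

import numpy as np

# area: μm² -> cm² is 1e-8; capacitance C = Cm[μF/cm²]·A[cm²] in μF,
# ×1e3 to nF
CAP_NF_PER_UM2 = 1e-8 * 1e3  # Cm [μF/cm²] · A [μm²] · this = C [nF]

# membrane conductance: ḡ[S/cm²]·A[cm²] in S, ×1e6 to μS
GMEM_US_PER_UM2 = 1e-8 * 1e6  # ḡ [S/cm²] · A [μm²] · this = g [μS]

# half-compartment axial resistance in MΩ:
#   R/2 = Ra[Ω·cm] · (l/2)[cm] / (π a² [cm²]) / 1e6
#       = 0.01 · Ra · (l/2) / (π a²)   with l, a in μm
AXIAL_MOHM_FACTOR = 0.01

NS_TO_US = 1e-3  # synaptic conductances are specified in nS


def capacitance_nF(area_um2, cm_uF_per_cm2):
    return cm_uF_per_cm2 * area_um2 * CAP_NF_PER_UM2


def membrane_conductance_uS(gbar_S_per_cm2, area_um2):
    return gbar_S_per_cm2 * area_um2 * GMEM_US_PER_UM2


def half_axial_resistance_MOhm(ra_ohm_cm, length_um, radius_um):
    return AXIAL_MOHM_FACTOR * ra_ohm_cm * (length_um / 2.0) / (
        np.pi * radius_um**2
    )
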