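"""Unit conventions and conversions.

Internal unit system
--------------------
The flow solver works in CGS: lengths in cm, areas in cm2, velocities in
cm/s, density in g/cm3, viscosity in poise, pressure in dyn/cm2, and the
wall-elasticity parameter ``beta`` in dyn/cm3. The left-ventricle model and
all reports use mmHg for pressure and mL (= cm3) for volume. The thermal
model uses W, J, g, cm and degC throughout, so conductivities are in
W/(cm*degC) and volumetric sources in W/cm3.

Every conversion used anywhere in the package goes through the constants in
this module so there is exactly one place where unit bugs can live.
"""

MMHG_TO_DYN = 1333.22368  # 1 mmHg in dyn/cm2
DYN_TO_MMHG = 1.0 / MMHG_TO_DYN

M_PER_S_TO_CM_PER_S = 100.0
CM_PER_S_TO_M_PER_S = 0.01

KCAL_PER_MIN_TO_W = 69.78  # 4186.8 J/kcal / 60 s

W_PER_M2K_TO_W_PER_CM2K = 1e-4
W_PER_MK_TO_W_PER_CMK = 1e-2

CM2_TO_M2 = 1e-4

# Resistance: mmHg*s/mL <-> dyn*s/cm5 (mL == cm3)
MMHG_S_PER_ML_TO_CGS = MMHG_TO_DYN


def mmhg(p_dyn: float) -> float:
    """dyn/cm2 -> mmHg."""
    return p_dyn * DYN_TO_MMHG


def dyn(p_mmhg: float) -> float:
    """mmHg -> dyn/cm2."""
    return p_mmhg * MMHG_TO_DYN
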