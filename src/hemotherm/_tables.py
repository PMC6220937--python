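"""Reference data tables for the ageing haemodynamics/bioheat model.

Age-indexed tables hold one row per decade; lookups elsewhere interpolate
linearly between decades and clamp outside the tabulated range. Body-segment
tables are keyed by segment *type* (limb segments are instantiated twice).
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Pulse-wave-velocity fitting coefficients per decade:
# c [m/s] = a_bar * d[mm] ** (-b_bar)   (inverse diameter relationship)
# ---------------------------------------------------------------------------
PWV_FIT_ROWS: dict[int, tuple[float, float]] = {
    30: (15.48, 0.502),
    40: (15.59, 0.458),
    50: (16.33, 0.447),
    60: (16.68, 0.428),
    70: (15.91, 0.372),
    80: (15.29, 0.345),
}

# ---------------------------------------------------------------------------
# Left-ventricle reference data per decade:
# (E_LV_max mmHg/mL, E_LV_min mmHg/mL, p_ED mmHg, HR bpm)
# ---------------------------------------------------------------------------
LV_ROWS: dict[int, tuple[float, float, float, float]] = {
    20: (1.00, 0.02500, 4.134, 73.3),
    30: (1.03, 0.02575, 4.410, 73.3),
    40: (1.09, 0.02725, 4.687, 72.1),
    50: (1.16, 0.02750, 4.964, 70.9),
    60: (1.24, 0.03100, 5.240, 69.7),
    70: (1.35, 0.03375, 5.517, 68.5),
    80: (1.51, 0.03755, 5.794, 67.3),
}

# ---------------------------------------------------------------------------
# Tissue-variation regression coefficients: ratio(age) = a + b*age (+ c*age^2)
# keyed by quantity; reference age xi0 recorded for documentation.
# ---------------------------------------------------------------------------
TISSUE_FITS: dict[str, dict] = {
    "muscle_limb": {"a": 1.070122, "b": -0.003506, "c": 0.0, "xi0": 20.0},
    "muscle_abdomen": {"a": 1.14687, "b": -0.00607, "c": 0.0, "xi0": 24.2},
    "fat_general": {"a": 1.05938, "b": -0.002969, "c": 0.0, "xi0": 20.0},
    "fat_abdomen": {"a": 0.87139, "b": -0.005314, "c": 0.0, "xi0": 24.2},
    "skin": {"a": 1.01026, "b": -0.000513, "c": 0.0, "xi0": 20.0},
    "bone_density": {"a": 0.95086, "b": 0.00443, "c": -6.620e-5, "xi0": 20.0},
    "metabolic": {"a": 1.152, "b": -0.008897, "c": 5.596e-5, "xi0": 20.0},
}

# Body weight [kg] and resting metabolic rate [kcal/min] quadratics in age.
BW_COEFFS = (51.64, 1.328, -0.01384)
RMR_COEFFS = (1.134, 0.008, -0.00013)

# Bone conductivity [W/(m K)] as a quadratic in bone density [g/cm3].
BONE_K_COEFFS = (0.0343, 0.9935, -0.5305)

# Cutaneous min/max flow attenuation: factor(age) = a + b*age
CUTANEOUS_FLOW_FIT = (1.198, -0.007677)

# Terminal-resistance ratio R_T/R_T0 models (reference age 20 y).
TERMINAL_MODELS: dict[str, tuple[float, ...]] = {
    "maksuti": (0.9, 0.005),
    "pagoulatou": (0.7722, 0.009365, -6.149e-5),
}

# ---------------------------------------------------------------------------
# Thermoregulation thresholds (young-adult baseline, degC)
# ---------------------------------------------------------------------------
T_DIL_LOW = 36.8
T_DIL_UPP = 37.2
T_CON_LOW = 27.8
T_CON_UPP = 33.7

# Decline of thermal sensitivity with age: (skin step, core step) in degC.
# Bands change exactly at 50, 65 and 70 years.
SENSITIVITY_DECLINE_BANDS = [
    (50.0, 0.0, 0.0),   # below 50
    (65.0, 1.5, 0.6),   # 50-65
    (70.0, 1.5, 0.6),   # 65-70
    (float("inf"), 1.5, 0.4),  # above 70
]

SHIVER_RATE_PRINTED = -0.031   # degC per year (printed value)
SHIVER_RATE_SESSLER = -0.029   # degC per year (recomputed from quoted points)

# ---------------------------------------------------------------------------
# Body-segment coefficient tables. `mult` is the number of instances of the
# segment in the 14-cylinder body (limbs are counted per-limb here; the
# sweating/shivering coefficient tables were already divided by the
# multiplicity where the source lumped limbs together).
# ---------------------------------------------------------------------------
SEGMENT_TYPES = [
    "head", "neck", "thorax", "abdomen",
    "shoulder", "arm", "forearm", "thigh", "leg",
]
SEGMENT_MULT = {
    "head": 1, "neck": 1, "thorax": 1, "abdomen": 1,
    "shoulder": 2, "arm": 2, "forearm": 2, "thigh": 2, "leg": 2,
}

# Sweating distribution coefficients alpha_swe and chi.
ALPHA_SWE = {
    "head": 0.149, "neck": 0.042, "thorax": 0.101, "abdomen": 0.181,
    "shoulder": 0.0185, "arm": 0.0455, "forearm": 0.0455,
    "thigh": 0.077, "leg": 0.077,
}
CHI_SWE = {
    "head": 1.0, "neck": 1.0, "thorax": 1.0, "abdomen": 1.0,
    "shoulder": 1.0, "arm": 1.0, "forearm": 1.0,
    "thigh": 0.6, "leg": 0.6,
}

# Cutaneous perfusion coefficients [cm3/s] per segment instance.
# As printed, the "max" column holds zeros and the "min" column the largest
# values; the package swaps them by default (see regulation module).
SKIN_FLOW_PRINTED = {
    # segment: (m_sk_0, printed_max, printed_min)
    "head": (1.681, 1.255, 4.598),
    "neck": (1.681, 1.255, 4.598),       # neck assumed equal to head
    "thorax": (0.956, 0.0, 9.235),
    "shoulder": (0.956, 0.0, 9.235),     # shoulder assumed equal to thorax
    "abdomen": (0.631, 0.0, 6.098),
    "arm": (0.253, 0.0, 2.311),
    "forearm": (0.141, 0.0, 1.543),
    "thigh": (0.404, 0.0, 3.459),
    "leg": (0.181, 0.0, 2.293),
}

# Shivering distribution coefficients alpha_shiv per segment instance.
ALPHA_SHIV = {
    "head": 0.01, "neck": 0.01, "thorax": 0.257, "abdomen": 0.364,
    "shoulder": 0.117, "arm": 0.0125, "forearm": 0.0125,
    "thigh": 0.022, "leg": 0.016,
}

# ---------------------------------------------------------------------------
# 14-cylinder body geometry at the reference age (30 y).
# Layers listed inside-out with their OUTER radius [cm]; innermost starts
# at r = 0. Lengths in cm. Limb rows are per limb.
# ---------------------------------------------------------------------------
BODY_GEOMETRY = {
    "head": {
        "layers": [("brain", 6.6), ("bone", 7.6), ("fat", 7.8), ("skin", 8.0)],
        "length": 23.5,
    },
    "neck": {
        "layers": [("bone", 1.9), ("muscle", 5.4), ("fat", 5.6), ("skin", 5.8)],
        "length": 7.9,
    },
    "shoulder": {
        "layers": [("bone", 3.7), ("muscle", 3.9), ("fat", 4.4), ("skin", 4.6)],
        "length": 13.4,
    },
    "arm": {
        "layers": [("bone", 1.5), ("muscle", 3.4), ("fat", 4.0), ("skin", 4.2)],
        "length": 29.6,
    },
    "forearm": {
        "layers": [("bone", 1.5), ("muscle", 3.4), ("fat", 4.0), ("skin", 4.2)],
        "length": 23.7,
    },
    "thorax": {
        "layers": [("lung", 7.7), ("bone", 8.9), ("muscle", 12.3),
                   ("fat", 12.6), ("skin", 12.9)],
        "length": 15.6,
    },
    "abdomen": {
        "layers": [("viscera", 7.9), ("bone", 8.3), ("muscle", 10.9),
                   ("fat", 12.4), ("skin", 12.6)],
        "length": 24.8,
    },
    "thigh": {
        "layers": [("bone", 2.2), ("muscle", 4.8), ("fat", 5.3), ("skin", 5.5)],
        "length": 58.5,
    },
    "leg": {
        "layers": [("bone", 2.2), ("muscle", 4.8), ("fat", 5.3), ("skin", 5.5)],
        "length": 34.3,
    },
}

# ---------------------------------------------------------------------------
# Default tissue thermophysical properties (literature-style values).
#   k   : thermal conductivity  W/(cm degC)
#   rho : density               g/cm3
#   c   : specific heat         J/(g degC)
#   qv0 : basal metabolic source, RELATIVE weight (normalised at body build
#         so whole-body basal production matches the RMR regression)
#   phi : basal perfusion rate  1/s
# Bone k is recomputed from bone density at build time; the value below is
# the young-adult starting point.
# ---------------------------------------------------------------------------
TISSUE_PROPERTIES = {
    "brain":   {"k": 0.0049, "rho": 1.08, "c": 3.85, "qv0": 0.0134, "phi": 0.0088},
    "lung":    {"k": 0.0028, "rho": 0.55, "c": 3.72, "qv0": 0.0006, "phi": 0.0040},
    "viscera": {"k": 0.0053, "rho": 1.00, "c": 3.70, "qv0": 0.0041, "phi": 0.0040},
    "bone":    {"k": 0.0050, "rho": 1.36, "c": 1.70, "qv0": 0.0004, "phi": 3.0e-5},
    "muscle":  {"k": 0.0042, "rho": 1.085, "c": 3.77, "qv0": 0.0007, "phi": 5.4e-4},
    "fat":     {"k": 0.0016, "rho": 0.85, "c": 2.30, "qv0": 0.00006, "phi": 3.6e-5},
    "skin":    {"k": 0.0047, "rho": 1.085, "c": 3.68, "qv0": 0.0004, "phi": None},
}
# skin phi is segment-specific: basal cutaneous flow / segment skin mass.

BONE_DENSITY_YOUNG = 1.36  # g/cm3, reference bone density fed to the k fit

BLOOD_RHO = 1.06      # g/cm3
BLOOD_CP = 3.9        # J/(g degC)
BLOOD_MU = 0.035      # poise
BLOOD_ALPHA = 0.0121  # cm2/s, thermal diffusivity
H_IN = 0.1            # W/(degC cm2), inner-wall heat transfer coefficient
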