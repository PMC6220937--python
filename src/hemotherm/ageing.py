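"""Age-dependent parameter laws.

Every age dependency used by the flow, heart, tissue and regulation modules
is computed here, so that the rest of the package is age-agnostic: a single
:class:`AgeingParameters` object carries all scalars and scalings for one
age ``xi`` (in years).

The laws are regression fits against age:

* pulse-wave velocity vs. arterial diameter, one (a, b) pair per decade,
  ``c = a * d**(-b)`` with d in mm and c in m/s;
* a uniform wall-stiffening rule in which the intrinsic wave speed doubles
  linearly from 20 to 80 years, so compliance falls by a factor 4;
* terminal-resistance growth (two selectable literature models);
* left-ventricle elastance/heart-rate decade table;
* linear/quadratic tissue-thickness, bone-density and metabolic-rate fits;
* cutaneous-flow attenuation and thermoregulatory threshold shifts.

Decade tables are interpolated linearly in age and clamped outside their
tabulated range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _tables as tbl

logger = logging.getLogger(__name__)

SCALING_FLOOR = 1e-3  # clamp for extreme extrapolations of linear fits


def _interp_decades(xi: float, rows: dict[int, tuple]) -> tuple:
    """Linear interpolation between decade rows, clamped at the ends."""
    ages = np.array(sorted(rows))
    cols = np.array([rows[a] for a in ages], dtype=float)
    xi_c = float(np.clip(xi, ages[0], ages[-1]))
    return tuple(float(np.interp(xi_c, ages, cols[:, j]))
                 for j in range(cols.shape[1]))


# ---------------------------------------------------------------------------
# Arterial stiffness
# ---------------------------------------------------------------------------

def pwv_from_diameter(d_mm: float, xi: float, *,
                      pwv_exponent_sign: int = -1) -> float:
    """Pulse wave velocity [m/s] from diameter [mm] at age ``xi``.

    The empirical fit is an inverse diameter relationship,
    ``c = a(xi) * d**(-b(xi))``; ``pwv_exponent_sign=+1`` selects the
    literal positive-exponent form (non-physiological, kept for audit).
    Ages outside [30, 80] are clamped to the nearest tabulated decade.
    """
    if d_mm <= 0:
        raise ValueError(f"diameter must be positive, got {d_mm}")
    a, b = _interp_decades(xi, tbl.PWV_FIT_ROWS)
    return a * d_mm ** (pwv_exponent_sign * b)


def uniform_beta_factor(xi: float, xi_ref: float) -> float:
    """Multiplicative factor on the wall parameter beta for uniform ageing.

    Assumes the intrinsic wave speed grows linearly from c0 at 20 y to 2*c0
    at 80 y with the unstressed area fixed; since c^2 is proportional to
    beta, the factor is ``(c(xi)/c(xi_ref))**2``.  It equals 4 for
    (80, 20) — the compliance-quartering rule.
    """
    def c_rel(age: float) -> float:
        return 1.0 + (age - 20.0) / 60.0

    return (c_rel(xi) / c_rel(xi_ref)) ** 2


def terminal_resistance_factor(xi: float, model: str = "maksuti") -> float:
    """Terminal resistance ratio R_T/R_T0 relative to the 20-year baseline."""
    try:
        coeffs = tbl.TERMINAL_MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown terminal model {model!r}; expected one of "
            f"{sorted(tbl.TERMINAL_MODELS)}") from None
    return float(sum(c * xi ** k for k, c in enumerate(coeffs)))


# ---------------------------------------------------------------------------
# Left ventricle
# ---------------------------------------------------------------------------

@dataclass
class LVParameters:
    """Time-varying elastance LV parameters for one age.

    The double-Hill shape parameters (psi, eta1, eta2, zeta1, zeta2) and the
    unprinted circuit constants (V_LV_0, p_ven, R_mv) carry documented
    defaults and are freely overridable.  ``psi`` normalises the double-Hill
    bracket so its maximum over one period is exactly 1, making
    ``max E = E_min + E_max``.
    """

    age: float
    E_max: float            # mmHg/mL
    E_min: float            # mmHg/mL
    p_ED: float             # mmHg
    HR: float               # bpm
    eta1: float = 1.32
    eta2: float = 21.9
    zeta1: float = 0.269
    zeta2: float = 0.452
    V_LV_0: float = 10.0    # mL, unloaded volume
    p_ven: float = 5.0      # mmHg, venous filling pressure
    R_mv: float = 0.0125    # mmHg s/mL, mitral resistance
    psi: float = field(default=0.0)         # filled in __post_init__
    t_peak_frac: float = field(default=0.0)  # fraction of T_card at peak E

    def __post_init__(self) -> None:
        if not self.E_max > self.E_min > 0:
            raise ValueError("require E_max > E_min > 0")
        # Normalise the double-Hill bracket numerically (shape depends only
        # on eta/zeta, not on T_card).
        s = np.linspace(0.0, 1.0, 20001)
        x = s / self.zeta1
        y = s / self.zeta2
        g = (x ** self.eta1 / (1.0 + x ** self.eta1)) / (1.0 + y ** self.eta2)
        i = int(np.argmax(g))
        self.psi = 1.0 / float(g[i])
        self.t_peak_frac = float(s[i])

    @property
    def T_card(self) -> float:
        """Cardiac period [s]."""
        return 60.0 / self.HR


def lv_parameters(xi: float, **overrides) -> LVParameters:
    """Decade-table LV parameters, interpolated linearly between decades."""
    lo, hi = 20.0, 80.0
    if not lo <= xi <= hi:
        logger.warning("age %.1f outside LV table range [20, 80]; clamping", xi)
        xi = min(max(xi, lo), hi)
    e_max, e_min, p_ed, hr = _interp_decades(xi, tbl.LV_ROWS)
    return LVParameters(age=xi, E_max=e_max, E_min=e_min, p_ED=p_ed, HR=hr,
                        **overrides)


# ---------------------------------------------------------------------------
# Tissue geometry / metabolism
# ---------------------------------------------------------------------------

def _fit(name: str, xi: float) -> float:
    f = tbl.TISSUE_FITS[name]
    v = f["a"] + f["b"] * xi + f["c"] * xi * xi
    if v <= 0:
        logger.warning("tissue fit %s at age %.1f gave %.4g; clamped to %.0e",
                       name, xi, v, SCALING_FLOOR)
        v = SCALING_FLOOR
    return v


@dataclass(frozen=True)
class TissueScalings:
    """Dimensionless age scalings of tissue geometry and metabolism.

    Each field is the raw regression value at age ``xi`` (the fits are
    normalised to their own reference ages, 20 y or 24.2 y, so the value is
    close to — but not exactly — 1 there).  Geometry scaling relative to the
    model's 30-year reference body divides by the same fit at 30.
    """

    age: float
    muscle_limb: float
    muscle_abdomen: float
    fat_general: float
    fat_abdomen: float
    skin: float
    bone_density: float
    metabolic: float
    cutaneous_flow: float

    def muscle(self, segment: str) -> float:
        return self.muscle_abdomen if segment == "abdomen" else self.muscle_limb

    def fat(self, segment: str) -> float:
        return self.fat_abdomen if segment == "abdomen" else self.fat_general


def tissue_scalings(xi: float) -> TissueScalings:
    """Evaluate all tissue-variation regressions at age ``xi``."""
    return TissueScalings(
        age=xi,
        muscle_limb=_fit("muscle_limb", xi),
        muscle_abdomen=_fit("muscle_abdomen", xi),
        fat_general=_fit("fat_general", xi),
        fat_abdomen=_fit("fat_abdomen", xi),
        skin=_fit("skin", xi),
        bone_density=_fit("bone_density", xi),
        metabolic=_fit("metabolic", xi),
        cutaneous_flow=cutaneous_flow_scaling(xi),
    )


def body_weight(xi: float) -> float:
    """Body weight [kg] from the age regression."""
    a, b, c = tbl.BW_COEFFS
    return a + b * xi + c * xi * xi


def resting_metabolic_rate(xi: float) -> float:
    """Resting metabolic rate [kcal/min] from the age regression."""
    a, b, c = tbl.RMR_COEFFS
    return a + b * xi + c * xi * xi


def metabolic_volumetric_rate(xi: float, rho_body: float = 1.17) -> float:
    """Whole-body mean metabolic volumetric production [W/cm3].

    ``0.06978 * rho_body * RMR / BW`` — the constant converts kcal/min to W
    and kg to cm3 through the mean body density (g/cm3).
    """
    return 0.06978 * rho_body * resting_metabolic_rate(xi) / body_weight(xi)


def bone_conductivity(rho_bo: float) -> float:
    """Bone thermal conductivity [W/(m K)] from density [g/cm3]."""
    if rho_bo < 0:
        raise ValueError("bone density must be non-negative")
    a, b, c = tbl.BONE_K_COEFFS
    k = a + b * rho_bo + c * rho_bo * rho_bo
    if k <= 0:
        raise ValueError(
            f"bone conductivity fit invalid at density {rho_bo} g/cm3")
    return k


def cutaneous_flow_scaling(xi: float) -> float:
    """Attenuation factor applied to min and max cutaneous flows."""
    a, b = tbl.CUTANEOUS_FLOW_FIT
    v = a + b * xi
    if v <= 0:
        logger.warning("cutaneous flow scaling at age %.1f clamped", xi)
        v = SCALING_FLOOR
    return v


# ---------------------------------------------------------------------------
# Thermoregulation thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSet:
    """Age-adjusted thermoregulatory thresholds [degC]."""

    age: float
    dTsk_dec: float      # sensitivity-decline step on skin deviation
    dTcr_dec: float      # sensitivity-decline step on core deviation
    T_dil_low: float
    T_dil_upp: float
    T_con_low: float
    T_con_upp: float
    shiver_shift: float  # additive shift of the shivering threshold


def regulation_thresholds(xi: float, *,
                          shiver_rate: float = tbl.SHIVER_RATE_PRINTED,
                          shiver_ref_age: float = 20.0) -> ThresholdSet:
    """Thermoregulation thresholds at age ``xi``.

    Below 50 years the young baseline applies unchanged.  Above 50 the
    vasoconstriction-activation threshold drops 0.5 degC, both vasodilation
    thresholds rise 0.05 degC, and the sensitivity-decline steps follow the
    tabulated bands (changing at 50, 65 and 70 years).  The shivering
    threshold shifts linearly with age at ``shiver_rate`` (degC/year,
    negative) relative to ``shiver_ref_age``.
    """
    for upper, sk, cr in tbl.SENSITIVITY_DECLINE_BANDS:
        if xi <= upper:
            dsk, dcr = sk, cr
            break
    aged = xi > 50.0
    return ThresholdSet(
        age=xi,
        dTsk_dec=dsk,
        dTcr_dec=dcr,
        T_dil_low=tbl.T_DIL_LOW + (0.05 if aged else 0.0),
        T_dil_upp=tbl.T_DIL_UPP + (0.05 if aged else 0.0),
        T_con_low=tbl.T_CON_LOW,
        T_con_upp=tbl.T_CON_UPP - (0.5 if aged else 0.0),
        shiver_shift=shiver_rate * max(xi - shiver_ref_age, 0.0),
    )


# ---------------------------------------------------------------------------
# Aggregate
# ---------------------------------------------------------------------------

@dataclass
class AgeingParameters:
    """All age-dependent parameters for one age, in one place."""

    age: float
    terminal_model: str = "maksuti"
    stiffening_mode: str = "uniform_trunk"  # uniform_all | uniform_trunk | specific
    pwv_exponent_sign: int = -1
    shiver_rate: float = tbl.SHIVER_RATE_PRINTED

    def __post_init__(self) -> None:
        if not 20.0 <= self.age <= 90.0:
            raise ValueError(f"age {self.age} outside supported range [20, 90]")
        if self.stiffening_mode not in ("uniform_all", "uniform_trunk",
                                        "specific"):
            raise ValueError(f"unknown stiffening mode {self.stiffening_mode!r}")
        self.lv = lv_parameters(min(self.age, 80.0))
        self.tissues = tissue_scalings(self.age)
        self.thresholds = regulation_thresholds(self.age,
                                                shiver_rate=self.shiver_rate)
        self.terminal_factor = terminal_resistance_factor(
            self.age, self.terminal_model)

    def beta_factor(self, xi_ref: float) -> float:
        return uniform_beta_factor(min(self.age, 80.0), xi_ref)

    def pwv(self, d_mm: float) -> float:
        return pwv_from_diameter(d_mm, self.age,
                                 pwv_exponent_sign=self.pwv_exponent_sign)

    def as_dict(self) -> dict:
        """Flat JSON-serialisable dump of every parameter (for audit)."""
        th, ts, lv = self.thresholds, self.tissues, self.lv
        return {
            "age": self.age,
            "terminal_model": self.terminal_model,
            "stiffening_mode": self.stiffening_mode,
            "terminal_resistance_factor": self.terminal_factor,
            "uniform_beta_factor_vs_20": self.beta_factor(20.0),
            "body_weight_kg": body_weight(self.age),
            "rmr_kcal_min": resting_metabolic_rate(self.age),
            "metabolic_volumetric_rate_W_cm3": metabolic_volumetric_rate(self.age),
            "lv": {
                "E_max": lv.E_max, "E_min": lv.E_min, "p_ED": lv.p_ED,
                "HR": lv.HR, "T_card": lv.T_card, "psi": lv.psi,
                "eta1": lv.eta1, "eta2": lv.eta2,
                "zeta1": lv.zeta1, "zeta2": lv.zeta2,
                "V_LV_0": lv.V_LV_0, "p_ven": lv.p_ven, "R_mv": lv.R_mv,
            },
            "tissues": {
                "muscle_limb": ts.muscle_limb,
                "muscle_abdomen": ts.muscle_abdomen,
                "fat_general": ts.fat_general,
                "fat_abdomen": ts.fat_abdomen,
                "skin": ts.skin,
                "bone_density": ts.bone_density,
                "metabolic": ts.metabolic,
                "cutaneous_flow": ts.cutaneous_flow,
            },
            "thresholds": {
                "dTsk_dec": th.dTsk_dec, "dTcr_dec": th.dTcr_dec,
                "T_dil_low": th.T_dil_low, "T_dil_upp": th.T_dil_upp,
                "T_con_low": th.T_con_low, "T_con_upp": th.T_con_upp,
                "shiver_shift": th.shiver_shift,
            },
        }
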