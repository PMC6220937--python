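"""Thermoregulatory controllers: sweating, cutaneous vasomotion, shivering.

All three mechanisms are driven by the two global indicators — core
temperature ``T_cr`` and area-averaged skin temperature ``T_sk`` — plus the
local skin temperature of each body segment.  Ageing enters through the
threshold set (sensitivity-decline steps that clip the sweating drives,
shifted vasomotion thresholds, a linear shivering-threshold drift) and
through the attenuation factor on the min/max cutaneous flows.

Units: sweating rates in g/(min m2) of body surface, cutaneous flows in
cm3/s per segment instance, heat rates in W.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from . import _tables as tbl
from .ageing import ThresholdSet, cutaneous_flow_scaling, regulation_thresholds

logger = logging.getLogger(__name__)

T_CR_SETPOINT = 36.8   # degC, thermoneutral core setpoint
T_SK_SETPOINT = 33.7   # degC, thermoneutral mean-skin setpoint
LATENT_FACTOR = 40.6   # W per g/(min m2) per m2 (latent heat / 60 s)
SHIVER_CEILING = 37.1  # degC, core temperature above which shivering is off


def alpha_swe_sum() -> float:
    """Whole-body sum of sweating coefficients with limb multiplicities."""
    return sum(tbl.ALPHA_SWE[s] * tbl.SEGMENT_MULT[s] for s in tbl.SEGMENT_TYPES)


def alpha_shiv_sum() -> float:
    """Whole-body sum of shivering coefficients with limb multiplicities."""
    return sum(tbl.ALPHA_SHIV[s] * tbl.SEGMENT_MULT[s]
               for s in tbl.SEGMENT_TYPES)


def saturation_vapour_pressure(T: float) -> float:
    """Saturated water-vapour pressure [mmHg] (Antoine fit, 1-100 degC)."""
    return 10.0 ** (8.07131 - 1730.63 / (233.426 + T))


def clipped_deviation(delta: float, decline: float) -> float:
    """Sensitivity-clipped deviation: 0 below the decline step, the excess
    above it otherwise (always >= 0 for positive deviations)."""
    return delta - decline if delta > decline else 0.0


# ---------------------------------------------------------------------------
# Sweating
# ---------------------------------------------------------------------------

def sweating_rate(segment: str, T_cr: float, T_sk_mean: float,
                  T_sk_local: float, thresholds: ThresholdSet,
                  T_cr_0: float = T_CR_SETPOINT,
                  T_sk_0: float = T_SK_SETPOINT,
                  m_swe_0: float = 0.3) -> float:
    """Segment sweating rate [g/(min m2)].

    ``m = m0 + chi * theta_sk * ( [0.8 tanh(0.59 dTsk - 0.19) + 1.2] dTsk*
    + [5.7 tanh(1.98 dTcr - 1.03) + 6.3] dTcr* )`` with
    ``theta_sk = alpha_swe * 2**((T_sk_local - T_sk_0)/10)`` and starred
    deviations clipped by the age-dependent sensitivity-decline steps.  The
    insensible baseline ``m0`` is distributed over segments by alpha_swe.
    """
    d_sk = T_sk_mean - T_sk_0
    d_cr = T_cr - T_cr_0
    d_sk_star = clipped_deviation(d_sk, thresholds.dTsk_dec)
    d_cr_star = clipped_deviation(d_cr, thresholds.dTcr_dec)
    alpha = tbl.ALPHA_SWE[segment]
    theta = alpha * 2.0 ** ((T_sk_local - T_sk_0) / 10.0)
    drive = ((0.8 * math.tanh(0.59 * d_sk - 0.19) + 1.2) * d_sk_star
             + (5.7 * math.tanh(1.98 * d_cr - 1.03) + 6.3) * d_cr_star)
    base = m_swe_0 * alpha
    return max(base + tbl.CHI_SWE[segment] * theta * drive, base)


def evaporative_loss(m_swe_total: float, A_sk_glob_cm2: float,
                     T_sk_mean: float, T_air: float, RH: float,
                     f_cl: float = 1.0, h_swe: float = 5.0) -> float:
    """Whole-body evaporative heat loss [W].

    ``Q = min(40.6 m A, 2.2 h_swe f_cl (p_sk - p_air) A)`` — the first term
    is the latent heat of the secreted sweat, the second the environmental
    uptake capacity (h_swe in W/(m2 degC), vapour pressures in mmHg, 2.2
    degC/mmHg the Lewis relation).  Condensing air caps evaporation at 0.
    """
    A_m2 = A_sk_glob_cm2 * 1e-4
    p_sk = saturation_vapour_pressure(T_sk_mean)
    p_air = saturation_vapour_pressure(T_air) * RH / 100.0
    if p_sk <= p_air:
        logger.warning("ambient vapour pressure exceeds skin saturation; "
                       "evaporation capped at 0")
        return 0.0
    supply = LATENT_FACTOR * m_swe_total * A_m2
    capacity = 2.2 * h_swe * f_cl * (p_sk - p_air) * A_m2
    return min(supply, capacity)


# ---------------------------------------------------------------------------
# Cutaneous vasomotion
# ---------------------------------------------------------------------------

def _ramp(x: float, lo: float, hi: float, y_lo: float, y_hi: float) -> float:
    if x <= lo:
        return y_lo
    if x >= hi:
        return y_hi
    return y_lo + (x - lo) / (hi - lo) * (y_hi - y_lo)


def skin_flow_bounds(segment: str, xi: float,
                     literal_table8: bool = False) -> tuple[float, float, float]:
    """(basal, max, min) cutaneous flows [cm3/s] for one segment instance.

    The shipped perfusion table's max/min columns are transposed (the max
    column holds zeros); by default the larger column is taken as the
    maximum.  ``literal_table8=True`` keeps the printed orientation.  The
    age attenuation multiplies min and max; the basal flow is age-free.
    """
    m0, col_max, col_min = tbl.SKIN_FLOW_PRINTED[segment]
    if not literal_table8:
        m_max, m_min = col_min, col_max
    else:
        m_max, m_min = col_max, col_min
    fac = cutaneous_flow_scaling(xi)
    return m0, m_max * fac, m_min * fac


def skin_perfusion(segment: str, T_cr: float, T_sk_mean: float,
                   thresholds: ThresholdSet, xi: float,
                   skin_mass_g: float | None = None,
                   rho_bl: float = tbl.BLOOD_RHO,
                   literal_table8: bool = False
                   ) -> tuple[float, float | None]:
    """Cutaneous blood flow [cm3/s] and perfusion rate [1/s] for a segment.

    ``m_sk = m_dil * m_con / m_sk0`` where the dilation branch ramps with
    core temperature between the dilation thresholds (basal -> max) and the
    constriction branch with mean skin temperature (min -> basal).  The
    perfusion rate divides the mass flow by the segment skin mass.
    """
    m0, m_max, m_min = skin_flow_bounds(segment, xi, literal_table8)
    m_dil = _ramp(T_cr, thresholds.T_dil_low, thresholds.T_dil_upp, m0, m_max)
    m_con = _ramp(T_sk_mean, thresholds.T_con_low, thresholds.T_con_upp,
                  m_min, m0)
    m_sk = m_dil * m_con / m0
    phi = m_sk * rho_bl / skin_mass_g if skin_mass_g else None
    return m_sk, phi


# ---------------------------------------------------------------------------
# Shivering
# ---------------------------------------------------------------------------

def shivering_threshold(T_cr: float) -> float:
    """Shivering threshold temperature [degC] as a function of core
    temperature: constant 35.5 below 35.8 degC, quadratic above."""
    if T_cr <= 35.8:
        return 35.5
    return -10222.0 + 570.9 * T_cr - 7.9455 * T_cr * T_cr


def shivering_power(T_cr: float, T_sk_mean: float,
                    thresholds: ThresholdSet,
                    V_mus_glob: float) -> tuple[float, float, dict[str, float]]:
    """(T_shiv, Q_shiv [W], per-segment q_shiv [W/cm3]).

    Shivering is active only for ``T_cr <= 37.1``; the age shift from the
    threshold set lowers the shivering threshold.  The heat production ramps
    quadratically with mean skin temperature below the threshold and is
    distributed over muscle via the shivering coefficients.
    """
    T_shiv = shivering_threshold(T_cr) + thresholds.shiver_shift
    if T_cr > SHIVER_CEILING:
        return T_shiv, 0.0, {s: 0.0 for s in tbl.SEGMENT_TYPES}
    gate_low = 40.0 - T_shiv
    if T_sk_mean <= gate_low or T_sk_mean > T_shiv:
        Q = 0.0
    else:
        Q_max = (-1.1861e9 + 6.552e7 * T_cr - 9.0418e5 * T_cr * T_cr) / 3600.0
        ramp = 1.0 - ((T_sk_mean - 20.0) / (T_shiv - 20.0)) ** 2
        Q = max(Q_max * ramp, 0.0)
    q = {s: tbl.ALPHA_SHIV[s] * Q / V_mus_glob for s in tbl.SEGMENT_TYPES}
    return T_shiv, Q, q


# ---------------------------------------------------------------------------
# Controller facade
# ---------------------------------------------------------------------------

@dataclass
class ControllerOutput:
    """One evaluation of all three mechanisms."""

    T_cr: float
    T_sk_mean: float
    m_swe_by_cylinder: dict[str, float]     # g/(min m2), per instance
    m_swe_total: float
    Q_swe_total: float                      # W
    Q_swe_by_cylinder: dict[str, float]     # W
    m_sk_by_cylinder: dict[str, float]      # cm3/s
    phi_sk_by_cylinder: dict[str, float]    # 1/s
    T_shiv: float
    Q_shiv: float                           # W
    q_shiv_by_cylinder: dict[str, float]    # W/cm3 (muscle layer)


@dataclass
class Thermoregulator:
    """Age-aware controller bound to a body's segment geometry.

    The ageing toggles mirror the experiment ladder: with ``age_sweating``
    (resp. ``age_vasomotion``, ``age_shivering``) off, that mechanism uses
    the young thresholds/scalings even for an aged body.
    """

    age: float
    reference_age: float = 30.0
    age_sweating: bool = True
    age_vasomotion: bool = True
    age_shivering: bool = True
    T_cr_0: float = T_CR_SETPOINT
    T_sk_0: float = T_SK_SETPOINT
    m_swe_0: float = 0.3
    f_cl: float = 1.0
    h_swe: float = 5.0
    shiver_rate: float = tbl.SHIVER_RATE_PRINTED
    literal_table8: bool = False

    def __post_init__(self) -> None:
        self._young = regulation_thresholds(self.reference_age,
                                            shiver_rate=self.shiver_rate)
        self._aged = regulation_thresholds(self.age,
                                           shiver_rate=self.shiver_rate)

    def _th(self, aged_flag: bool) -> ThresholdSet:
        return self._aged if aged_flag else self._young

    def evaluate(self, body, T_cr: float, T_sk_mean: float,
                 T_sk_by_cylinder: dict[str, float] | None = None
                 ) -> ControllerOutput:
        """Evaluate all mechanisms against the current body state."""
        T_sk_by_cylinder = T_sk_by_cylinder or {
            c.name: c.T_surface for c in body.cylinders}
        th_swe = self._th(self.age_sweating)
        th_vas = self._th(self.age_vasomotion)
        th_shv = self._th(self.age_shivering)
        xi_vas = self.age if self.age_vasomotion else self.reference_age

        m_swe = {}
        for c in body.cylinders:
            m_swe[c.name] = sweating_rate(
                c.segment, T_cr, T_sk_mean, T_sk_by_cylinder[c.name],
                th_swe, self.T_cr_0, self.T_sk_0, self.m_swe_0)
        m_tot = sum(m_swe.values())
        env = body.environment
        Q_tot = evaporative_loss(m_tot, body.A_sk_glob, T_sk_mean,
                                 env.T_air, env.RH, self.f_cl, self.h_swe)
        Q_by = {name: Q_tot * m / m_tot if m_tot > 0 else 0.0
                for name, m in m_swe.items()}

        m_sk, phi_sk = {}, {}
        for c in body.cylinders:
            m, phi = skin_perfusion(c.segment, T_cr, T_sk_mean, th_vas,
                                    xi_vas, c.skin_mass, body.rho_bl,
                                    self.literal_table8)
            m_sk[c.name], phi_sk[c.name] = m, phi

        T_shiv, Q_shiv, q_by_segment = shivering_power(
            T_cr, T_sk_mean, th_shv, body.V_mus_glob)
        q_shiv = {c.name: q_by_segment[c.segment] for c in body.cylinders}

        return ControllerOutput(
            T_cr=T_cr, T_sk_mean=T_sk_mean, m_swe_by_cylinder=m_swe,
            m_swe_total=m_tot, Q_swe_total=Q_tot, Q_swe_by_cylinder=Q_by,
            m_sk_by_cylinder=m_sk, phi_sk_by_cylinder=phi_sk,
            T_shiv=T_shiv, Q_shiv=Q_shiv, q_shiv_by_cylinder=q_shiv)

    def apply(self, body, out: ControllerOutput) -> None:
        """Write perfusion overrides and shivering sources into the body."""
        for c in body.cylinders:
            c.phi_skin_override = out.phi_sk_by_cylinder[c.name]
            c.q_shiv[:] = 0.0
            c.q_shiv[c.muscle_mask] = out.q_shiv_by_cylinder[c.name]
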