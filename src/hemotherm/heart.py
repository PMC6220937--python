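"""Time-varying elastance left ventricle with aortic-valve coupling.

The LV is a lumped chamber whose pressure follows ``p_LV = E(t) (V - V0)``
with a double-Hill elastance curve rising from the end-diastolic value
``E_min`` to ``E_min + E_max`` and back within each cardiac period.  The
cycle is a four-phase state machine:

1. *isovolumetric contraction* — volume frozen, pressure rises with E(t)
   until it exceeds the instantaneous arterial-root pressure (valve opens);
2. *ejection* — ``dV/dt = -G_AV`` where ``G_AV`` is the net flow through
   the inlet node of the arterial network; ends when E(t) reaches its peak;
3. *isovolumetric relaxation* — volume frozen until ``p_LV`` falls back to
   the end-diastolic pressure;
4. *filling* — ``dV/dt = (p_ven - p_LV)/R_mv`` until the period ends.

Volume updates use forward Euler.  The aortic valve enters the
characteristic treatment of the network inlet through a transmission
coefficient ``R_AV`` in [0 (open), 1 (closed)] ramped linearly over a
configurable opening/closing interval (default 5 ms), triggered by the
phase machine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .ageing import LVParameters


def elastance(t_cycle, params: LVParameters):
    """Double-Hill elastance [mmHg/mL] at time ``t_cycle`` within the cycle.

    ``E = E_min + E_max * psi * [x^eta1/(1+x^eta1)] * [1/(1+y^eta2)]`` with
    ``x = t/(zeta1*T)`` and ``y = t/(zeta2*T)``; psi normalises the bracket
    maximum to 1, so the curve peaks at exactly ``E_min + E_max``.
    """
    t = np.asarray(t_cycle, dtype=float)
    T = params.T_card
    x = t / (params.zeta1 * T)
    y = t / (params.zeta2 * T)
    xb = x ** params.eta1
    g = (xb / (1.0 + xb)) / (1.0 + y ** params.eta2)
    return params.E_min + params.E_max * params.psi * g


PHASES = ("isovolumetric_contraction", "ejection",
          "isovolumetric_relaxation", "filling")


@dataclass
class LVState:
    """Instantaneous left-ventricle state."""

    params: LVParameters
    V: float = field(default=0.0)       # mL
    phase: str = "isovolumetric_contraction"
    t_cycle: float = 0.0                # s
    R_AV: float = 1.0                   # 1 = closed, 0 = open
    cycle_index: int = 0
    valve_tau: float = 0.005            # s, ramp duration
    _ramp_from: float = field(default=1.0, repr=False)
    _ramp_target: float = field(default=1.0, repr=False)
    _ramp_t0: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        if self.V == 0.0:
            self.V = self.V_ED
        if self.V < self.params.V_LV_0:
            raise ValueError("LV volume below unloaded volume")

    @property
    def V_ED(self) -> float:
        """End-diastolic volume V0 + p_ED/E_min [mL]."""
        return self.params.V_LV_0 + self.params.p_ED / self.params.E_min

    @property
    def E(self) -> float:
        return float(elastance(self.t_cycle, self.params))

    @property
    def p_LV(self) -> float:
        """LV pressure [mmHg]."""
        return self.E * (self.V - self.params.V_LV_0)

    @property
    def p_LV_dyn(self) -> float:
        return units.dyn(self.p_LV)

    # -- valve ramp -----------------------------------------------------------
    def _set_valve(self, target: float) -> None:
        if target != self._ramp_target:
            self._ramp_from = self.R_AV
            self._ramp_target = target
            self._ramp_t0 = self.t_cycle

    def _advance_valve(self) -> None:
        dt_r = self.t_cycle - self._ramp_t0
        if dt_r >= self.valve_tau:
            self.R_AV = self._ramp_target
        else:
            f = dt_r / self.valve_tau
            self.R_AV = self._ramp_from + (self._ramp_target - self._ramp_from) * f

    # -- cycle step -----------------------------------------------------------
    def step(self, dt: float, G_AV: float, p_root_mmhg: float) -> "LVState":
        """Advance one time step.

        ``G_AV`` is the net inlet flow [mL/s] (area*velocity at the first
        arterial node) and ``p_root_mmhg`` the instantaneous pressure there,
        used for the valve-opening trigger.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        p = self.params
        if self.phase == "ejection":
            self.V -= G_AV * dt
        elif self.phase == "filling":
            self.V += (p.p_ven - self.p_LV) / p.R_mv * dt
        if self.V < 0:
            raise RuntimeError("negative LV volume; aborting")
        self.t_cycle += dt
        if self.t_cycle >= p.T_card:
            self.t_cycle -= p.T_card
            self.cycle_index += 1
            self._ramp_t0 -= p.T_card
            self.phase = "isovolumetric_contraction"
            self._set_valve(1.0)

        # phase transitions
        if self.phase == "isovolumetric_contraction":
            if self.p_LV >= p_root_mmhg:
                self.phase = "ejection"
                self._set_valve(0.0)
        elif self.phase == "ejection":
            if self.t_cycle >= p.t_peak_frac * p.T_card:
                self.phase = "isovolumetric_relaxation"
                self._set_valve(1.0)
        elif self.phase == "isovolumetric_relaxation":
            if self.p_LV <= p.p_ED:
                self.phase = "filling"
        self._advance_valve()
        return self


def inlet_w1(p_LV_dyn: float, beta: float, A0: float, p_ext: float,
             rho: float, R_AV: float, w1_0: float, w2_0: float,
             w1_extrap: float, w2_new: float) -> float:
    """Forward characteristic at the network inlet under valve regulation.

    The LV-driven characteristic is
    ``w1_in = w2_0 + 4*sqrt((2/rho)*(p_LV - p_ext + beta*sqrt(A0)))``
    (= ``w2_0 + 8 c(A_eq)`` with ``A_eq`` the area equilibrated to the LV
    pressure, so ``p_LV = p_ext`` reproduces the unstressed ``w1_0``);
    the valve blends it with pure reflection of the backward wave:
    ``w1 = w1_0 + (1 - R_AV)*(w1_in - w1_0) - R_AV*(w2_new - w2_0)``.
    At ``R_AV = 0`` (open) the LV value transmits fully; at ``R_AV = 1``
    (closed) the inlet is a total reflector.
    """
    radicand = (2.0 / rho) * (p_LV_dyn - p_ext + beta * math.sqrt(A0))
    if radicand < 0:
        raise ValueError("LV pressure below tube-law collapse limit at inlet")
    w1_lv = w2_0 + 4.0 * math.sqrt(radicand)
    del w1_extrap  # kept in the signature for interface symmetry/audit
    return w1_0 + (1.0 - R_AV) * (w1_lv - w1_0) - R_AV * (w2_new - w2_0)
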