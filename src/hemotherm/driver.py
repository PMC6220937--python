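"""Experiment orchestration: flow-only runs, coupled runs, waveform metrics.

Two experiment families mirror the two halves of the model:

* **Flow experiments** run the 1D network driven by the age-specific left
  ventricle for a number of cardiac cycles and summarise the last cycle
  with pressure-waveform indicators (systolic/diastolic pressure, pulse
  pressure, augmentation pressure, pulse-pressure ratio between two sites)
  and per-cycle LV diagnostics.

* **Coupled experiments** expose the 14-cylinder body to an environment for
  a prescribed duration with the thermoregulatory controller in the loop.
  ``flow_mode="pool"`` couples blood and tissue through the central
  perfusion pool only (suitable for hour-long exposures);
  ``flow_mode="live"`` nests full flow steps inside every thermal step and
  exchanges heat between mapped vessels and tissue cells (used for short
  windows, e.g. to quantify how little the flow ageing matters thermally).

The per-mechanism ageing toggles reproduce the hot-exposure case ladder:
young baseline, then cumulatively aged fluid, tissues, vasomotion and
sweating.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .ageing import AgeingParameters, lv_parameters
from .flow1d import FlowRecord, FlowSolver, Probe
from .heart import LVState
from .network import ArterialNetwork, apply_ageing, generate_synthetic_network
from .regulation import Thermoregulator
from .thermal import BodyModel, Environment, VesselCoupling, build_body, couple_arteries


# ---------------------------------------------------------------------------
# Waveform indicators
# ---------------------------------------------------------------------------

@dataclass
class PressureIndicators:
    p_sys: float
    p_dia: float
    PP: float
    MAP: float
    AP: float | None   # augmentation pressure; None when no inflection found

    def as_dict(self) -> dict:
        return {"p_sys": self.p_sys, "p_dia": self.p_dia, "PP": self.PP,
                "MAP": self.MAP, "AP": self.AP}


def pressure_indicators(t: np.ndarray, p: np.ndarray) -> PressureIndicators:
    """Waveform indicators over one (or more) converged cycles.

    The augmentation pressure is measured at the inflection point: the first
    zero crossing of the smoothed second time-derivative between the point
    of steepest upstroke and the systolic peak.  A waveform without such a
    crossing (e.g. a pure sinusoid) reports ``AP=None`` rather than zero.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(p) < 8:
        raise ValueError("waveform too short for indicator extraction")
    p_sys = float(np.max(p))
    p_dia = float(np.min(p))
    map_ = float(np.trapezoid(p, t) / (t[-1] - t[0]))

    win = min(len(p) // 8 * 2 + 1, 51)
    ps = savgol_filter(p, win, 3) if win >= 5 else p
    dp = np.gradient(ps, t)
    d2p = np.gradient(dp, t)

    i_peak = int(np.argmax(ps))
    i_foot = int(np.argmin(ps[:i_peak])) if i_peak > 0 else 0
    seg = slice(i_foot, i_peak + 1)
    if i_peak - i_foot < 4:
        return PressureIndicators(p_sys, p_dia, p_sys - p_dia, map_, None)
    i_steep = i_foot + int(np.argmax(dp[seg]))
    ap = None
    for i in range(i_steep + 1, i_peak):
        if d2p[i] * d2p[i + 1] < 0:  # sign change: shoulder inflection
            ap = p_sys - float(p[i])
            break
    return PressureIndicators(p_sys, p_dia, p_sys - p_dia, map_, ap)


def last_cycle(record: FlowRecord, T_card: float, probe_index: int = 0
               ) -> tuple[np.ndarray, np.ndarray]:
    """(t, p) of the final full cardiac cycle at one probe."""
    t = record.t
    mask = t >= t[-1] - T_card
    return t[mask], record.p_mmHg[mask, probe_index]


def cycle_periodicity(record: FlowRecord, T_card: float,
                      probe_index: int = 0) -> float:
    """Max relative pressure difference between the last two cycles."""
    t = record.t
    m1 = (t >= t[-1] - T_card) & (t <= t[-1])
    m0 = (t >= t[-1] - 2 * T_card) & (t < t[-1] - T_card)
    n = min(m0.sum(), m1.sum())
    p0 = record.p_mmHg[m0, probe_index][:n]
    p1 = record.p_mmHg[m1, probe_index][:n]
    scale = max(float(np.max(p1) - np.min(p1)), 1e-9)
    return float(np.max(np.abs(p1 - p0)) / scale)


# ---------------------------------------------------------------------------
# Flow experiment
# ---------------------------------------------------------------------------

@dataclass
class FlowExperimentResult:
    age: float
    record: FlowRecord
    indicators: list[PressureIndicators]
    pp_ratio: float | None
    cardiac_output_L_min: float     # mean aortic flow over the last cycle
    stroke_volume_mL: float
    cycles: int
    periodicity: float


def run_flow_experiment(age: float,
                        network: ArterialNetwork | None = None,
                        *,
                        stiffening_mode: str = "uniform_all",
                        terminal_model: str = "maksuti",
                        n_generations: int = 2,
                        seed: int = 0,
                        n_cycles: int = 8,
                        dt: float = 2e-4,
                        probes: list[Probe] | None = None,
                        record_every: int = 10,
                        apply_age: bool = True) -> FlowExperimentResult:
    """Run the LV-driven network for ``n_cycles`` cardiac cycles.

    The default probes sit at the network root (aortic site) and at the
    midpoint of the first daughter (downstream site) so a pulse-pressure
    ratio can be formed.
    """
    if network is None:
        network = generate_synthetic_network(n_generations, seed)
    if apply_age:
        params = AgeingParameters(age=age, terminal_model=terminal_model,
                                  stiffening_mode=stiffening_mode)
        network = apply_ageing(network, params)
    lv = LVState(params=lv_parameters(age))
    if probes is None:
        probes = [Probe(network.inlet, 0.1)]
        children = {j.parent: j.daughters for j in network.junctions}
        if network.inlet in children:
            probes.append(Probe(children[network.inlet][0], 0.5))
    solver = FlowSolver(network, dt=dt, lv=lv)
    duration = n_cycles * lv.params.T_card
    record = solver.run(duration, probes=probes, record_every=record_every)

    T = lv.params.T_card
    t_c, p_c = last_cycle(record, T, 0)
    inds = [pressure_indicators(*last_cycle(record, T, j))
            for j in range(len(probes))]
    pp_ratio = (inds[1].PP / inds[0].PP) if len(inds) > 1 else None

    mask = record.t >= record.t[-1] - T
    q_mean = float(np.mean(record.Q[mask, 0]))
    co = q_mean * 60.0 / 1000.0
    sv = q_mean * T
    return FlowExperimentResult(
        age=age, record=record, indicators=inds, pp_ratio=pp_ratio,
        cardiac_output_L_min=co, stroke_volume_mL=sv, cycles=n_cycles,
        periodicity=cycle_periodicity(record, T, 0))


def pv_loop_metrics(record: FlowRecord, T_card: float) -> dict:
    """Stroke volume, loop closure and loop area from the LV trace."""
    t, V, p = record.t, record.lv["V"], record.lv["p_LV"]
    mask = t >= t[-1] - T_card
    Vc, pc = V[mask], p[mask]
    sv = float(np.max(Vc) - np.min(Vc))
    # shoelace area of the (V, p) loop; counter-clockwise => positive
    area = 0.5 * float(np.sum(Vc * np.roll(pc, -1) - np.roll(Vc, -1) * pc))
    closure = float(math.hypot(Vc[-1] - Vc[0], pc[-1] - pc[0]))
    return {"SV_mL": sv, "loop_area_mmHg_mL": area,
            "closure_gap": closure,
            "V_ED": float(np.max(Vc)), "V_ES": float(np.min(Vc))}


# ---------------------------------------------------------------------------
# Coupled experiment
# ---------------------------------------------------------------------------

@dataclass
class AgeingToggles:
    """Independent switches for each age-modification family."""

    fluid: bool = True
    tissues: bool = True
    vasomotion: bool = True
    sweating: bool = True
    shivering: bool = True


@dataclass
class ExperimentConfig:
    """Configuration of a coupled flow-thermal exposure."""

    age: float = 30.0
    reference_age: float = 30.0
    stiffening_mode: str = "specific"
    terminal_model: str = "maksuti"
    T_air: float = 40.0
    RH: float = 42.0
    T_surr: float | None = None
    duration: float = 3600.0
    dt_thermal: float = 0.5
    dt_flow: float = 2e-4
    flow_mode: str = "pool"          # pool | live
    n_generations: int = 1
    seed: int = 0
    initial_T: float = 37.0
    control_every: int = 1           # controller cadence in thermal steps
    record_every: int = 10
    toggles: AgeingToggles = field(default_factory=AgeingToggles)

    def __post_init__(self) -> None:
        if isinstance(self.toggles, dict):
            self.toggles = AgeingToggles(**self.toggles)
        if self.flow_mode not in ("pool", "live"):
            raise ValueError(f"unknown flow_mode {self.flow_mode!r}")
        if self.flow_mode == "live":
            n = self.dt_thermal / self.dt_flow
            if abs(n - round(n)) > 1e-9 or n < 1:
                raise ValueError("dt_thermal must be an integer multiple of "
                                 "dt_flow in live mode")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def with_overrides(self, overrides: dict[str, str]) -> "ExperimentConfig":
        """Apply dotted ``key=value`` string overrides (CLI ``--set``)."""
        d = self.to_dict()
        for key, val in overrides.items():
            parts = key.split(".")
            tgt = d
            for p in parts[:-1]:
                if p not in tgt:
                    raise ValueError(f"unknown config key {key!r}")
                tgt = tgt[p]
            leaf = parts[-1]
            if leaf not in tgt:
                raise ValueError(f"unknown config key {key!r}")
            cur = tgt[leaf]
            if isinstance(cur, bool):
                tgt[leaf] = val.lower() in ("1", "true", "yes", "on")
            elif isinstance(cur, (int, float)) and cur is not None:
                tgt[leaf] = type(cur)(float(val))
            else:
                tgt[leaf] = val
        return ExperimentConfig.from_dict(d)


@dataclass
class CoupledResult:
    config: ExperimentConfig
    t: np.ndarray
    T_cr: np.ndarray
    T_sk: np.ndarray
    Q_swe: np.ndarray
    Q_shiv: np.ndarray
    body: BodyModel
    profiles: dict[str, tuple[np.ndarray, np.ndarray]]  # cylinder -> (r, T)

    @property
    def final_T_cr(self) -> float:
        return float(self.T_cr[-1])

    @property
    def final_T_sk(self) -> float:
        return float(self.T_sk[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_s": self.t, "T_cr_C": self.T_cr,
                             "T_sk_C": self.T_sk, "Q_swe_W": self.Q_swe,
                             "Q_shiv_W": self.Q_shiv})


def default_mapping(network: ArterialNetwork, body: BodyModel) -> dict:
    """Deterministic vessel->cylinder thermal mapping for synthetic trees.

    The root is a core vessel in the thorax; subsequent vessels are dealt
    round-robin to central positions of the large cylinders; terminal tapers
    become transversal sources in limb muscle.
    """
    hosts = ["abdomen", "arm_L", "arm_R", "thigh_L", "thigh_R",
             "forearm_L", "forearm_R", "leg_L", "leg_R", "neck", "head"]
    mapping = {network.inlet: {"cylinder": "thorax", "class": "core"}}
    i = 0
    for vid, v in network.vessels.items():
        if vid == network.inlet:
            continue
        host = hosts[i % len(hosts)]
        i += 1
        mode = "transversal" if v.category == "terminal_taper" else "central"
        mapping[vid] = {"cylinder": host, "class": mode}
    return mapping


def _vessel_heat_exchange(solver: FlowSolver, body: BodyModel,
                          table: list[VesselCoupling], dt_thermal: float
                          ) -> None:
    """Exchange heat between mapped vessels and their tissue cells.

    The fluid side sees the tissue-cell temperature as wall temperature; the
    tissue side receives the integrated convective power as a volumetric
    source for the next thermal step (loose, latest-available coupling).
    """
    h_in = solver.h_in
    wall: dict[str, float] = {}
    for cyl in body.cylinders:
        cyl.q_vessel[:] = 0.0
    for cpl in table:
        cyl = body.by_name[cpl.cylinder]
        f = solver.fields[cpl.vessel]
        if cpl.mode == "core":
            wall[cpl.vessel] = float(f.T[0])  # adiabatic: T_w=T disables flux
            continue
        T_cell = float(cyl.T[cpl.cell_index])
        wall[cpl.vessel] = T_cell
        # power [W] transferred blood -> tissue along the vessel
        perim = 2.0 * np.sqrt(math.pi * f.A)
        P = float(np.trapezoid(h_in * perim * (f.T - T_cell), dx=f.dx))
        cyl.q_vessel[cpl.cell_index] += P / float(cyl.V[cpl.cell_index])
    # core vessels: truly adiabatic
    for cpl in table:
        if cpl.mode == "core":
            f = solver.fields[cpl.vessel]
            wall[cpl.vessel] = f.T.copy()
    solver.wall_temperature = wall


def run_coupled(config: ExperimentConfig) -> CoupledResult:
    """Run one coupled exposure experiment.

    Initial blood and tissue temperatures are uniform ``initial_T``.  Each
    thermal step re-evaluates the controller (sweating, vasomotion,
    shivering) from the current indicators and, in live mode, advances the
    flow solver ``dt_thermal/dt_flow`` sub-steps with two-way thermal
    exchange on the mapped vessels.
    """
    cfg = config
    tg = cfg.toggles
    env = Environment(T_air=cfg.T_air, RH=cfg.RH, T_surr=cfg.T_surr)
    body = build_body(cfg.age if tg.tissues else cfg.reference_age,
                      environment=env, age_tissues=tg.tissues)
    body.set_uniform_temperature(cfg.initial_T)
    reg = Thermoregulator(
        age=cfg.age, reference_age=cfg.reference_age,
        age_sweating=tg.sweating, age_vasomotion=tg.vasomotion,
        age_shivering=tg.shivering)

    solver = None
    table: list[VesselCoupling] = []
    if cfg.flow_mode == "live":
        net = generate_synthetic_network(cfg.n_generations, cfg.seed)
        if tg.fluid:
            params = AgeingParameters(age=cfg.age,
                                      terminal_model=cfg.terminal_model,
                                      stiffening_mode=cfg.stiffening_mode)
            net = apply_ageing(net, params)
        lv = LVState(params=lv_parameters(cfg.age if tg.fluid
                                          else cfg.reference_age))
        solver = FlowSolver(net, dt=cfg.dt_flow, lv=lv,
                            initial_T=cfg.initial_T,
                            inlet_temperature=cfg.initial_T)
        table = couple_arteries(net, body, default_mapping(net, body))
        n_sub = int(round(cfg.dt_thermal / cfg.dt_flow))

    n_steps = int(round(cfg.duration / cfg.dt_thermal))
    n_rec = n_steps // cfg.record_every + 1
    t_r = np.empty(n_rec)
    tcr_r = np.empty(n_rec)
    tsk_r = np.empty(n_rec)
    qswe_r = np.empty(n_rec)
    qshiv_r = np.empty(n_rec)

    T_cr, T_sk = body.thermal_indicators()
    out = reg.evaluate(body, T_cr, T_sk)
    t_r[0], tcr_r[0], tsk_r[0] = 0.0, T_cr, T_sk
    qswe_r[0], qshiv_r[0] = out.Q_swe_total, out.Q_shiv
    k = 1
    for s in range(1, n_steps + 1):
        if (s - 1) % cfg.control_every == 0:
            T_cr, T_sk = body.thermal_indicators()
            out = reg.evaluate(body, T_cr, T_sk)
            reg.apply(body, out)
        if solver is not None:
            _vessel_heat_exchange(solver, body, table, cfg.dt_thermal)
            solver.inlet_temperature = T_cr
            for _ in range(n_sub):
                solver.step()
        body.step(cfg.dt_thermal, out.Q_swe_by_cylinder)
        if s % cfg.record_every == 0:
            T_cr, T_sk = body.thermal_indicators()
            t_r[k] = s * cfg.dt_thermal
            tcr_r[k], tsk_r[k] = T_cr, T_sk
            qswe_r[k], qshiv_r[k] = out.Q_swe_total, out.Q_shiv
            k += 1

    profiles = {c.name: (c.r.copy(), c.T.copy()) for c in body.cylinders}
    return CoupledResult(config=cfg, t=t_r[:k], T_cr=tcr_r[:k],
                         T_sk=tsk_r[:k], Q_swe=qswe_r[:k],
                         Q_shiv=qshiv_r[:k], body=body, profiles=profiles)


# ---------------------------------------------------------------------------
# The hot-exposure case ladder
# ---------------------------------------------------------------------------

LADDER_CASES = ("young", "fluid", "tissues", "vasomotion", "sweating")


def ladder_config(case: str, base: ExperimentConfig) -> ExperimentConfig:
    """Cumulative ageing-toggle configuration for one ladder case."""
    if case not in LADDER_CASES:
        raise ValueError(f"unknown ladder case {case!r}")
    d = base.to_dict()
    if case == "young":
        d["age"] = base.reference_age
        d["toggles"] = asdict(AgeingToggles())
    else:
        order = ["fluid", "tissues", "vasomotion", "sweating"]
        upto = order[: order.index(case) + 1]
        d["toggles"] = {name: (name in upto) for name in
                        ["fluid", "tissues", "vasomotion", "sweating"]}
        d["toggles"]["shivering"] = False
    return ExperimentConfig.from_dict(d)


def run_ladder(base: ExperimentConfig,
               cases: tuple[str, ...] = LADDER_CASES
               ) -> dict[str, CoupledResult]:
    """Run the hot-exposure experiment for each toggle case."""
    return {case: run_coupled(ladder_config(case, base)) for case in cases}


# ---------------------------------------------------------------------------
# Output plumbing
# ---------------------------------------------------------------------------

def write_with_metadata(frame, path, config: dict) -> dict:
    """Write a CSV plus a JSON sidecar embedding config and content hash."""
    path = Path(path)
    csv_text = frame.to_csv(index=False)
    path.write_text(csv_text)
    meta = {
        "config": config,
        "sha256": hashlib.sha256(csv_text.encode()).hexdigest(),
        "rows": int(len(frame)),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    return meta
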