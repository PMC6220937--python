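"""Elastic-tube arterial network: data model, constitutive law, I/O, fixtures.

A network is a directed tree of 1D elastic vessels.  Each vessel carries a
(possibly linearly tapering) unstressed area ``A0`` and wall parameter
``beta`` entering the tube law ``p = p_ext + beta*(sqrt(A) - sqrt(A0))``.
The tree has one inlet vessel (fed by the left-ventricle model), internal
junctions (one parent, one or more daughters) and terminal vessels.
Peripheral circulation is represented by short *terminal taper* vessels with
a step decrease in A0 (step increase in beta): their raised characteristic
impedance supplies both the resistive load and the physiological wave
reflection, with an optional extra reflection coefficient ``R_R`` at the
very outlet.

Networks are stored as versioned JSON documents (``schema: 1``); a seeded
synthetic binary-tree generator provides test fixtures, since no anatomical
atlas is shipped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _tables as tbl
from . import units
from .ageing import AgeingParameters, terminal_resistance_factor

CATEGORIES = ("core", "central", "transversal", "terminal_taper")


# ---------------------------------------------------------------------------
# Constitutive relations
# ---------------------------------------------------------------------------

def pressure_from_area(A, A0, beta, p_ext=0.0):
    """Tube law: p = p_ext + beta*(sqrt(A) - sqrt(A0)).  CGS pressures."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("non-positive cross-sectional area in tube law")
    return p_ext + beta * (np.sqrt(A) - np.sqrt(A0))


def area_from_pressure(p, A0, beta, p_ext=0.0):
    """Inverse tube law."""
    root = (np.asarray(p, dtype=float) - p_ext) / beta + math.sqrt(A0)
    if np.any(root <= 0):
        raise ValueError("pressure below collapse limit of the tube law")
    return root ** 2


def beta_from_wall(h_w: float, E: float, A0: float, sigma: float = 0.5) -> float:
    """Wall parameter from thickness, Young's modulus and Poisson ratio.

    beta = sqrt(pi) * h_w * E / (A0 * (1 - sigma^2)); CGS units.
    """
    if not 0 < sigma < 1:
        raise ValueError("Poisson ratio must lie in (0, 1)")
    if min(h_w, E, A0) <= 0:
        raise ValueError("wall thickness, modulus and area must be positive")
    return math.sqrt(math.pi) * h_w * E / (A0 * (1.0 - sigma ** 2))


def wave_speed(beta, A, rho):
    """Intrinsic wave speed c = sqrt(beta*sqrt(A)/(2 rho)) [cm/s]."""
    return np.sqrt(beta * np.sqrt(A) / (2.0 * rho))


def beta_from_wave_speed(c: float, A0: float, rho: float) -> float:
    """Invert the wave-speed relation at the unstressed area."""
    return 2.0 * rho * c * c / math.sqrt(A0)


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class Vessel:
    """One elastic 1D segment with linear taper in A0 and beta."""

    id: str
    length: float            # cm
    n_elements: int
    A0_prox: float           # cm2
    A0_dist: float
    beta_prox: float         # dyn/cm3
    beta_dist: float
    category: str = "central"
    trunk: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"vessel {self.id}: unknown category "
                             f"{self.category!r}")
        if self.length <= 0 or self.n_elements < 1:
            raise ValueError(f"vessel {self.id}: non-positive discretisation")
        if min(self.A0_prox, self.A0_dist, self.beta_prox, self.beta_dist) <= 0:
            raise ValueError(f"vessel {self.id}: non-positive A0 or beta")

    @property
    def n_nodes(self) -> int:
        return self.n_elements + 1

    @property
    def dx(self) -> float:
        return self.length / self.n_elements

    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_nodes)

    def A0(self) -> np.ndarray:
        return np.linspace(self.A0_prox, self.A0_dist, self.n_nodes)

    def beta(self) -> np.ndarray:
        return np.linspace(self.beta_prox, self.beta_dist, self.n_nodes)

    def midpoint_diameter_mm(self) -> float:
        a_mid = 0.5 * (self.A0_prox + self.A0_dist)
        return 2.0 * math.sqrt(a_mid / math.pi) * 10.0


@dataclass
class Junction:
    parent: str
    daughters: list[str]


@dataclass
class ArterialNetwork:
    """Directed tree of vessels with one inlet and taper/reflection terminals."""

    vessels: dict[str, Vessel]
    junctions: list[Junction]
    inlet: str
    terminals: dict[str, float]          # vessel id -> reflection coeff R_R
    fluid: dict = field(default_factory=lambda: {
        "rho": tbl.BLOOD_RHO, "mu": tbl.BLOOD_MU, "alpha": tbl.BLOOD_ALPHA,
        "cp": tbl.BLOOD_CP, "h_in": tbl.H_IN, "p_ext_mmHg": 0.0,
    })
    reference_age: float = 40.0
    name: str = "unnamed"

    # -- topology helpers ---------------------------------------------------
    def parents(self) -> dict[str, str]:
        out = {}
        for j in self.junctions:
            for d in j.daughters:
                out[d] = j.parent
        return out

    def validate(self) -> list[str]:
        """Return the full list of schema/topology violations (empty = OK)."""
        errors: list[str] = []
        if self.inlet not in self.vessels:
            errors.append(f"inlet vessel {self.inlet!r} not defined")
        seen_daughters: dict[str, str] = {}
        for j in self.junctions:
            if j.parent not in self.vessels:
                errors.append(f"junction parent {j.parent!r} not defined")
            if not j.daughters:
                errors.append(f"junction at {j.parent!r} has no daughters")
            for d in j.daughters:
                if d not in self.vessels:
                    errors.append(f"daughter {d!r} not defined")
                if d in seen_daughters:
                    errors.append(
                        f"vessel {d!r} has two parents "
                        f"({seen_daughters[d]!r} and {j.parent!r})")
                seen_daughters[d] = j.parent
                if d == self.inlet:
                    errors.append("inlet vessel cannot be a daughter")
        # connectivity: walk from inlet
        children: dict[str, list[str]] = {}
        for j in self.junctions:
            children.setdefault(j.parent, []).extend(j.daughters)
        reached, stack = set(), [self.inlet]
        while stack:
            v = stack.pop()
            if v in reached or v not in self.vessels:
                continue
            reached.add(v)
            stack.extend(children.get(v, []))
        for vid in self.vessels:
            if vid not in reached:
                errors.append(f"vessel {vid!r} unreachable from inlet")
        # leaves must be terminals and vice versa
        nonleaf = {j.parent for j in self.junctions}
        for vid in self.vessels:
            if vid not in nonleaf and vid not in self.terminals:
                errors.append(f"leaf vessel {vid!r} has no terminal entry")
        for vid, rr in self.terminals.items():
            if vid not in self.vessels:
                errors.append(f"terminal {vid!r} not defined")
            elif vid in nonleaf:
                errors.append(f"terminal {vid!r} is not a leaf")
            if not 0.0 <= rr <= 1.0:
                errors.append(f"terminal {vid!r}: R_R={rr} outside [0, 1]")
        parent_of = self.parents()
        for v in self.vessels.values():
            if v.category == "terminal_taper" and v.id in parent_of:
                pa = self.vessels.get(parent_of[v.id])
                if pa is not None and v.A0_prox >= pa.A0_dist:
                    errors.append(
                        f"terminal taper {v.id!r} lacks a step decrease in A0 "
                        f"relative to parent {pa.id!r}")
        return errors

    def require_valid(self) -> "ArterialNetwork":
        errs = self.validate()
        if errs:
            raise ValueError("invalid network:\n  " + "\n  ".join(errs))
        return self

    @property
    def p_ext(self) -> float:
        """External pressure in dyn/cm2."""
        return units.dyn(self.fluid.get("p_ext_mmHg", 0.0))

    # -- document I/O -------------------------------------------------------
    def to_document(self) -> dict:
        return {
            "schema": 1,
            "name": self.name,
            "reference_age": self.reference_age,
            "fluid": dict(self.fluid),
            "inlet": self.inlet,
            "vessels": [
                {"id": v.id, "length_cm": v.length, "n_elements": v.n_elements,
                 "A0_prox_cm2": v.A0_prox, "A0_dist_cm2": v.A0_dist,
                 "beta_prox": v.beta_prox, "beta_dist": v.beta_dist,
                 "category": v.category, "trunk": v.trunk}
                for v in self.vessels.values()
            ],
            "junctions": [{"parent": j.parent, "daughters": list(j.daughters)}
                          for j in self.junctions],
            "terminals": dict(self.terminals),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_document(), indent=2,
                                         sort_keys=True) + "\n")

    def copy(self) -> "ArterialNetwork":
        return load_network(self.to_document())


def load_network(document) -> ArterialNetwork:
    """Build a validated network from a JSON document (dict, str or path)."""
    if isinstance(document, (str, Path)):
        document = json.loads(Path(document).read_text())
    if document.get("schema") != 1:
        raise ValueError(f"unsupported network schema {document.get('schema')!r}")
    vessels = {}
    for row in document["vessels"]:
        v = Vessel(
            id=str(row["id"]), length=float(row["length_cm"]),
            n_elements=int(row["n_elements"]),
            A0_prox=float(row["A0_prox_cm2"]), A0_dist=float(row["A0_dist_cm2"]),
            beta_prox=float(row["beta_prox"]), beta_dist=float(row["beta_dist"]),
            category=row.get("category", "central"),
            trunk=bool(row.get("trunk", False)),
        )
        if v.id in vessels:
            raise ValueError(f"duplicate vessel id {v.id!r}")
        vessels[v.id] = v
    net = ArterialNetwork(
        vessels=vessels,
        junctions=[Junction(str(j["parent"]), [str(d) for d in j["daughters"]])
                   for j in document.get("junctions", [])],
        inlet=str(document["inlet"]),
        terminals={str(k): float(v)
                   for k, v in document.get("terminals", {}).items()},
        fluid=dict(document.get("fluid", {})) or None or {
            "rho": tbl.BLOOD_RHO, "mu": tbl.BLOOD_MU, "alpha": tbl.BLOOD_ALPHA,
            "cp": tbl.BLOOD_CP, "h_in": tbl.H_IN, "p_ext_mmHg": 0.0},
        reference_age=float(document.get("reference_age", 40.0)),
        name=document.get("name", "unnamed"),
    )
    return net.require_valid()


def save_network(network: ArterialNetwork, path) -> None:
    network.save(path)


# ---------------------------------------------------------------------------
# Ageing application
# ---------------------------------------------------------------------------

def apply_ageing(network: ArterialNetwork, params: AgeingParameters
                 ) -> ArterialNetwork:
    """Return an aged copy of the network.

    Unstressed areas never change with age; only ``beta`` does.

    * ``uniform_all`` / ``uniform_trunk`` multiply beta of every non-taper
      vessel (resp. only trunk-flagged vessels) by the compliance-based
      factor relative to the network's reference age.
    * ``specific`` recomputes beta of every non-taper vessel from the
      diameter/PWV fit at the target age.
    * Terminal tapers follow the terminal-resistance law: the characteristic
      impedance scales as sqrt(beta) at fixed area, so beta is multiplied by
      the squared resistance ratio relative to the reference age.
    """
    aged = network.copy()
    rho = aged.fluid["rho"]
    mode = params.stiffening_mode
    beta_factor = params.beta_factor(network.reference_age)
    term_rel = (params.terminal_factor /
                terminal_resistance_factor(network.reference_age,
                                           params.terminal_model))
    for v in aged.vessels.values():
        if v.category == "terminal_taper":
            v.beta_prox *= term_rel ** 2
            v.beta_dist *= term_rel ** 2
        elif mode == "specific":
            for attr_a, attr_b in (("A0_prox", "beta_prox"),
                                   ("A0_dist", "beta_dist")):
                a0 = getattr(v, attr_a)
                d_mm = 2.0 * math.sqrt(a0 / math.pi) * 10.0
                c = params.pwv(d_mm) * units.M_PER_S_TO_CM_PER_S
                setattr(v, attr_b, beta_from_wave_speed(c, a0, rho))
        elif mode == "uniform_all" or (mode == "uniform_trunk" and v.trunk):
            v.beta_prox *= beta_factor
            v.beta_dist *= beta_factor
    return aged


# ---------------------------------------------------------------------------
# Synthetic fixture generator
# ---------------------------------------------------------------------------

def generate_synthetic_network(
    n_generations: int = 2,
    seed: int = 0,
    *,
    root_area: float = 4.0,          # cm2
    root_wave_speed: float = 600.0,  # cm/s
    root_length: float = 14.0,       # cm
    area_ratio: float = 1.16,        # total daughter/parent area
    speed_ratio: float = 1.08,       # per-generation wave-speed growth
    length_ratio: float = 0.75,
    total_resistance_mmhg_s_ml: float = 1.0,
    taper_wave_speed: float = 1200.0,  # cm/s, sets taper impedance/area
    taper_length: float = 2.0,
    target_dx: float = 0.5,          # cm
    terminal_R_R: float = 0.0,
) -> ArterialNetwork:
    """Deterministic synthetic binary arterial tree plus terminal tapers.

    ``n_generations`` levels of symmetric bifurcations below the root give
    ``2**(n+1) - 1`` tree vessels and ``2**n`` terminals; each leaf gets a
    short stiff taper whose characteristic impedances in parallel add up to
    ``total_resistance_mmhg_s_ml``.  Geometry is mildly jittered by the
    seeded RNG (same seed -> identical document).  Wave speeds stay inside
    the physiological 2-15 m/s envelope.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = np.random.default_rng(seed)
    rho = tbl.BLOOD_RHO
    vessels: dict[str, Vessel] = {}
    junctions: list[Junction] = []
    terminals: dict[str, float] = {}

    def n_elem(length: float) -> int:
        return max(4, int(round(length / target_dx)))

    def add_vessel(vid, length, a0, c0, category, trunk):
        beta = beta_from_wave_speed(c0, a0, rho)
        vessels[vid] = Vessel(id=vid, length=length, n_elements=n_elem(length),
                              A0_prox=a0, A0_dist=a0, beta_prox=beta,
                              beta_dist=beta, category=category, trunk=trunk)

    # breadth-first construction
    leaves: list[tuple[str, float, float]] = []  # (id, area, speed)
    add_vessel("v0", root_length * (1 + 0.1 * rng.uniform(-1, 1)),
               root_area, root_wave_speed, "core", True)
    frontier = [("v0", root_area, root_wave_speed, root_length)]
    counter = 1
    for gen in range(1, n_generations + 1):
        new_frontier = []
        for pid, pa, pc, plen in frontier:
            da = pa * area_ratio / 2.0
            dc = pc * speed_ratio
            dlen = plen * length_ratio
            ids = []
            for _ in range(2):
                vid = f"v{counter}"
                counter += 1
                add_vessel(vid, dlen * (1 + 0.1 * rng.uniform(-1, 1)), da, dc,
                           "central" if gen > 1 else "core", gen == 1)
                ids.append(vid)
                new_frontier.append((vid, da, dc, dlen))
            junctions.append(Junction(pid, ids))
        frontier = new_frontier
    leaves = [(vid, a, c) for vid, a, c, _ in frontier]

    # terminal tapers: impedance per terminal = n_term * R_total
    n_term = len(leaves)
    z_term = (total_resistance_mmhg_s_ml * units.MMHG_S_PER_ML_TO_CGS * n_term)
    a_taper = taper_wave_speed * rho / z_term
    for vid, a_leaf, _ in leaves:
        tid = f"{vid}t"
        a_t = min(a_taper, 0.6 * a_leaf)  # enforce a genuine step decrease
        c_t = z_term * a_t / rho
        beta_t = beta_from_wave_speed(c_t, a_t, rho)
        vessels[tid] = Vessel(id=tid, length=taper_length,
                              n_elements=n_elem(taper_length),
                              A0_prox=a_t, A0_dist=a_t,
                              beta_prox=beta_t, beta_dist=beta_t,
                              category="terminal_taper", trunk=False)
        junctions.append(Junction(vid, [tid]))
        terminals[tid] = terminal_R_R

    net = ArterialNetwork(vessels=vessels, junctions=junctions, inlet="v0",
                          terminals=terminals, reference_age=40.0,
                          name=f"synthetic-g{n_generations}-s{seed}")
    return net.require_valid()
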