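"""Layered-cylinder bioheat conduction model of the passive body.

The body is 14 solid circular cylinders (head, neck, thorax, abdomen and
paired shoulders, arms, forearms, thighs, legs), each a stack of concentric
tissue layers (inner organ / bone / muscle / fat / skin).  Heat moves
radially by conduction,

    rho_t c_t dT/dt - k_t (1/r) d/dr (r dT/dr)
        = q_v + cp rho [ phi (T_pool - T_t) + vessel convective sources ],

discretised with a cell-centred finite-volume scheme in r (node spacing
<= 1 mm, faces pinned at layer interfaces, harmonic-mean interface
conductances) and integrated with backward Euler, which is unconditionally
stable.  Perfusion exchanges heat with a central blood pool whose
temperature is the perfusion-weighted mean tissue temperature (so the pool
itself stores no energy).  Skin cells exchange with the environment through
Newton cooling, linearised radiation and an explicit evaporative flux.

Geometry at the 30-year reference age reproduces the shipped tissue table
exactly; ageing rescales muscle/fat/skin layer thicknesses (bone and inner
organs keep their radii), bone density (and with it conductivity) and the
basal metabolic sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from . import _tables as tbl
from . import units
from .ageing import (TissueScalings, bone_conductivity, resting_metabolic_rate,
                     tissue_scalings)

CORE_TISSUES = ("brain", "lung", "viscera")


@dataclass
class Environment:
    """Ambient conditions seen by the skin."""

    T_air: float = 30.0       # degC
    RH: float = 40.0          # %
    T_surr: float | None = None  # radiant temperature; defaults to T_air
    h_con: float = 5.0e-4     # W/(cm2 degC), convective coefficient
    h_rad: float = 4.7e-4     # W/(cm2 degC), linearised radiation

    def __post_init__(self) -> None:
        if self.T_surr is None:
            self.T_surr = self.T_air

    @property
    def h_tot(self) -> float:
        return self.h_con + self.h_rad

    @property
    def T_eff(self) -> float:
        """Convection/radiation-weighted effective sink temperature."""
        return (self.h_con * self.T_air + self.h_rad * self.T_surr) / self.h_tot


@dataclass
class TissueLayer:
    tissue: str
    r_in: float     # cm
    r_out: float
    k: float        # W/(cm degC)
    rho: float      # g/cm3
    c: float        # J/(g degC)
    qv0: float      # W/cm3, basal metabolic source
    phi: float      # 1/s, basal perfusion

    def __post_init__(self) -> None:
        if self.r_out <= self.r_in:
            raise ValueError(f"{self.tissue}: non-increasing layer radii")
        if min(self.k, self.rho, self.c) <= 0:
            raise ValueError(f"{self.tissue}: non-positive properties")


class Cylinder:
    """One body segment: radial FV grid over a stack of tissue layers."""

    def __init__(self, name: str, segment: str, layers: list[TissueLayer],
                 length: float, dr_target: float = 0.1,
                 inner_radius: float = 0.0):
        self.name = name
        self.segment = segment
        self.layers = layers
        self.length = length
        self.inner_radius = inner_radius

        faces = [inner_radius]
        cell_tissue: list[str] = []
        for lay in layers:
            h = lay.r_out - lay.r_in
            n = max(1, int(math.ceil(h / dr_target)))
            edges = np.linspace(lay.r_in, lay.r_out, n + 1)
            faces.extend(edges[1:].tolist())
            cell_tissue.extend([lay.tissue] * n)
        self.faces = np.asarray(faces)
        self.r = 0.5 * (self.faces[:-1] + self.faces[1:])
        self.n_cells = len(self.r)
        self.tissue = np.asarray(cell_tissue)

        by_tissue = {lay.tissue: lay for lay in layers}
        self.k = np.array([by_tissue[t].k for t in cell_tissue])
        self.rho = np.array([by_tissue[t].rho for t in cell_tissue])
        self.c = np.array([by_tissue[t].c for t in cell_tissue])
        self.qv0 = np.array([by_tissue[t].qv0 for t in cell_tissue])
        self.phi = np.array([by_tissue[t].phi for t in cell_tissue])

        L = length
        self.V = math.pi * (self.faces[1:] ** 2 - self.faces[:-1] ** 2) * L
        self.A_face = 2.0 * math.pi * self.faces * L  # at every face
        self.A_ext = float(self.A_face[-1])
        self.r_ext = float(self.faces[-1])

        # inter-cell conductances G[i]: between cell i and i+1 [W/degC]
        rf = self.faces[1:-1]
        d1 = rf - self.r[:-1]
        d2 = self.r[1:] - rf
        self.G = self.A_face[1:-1] / (d1 / self.k[:-1] + d2 / self.k[1:])
        # half-cell conductance from the outermost cell centre to the surface
        self.G_surf = self.k[-1] * self.A_ext / (self.r_ext - self.r[-1])
        # and from the innermost cell centre to the inner surface (annulus)
        if inner_radius > 0:
            A_in = float(self.A_face[0])
            self.G_inner = self.k[0] * A_in / (self.r[0] - inner_radius)
        else:
            self.G_inner = 0.0

        self.T = np.full(self.n_cells, 37.0)
        self.q_shiv = np.zeros(self.n_cells)       # W/cm3
        self.q_extra = np.zeros(self.n_cells)      # W/cm3 (respiration)
        self.q_vessel = np.zeros(self.n_cells)     # W/cm3 (artery coupling)
        self.phi_skin_override: float | None = None
        self.T_surface = 37.0

        self.skin_mask = self.tissue == "skin"
        self.muscle_mask = self.tissue == "muscle"
        self.core_mask = np.isin(self.tissue, CORE_TISSUES)

    # -- derived quantities ---------------------------------------------------
    @property
    def skin_mass(self) -> float:
        return float(np.sum((self.rho * self.V)[self.skin_mask]))

    @property
    def muscle_volume(self) -> float:
        return float(np.sum(self.V[self.muscle_mask]))

    def effective_phi(self) -> np.ndarray:
        phi = self.phi.copy()
        if self.phi_skin_override is not None:
            phi[self.skin_mask] = self.phi_skin_override
        return phi

    def heat_capacity(self) -> np.ndarray:
        return self.rho * self.c * self.V  # J/degC per cell

    # -- time integration -----------------------------------------------------
    def step(self, dt: float, T_pool: float, env: Environment | None,
             Q_sweat: float = 0.0,
             outer_mode: str = "robin", outer_value: float | None = None,
             inner_mode: str = "zero_flux", inner_value: float | None = None,
             rho_bl: float = tbl.BLOOD_RHO, cp_bl: float = tbl.BLOOD_CP
             ) -> None:
        """Backward-Euler update of the radial temperature profile.

        ``Q_sweat`` [W] leaves through the outer surface (treated
        explicitly).  ``outer_mode`` is ``robin`` (convection + radiation
        against ``env``), ``dirichlet`` (surface held at ``outer_value``) or
        ``insulated``; ``inner_mode`` is ``zero_flux`` or ``dirichlet``
        (annulus test geometries only).
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        n = self.n_cells
        cap = self.heat_capacity() / dt
        lower = np.zeros(n)
        diag = cap.copy()
        upper = np.zeros(n)
        rhs = cap * self.T

        # conduction between cells
        diag[:-1] += self.G
        diag[1:] += self.G
        upper[1:] = -self.G      # superdiagonal storage for solve_banded
        lower[:-1] = -self.G     # subdiagonal

        # perfusion against the blood pool (implicit in T)
        phi = self.effective_phi()
        w = rho_bl * cp_bl * phi * self.V
        diag += w
        rhs += w * T_pool

        # metabolic + shivering + extra volumetric sources (explicit)
        rhs += (self.qv0 + self.q_shiv + self.q_extra + self.q_vessel) * self.V

        # outer boundary
        if outer_mode == "robin":
            if env is None:
                raise ValueError("robin outer boundary needs an environment")
            h_area = env.h_tot * self.A_ext
            G_env = 1.0 / (1.0 / self.G_surf + 1.0 / h_area)
            diag[-1] += G_env
            rhs[-1] += G_env * env.T_eff - Q_sweat
        elif outer_mode == "dirichlet":
            diag[-1] += self.G_surf
            rhs[-1] += self.G_surf * float(outer_value)
        elif outer_mode == "insulated":
            rhs[-1] -= Q_sweat
        else:
            raise ValueError(f"unknown outer boundary mode {outer_mode!r}")

        # inner boundary
        if inner_mode == "dirichlet":
            if self.G_inner == 0.0:
                raise ValueError("dirichlet inner boundary needs an annulus")
            diag[0] += self.G_inner
            rhs[0] += self.G_inner * float(inner_value)
        elif inner_mode != "zero_flux":
            raise ValueError(f"unknown inner boundary mode {inner_mode!r}")

        ab = np.zeros((3, n))
        ab[0] = upper
        ab[1] = diag
        ab[2] = lower
        self.T = solve_banded((1, 1), ab, rhs)

        # surface temperature from the outer-face flux balance
        if outer_mode == "robin":
            h_area = env.h_tot * self.A_ext
            self.T_surface = float(
                (self.G_surf * self.T[-1] + h_area * env.T_eff - Q_sweat)
                / (self.G_surf + h_area))
        elif outer_mode == "dirichlet":
            self.T_surface = float(outer_value)
        else:
            self.T_surface = float(self.T[-1])

    def solve_steady(self, **kwargs) -> np.ndarray:
        """Steady profile: one backward-Euler step with a huge dt."""
        self.step(dt=1e12, T_pool=float(np.mean(self.T)), **kwargs)
        return self.T


@dataclass
class BodyModel:
    """The 14-cylinder passive system plus global bookkeeping."""

    age: float
    cylinders: list[Cylinder]
    environment: Environment = field(default_factory=Environment)
    rho_bl: float = tbl.BLOOD_RHO
    cp_bl: float = tbl.BLOOD_CP

    def __post_init__(self) -> None:
        self.by_name = {c.name: c for c in self.cylinders}

    # -- global geometry ------------------------------------------------------
    @property
    def A_sk_glob(self) -> float:
        """Total external skin area [cm2]."""
        return sum(c.A_ext for c in self.cylinders)

    @property
    def V_mus_glob(self) -> float:
        """Total muscle volume [cm3]."""
        return sum(c.muscle_volume for c in self.cylinders)

    # -- indicators -----------------------------------------------------------
    def thermal_indicators(self) -> tuple[float, float]:
        """(T_cr, T_sk_mean): mass-weighted core, area-weighted skin."""
        m_sum = t_sum = 0.0
        for c in self.cylinders:
            if np.any(c.core_mask):
                m = (c.rho * c.V)[c.core_mask]
                m_sum += float(np.sum(m))
                t_sum += float(np.sum(m * c.T[c.core_mask]))
        T_cr = t_sum / m_sum
        a_sum = sum(c.A_ext for c in self.cylinders)
        T_sk = sum(c.A_ext * c.T_surface for c in self.cylinders) / a_sum
        return T_cr, T_sk

    def blood_pool_temperature(self) -> float:
        """Perfusion-weighted mean tissue temperature (zero-capacity pool)."""
        num = den = 0.0
        for c in self.cylinders:
            w = c.effective_phi() * c.V
            num += float(np.sum(w * c.T))
            den += float(np.sum(w))
        return num / den if den > 0 else 37.0

    def total_energy(self) -> float:
        """Stored thermal energy relative to 0 degC [J]."""
        return sum(float(np.sum(c.heat_capacity() * c.T))
                   for c in self.cylinders)

    def basal_production(self) -> float:
        """Whole-body basal metabolic power including respiration sink [W]."""
        return sum(float(np.sum((c.qv0 + c.q_extra) * c.V))
                   for c in self.cylinders)

    def set_uniform_temperature(self, T: float) -> None:
        for c in self.cylinders:
            c.T[:] = T
            c.T_surface = T

    def step(self, dt: float, Q_sweat_by_segment: dict[str, float]
             | None = None) -> None:
        """Advance every cylinder one backward-Euler step."""
        T_pool = self.blood_pool_temperature()
        q = Q_sweat_by_segment or {}
        for c in self.cylinders:
            c.step(dt, T_pool, self.environment, Q_sweat=q.get(c.name, 0.0),
                   rho_bl=self.rho_bl, cp_bl=self.cp_bl)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _aged_radii(segment: str, layers: list[tuple[str, float]],
                scal: TissueScalings | None, ref: TissueScalings | None
                ) -> list[tuple[str, float, float]]:
    """(tissue, r_in, r_out) per layer with age-scaled thicknesses.

    Thickness ratios are evaluated relative to the 30-year reference fits;
    bone and inner organs keep their thickness (bone changes density, not
    geometry).
    """
    out = []
    prev_ref = 0.0  # reference-geometry outer radius of the previous layer
    for tissue, r_out_ref in layers:
        h = r_out_ref - prev_ref
        prev_ref = r_out_ref
        # scale relative to reference-age fit value
        if scal is not None and ref is not None:
            if tissue == "muscle":
                h *= scal.muscle(segment) / ref.muscle(segment)
            elif tissue == "fat":
                h *= scal.fat(segment) / ref.fat(segment)
            elif tissue == "skin":
                h *= scal.skin / ref.skin
        if h <= 0:
            raise ValueError(
                f"{segment}/{tissue}: layer thickness {h:.4g} <= 0 after "
                f"age scaling")
        r_in = out[-1][2] if out else 0.0
        out.append((tissue, r_in, r_in + h))
    return out


def build_body(xi: float, scalings: TissueScalings | None = None,
               properties: dict | None = None,
               environment: Environment | None = None,
               dr_target: float = 0.1,
               reference_age: float = 30.0,
               respiration_fraction: float = 0.09,
               age_tissues: bool = True) -> BodyModel:
    """Assemble the 14-cylinder body at age ``xi``.

    ``age_tissues=False`` keeps the reference geometry/properties regardless
    of ``xi`` (used by the ageing-toggle experiments).  The basal metabolic
    sources are normalised so that whole-body production at the reference
    age equals the resting-metabolic-rate regression (in W), then scaled by
    the per-tissue metabolic ageing ratio; a fixed fraction of production is
    removed at the lung as respiration loss.
    """
    props = {t: dict(p) for t, p in (properties or tbl.TISSUE_PROPERTIES).items()}
    ref = tissue_scalings(reference_age)
    if not age_tissues:
        scal = None
        met_ratio = 1.0
        rho_bo = tbl.BONE_DENSITY_YOUNG
    else:
        scal = scalings or tissue_scalings(xi)
        met_ratio = scal.metabolic / ref.metabolic
        rho_bo = tbl.BONE_DENSITY_YOUNG * scal.bone_density / ref.bone_density
    props["bone"]["rho"] = rho_bo
    props["bone"]["k"] = (bone_conductivity(rho_bo)
                          * units.W_PER_MK_TO_W_PER_CMK)

    cylinders: list[Cylinder] = []
    for segment, geom in tbl.BODY_GEOMETRY.items():
        radii = _aged_radii(segment, geom["layers"], scal, ref if scal else None)
        names = ([segment] if tbl.SEGMENT_MULT[segment] == 1
                 else [f"{segment}_L", f"{segment}_R"])
        for name in names:
            layers = []
            for tissue, r_in, r_out in radii:
                p = props[tissue]
                layers.append(TissueLayer(
                    tissue=tissue, r_in=r_in, r_out=r_out, k=p["k"],
                    rho=p["rho"], c=p["c"], qv0=p["qv0"],
                    phi=p["phi"] if p["phi"] is not None else 0.0))
            cylinders.append(Cylinder(name, segment, layers, geom["length"],
                                      dr_target=dr_target))

    body = BodyModel(age=xi, cylinders=cylinders,
                     environment=environment or Environment())

    # normalise basal sources to the RMR regression at the reference age
    raw_total = sum(float(np.sum(c.qv0 * c.V)) for c in cylinders)
    target_ref = (resting_metabolic_rate(reference_age)
                  * units.KCAL_PER_MIN_TO_W)
    norm = target_ref / raw_total
    for c in cylinders:
        c.qv0 *= norm * met_ratio

    # basal skin perfusion from the cutaneous-flow table
    for c in cylinders:
        base_flow = tbl.SKIN_FLOW_PRINTED[c.segment][0]  # cm3/s per instance
        c.phi[c.skin_mask] = base_flow * body.rho_bl / c.skin_mass

    # respiration: negative volumetric source on lung cells
    production = sum(float(np.sum(c.qv0 * c.V)) for c in cylinders)
    thorax = body.by_name["thorax"]
    lung_mask = thorax.tissue == "lung"
    V_lung = float(np.sum(thorax.V[lung_mask]))
    thorax.q_extra[lung_mask] -= respiration_fraction * production / V_lung

    return body


# ---------------------------------------------------------------------------
# Artery-tissue coupling table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselCoupling:
    vessel: str
    cylinder: str
    mode: str          # core | central | transversal
    cell_index: int    # tissue cell receiving / providing the heat


def couple_arteries(network, body: BodyModel, mapping: dict
                    ) -> list[VesselCoupling]:
    """Validate and resolve the vessel->cylinder thermal mapping.

    ``mapping`` maps vessel id to ``{"cylinder": name, "class": mode}``.
    Core vessels are adiabatic (their inlet is reset to the core
    temperature by the driver); central vessels exchange at the cylinder's
    innermost cell; transversal vessels act as volumetric sources in the
    host muscle layer.
    """
    table: list[VesselCoupling] = []
    for vid, entry in mapping.items():
        if vid not in network.vessels:
            raise ValueError(f"mapping references unknown vessel {vid!r}")
        mode = entry.get("class", "central")
        if mode not in ("core", "central", "transversal"):
            raise ValueError(f"vessel {vid!r}: unknown thermal class {mode!r}")
        cyl_name = entry["cylinder"]
        if cyl_name not in body.by_name:
            raise ValueError(
                f"vessel {vid!r} mapped to missing cylinder {cyl_name!r}")
        cyl = body.by_name[cyl_name]
        if mode == "central":
            cell = 0
        elif mode == "transversal":
            idx = np.flatnonzero(cyl.muscle_mask)
            cell = int(idx[len(idx) // 2]) if idx.size else 0
        else:
            cell = -1
        table.append(VesselCoupling(vid, cyl_name, mode, cell))
    return table
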