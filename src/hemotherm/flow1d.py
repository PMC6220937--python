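"""Explicit 1D solver for (A, u, T) pulse-wave propagation in elastic tubes.

The hyperbolic system (mass, momentum, energy of the cross-averaged flow)

    dA/dt + d(Au)/dx                = 0
    du/dt + d(u^2/2 + p/rho)/dx     = -8 pi mu u / (rho A)
    dT/dt + u dT/dx                 = alpha d2T/dx2
                                      + 2 h_in/(rho cp sqrt(A/pi)) (T_w - T)

with the tube law ``p = p_ext + beta (sqrt A - sqrt A0)`` is advanced with a
fully explicit two-step (predictor/corrector) Taylor-Galerkin scheme on
linear elements over a uniform grid — the classical Richtmyer form, second
order in space and time.  Boundary and junction values are imposed through
the characteristic variables

    w1 = u + 4c,   w2 = u - 4c,   w3 = T,   c = sqrt(beta sqrt(A)/(2 rho)),

extrapolated semi-Lagrangially along their wave speeds (``w`` at the
boundary at t+dt equals ``w`` at ``x -/+ lambda dt`` at t).  Terminals
reflect through ``w2 = w2_0 - R_R (w1 - w1_0)``; junctions solve mass
conservation + total-pressure continuity + characteristic compatibility
with Newton's method (batched over junctions of equal arity); the inlet is
driven by the left-ventricle model.

Implementation note: all vessels live in one zero-padded (n_vessels,
n_max_nodes) array family so every interior update is a handful of whole-
array operations; the per-vessel ``fields`` views expose the same data for
inspection and boundary writes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import units
from .heart import LVState, inlet_w1
from .network import ArterialNetwork, pressure_from_area, wave_speed


# ---------------------------------------------------------------------------
# Characteristic variables
# ---------------------------------------------------------------------------

def compute_characteristics(A, u, beta, rho, T=None):
    """(w1, w2[, w3]) from the primitive state."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("non-positive area in characteristic computation")
    c = wave_speed(beta, A, rho)
    w1 = u + 4.0 * c
    w2 = u - 4.0 * c
    if T is None:
        return w1, w2
    return w1, w2, np.asarray(T, dtype=float)


def invert_characteristics(w1, w2, beta, rho):
    """Closed-form (A, u) from (w1, w2): c = (w1 - w2)/8."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if np.any(w1 <= w2):
        raise ValueError("nonphysical state: w1 <= w2")
    c = (w1 - w2) / 8.0
    A = (2.0 * rho * c * c / beta) ** 2
    u = 0.5 * (w1 + w2)
    return A, u


class SolverError(RuntimeError):
    pass


@dataclass
class VesselField:
    """Views into the solver state for one vessel."""

    A: np.ndarray
    u: np.ndarray
    T: np.ndarray
    A0: np.ndarray
    beta: np.ndarray
    dx: float

    def pressure(self, p_ext: float) -> np.ndarray:
        return pressure_from_area(self.A, self.A0, self.beta, p_ext)


@dataclass
class Probe:
    vessel: str
    frac: float  # 0 = proximal, 1 = distal

    def node(self, n_nodes: int) -> int:
        return int(round(self.frac * (n_nodes - 1)))


@dataclass
class FlowRecord:
    """Time series recorded at probe locations."""

    t: np.ndarray
    probes: list[Probe]
    p_mmHg: np.ndarray   # (n_t, n_probes)
    Q: np.ndarray        # mL/s
    u: np.ndarray        # cm/s
    A: np.ndarray        # cm2
    T: np.ndarray        # degC
    lv: dict = field(default_factory=dict)  # per-sample LV trace

    def to_frame(self):
        import pandas as pd

        rows = []
        for j, pr in enumerate(self.probes):
            rows.append(pd.DataFrame({
                "t_s": self.t, "node": f"{pr.vessel}@{pr.frac:g}",
                "p_mmHg": self.p_mmHg[:, j], "Q_mL_s": self.Q[:, j],
                "u_cm_s": self.u[:, j], "A_cm2": self.A[:, j],
                "T_C": self.T[:, j],
            }))
        return pd.concat(rows, ignore_index=True)


class _JunctionGroup:
    """All junctions with the same daughter count, solved in one batch."""

    def __init__(self, n_daughters: int):
        self.n = n_daughters
        self.parents: list[str] = []
        self.daughters: list[list[str]] = []
        # filled by finalise()
        self.ip = self.np_ = self.id_ = None

    def finalise(self, row: dict[str, int], n_nodes: dict[str, int],
                 beta2d, A02d, dx1d) -> None:
        k, n = len(self.parents), self.n
        self.k = k
        self.ip = np.array([row[p] for p in self.parents])
        self.np_ = np.array([n_nodes[p] for p in self.parents])
        self.id_ = np.array([[row[d] for d in ds] for ds in self.daughters])
        self.beta_p = beta2d[self.ip, self.np_ - 1]
        self.A0p = A02d[self.ip, self.np_ - 1]
        self.beta_d = beta2d[self.id_, 0]
        self.A0d = A02d[self.id_, 0]
        self.dxp = dx1d[self.ip]
        self.dxd = dx1d[self.id_]
        self.sqA0p = np.sqrt(self.A0p)
        self.sqA0d = np.sqrt(self.A0d)


class FlowSolver:
    """Explicit characteristic-based solver over an arterial tree.

    Parameters
    ----------
    network
        Validated :class:`~hemotherm.network.ArterialNetwork`.
    dt
        Time step [s]; must satisfy the CFL bound (checked every step).
    lv
        Optional :class:`~hemotherm.heart.LVState` driving the inlet. If
        absent, ``inlet_w1_fn(t)`` prescribes the forward characteristic
        directly (wave/physics tests); with neither, the inlet holds its
        initial characteristic (quiescent).
    wall_temperature
        Tissue temperature seen by the fluid energy equation; a scalar or a
        dict vessel id -> scalar/array (updated externally by the thermal
        coupling).
    """

    def __init__(self, network: ArterialNetwork, dt: float,
                 lv: LVState | None = None,
                 inlet_w1_fn: Callable[[float], float] | None = None,
                 initial_T: float = 37.0,
                 wall_temperature: float | dict = 37.0,
                 inlet_temperature: float | None = None,
                 cfl_limit: float = 1.0,
                 junction_tol: float = 1e-10,
                 convect_heat: bool = True):
        network.require_valid()
        self.net = network
        self.dt = float(dt)
        self.lv = lv
        self.inlet_w1_fn = inlet_w1_fn
        self.t = 0.0
        self.step_count = 0
        fl = network.fluid
        self.rho = fl["rho"]
        self.mu = fl["mu"]
        self.alpha = fl["alpha"]
        self.cp = fl["cp"]
        self.h_in = fl["h_in"] if convect_heat else 0.0
        self.p_ext = network.p_ext
        self.cfl_limit = cfl_limit
        self.junction_tol = junction_tol
        self.wall_temperature = wall_temperature
        self.inlet_temperature = (initial_T if inlet_temperature is None
                                  else inlet_temperature)

        # ---- padded state arrays -------------------------------------------
        vids = list(network.vessels)
        self._vids = vids
        self._row = {vid: i for i, vid in enumerate(vids)}
        self._n = {vid: network.vessels[vid].n_nodes for vid in vids}
        nv = len(vids)
        nmax = max(self._n.values())
        self._nv, self._nmax = nv, nmax

        def padded(fill):
            return np.full((nv, nmax), float(fill))

        self._A = padded(1.0)
        self._u = padded(0.0)
        self._T = padded(initial_T)
        self._A0 = padded(1.0)
        self._beta = padded(1.0)
        self._dx = np.empty(nv)
        self._valid = np.zeros((nv, nmax), dtype=bool)
        for vid in vids:
            i, n = self._row[vid], self._n[vid]
            v = network.vessels[vid]
            self._A0[i, :n] = v.A0()
            self._beta[i, :n] = v.beta()
            self._A[i, :n] = v.A0()
            self._dx[i] = v.dx
            self._valid[i, :n] = True
            # pad with the last valid values so ufuncs stay finite
            self._A0[i, n:] = v.A0_dist
            self._beta[i, n:] = v.beta_dist
            self._A[i, n:] = v.A0_dist
        self._sqA0 = np.sqrt(self._A0)
        self._dxc = self._dx[:, None]
        # interior mask on the corrector stencil (nodes 1..n-2)
        self._int_mask = self._valid[:, 2:] & self._valid[:, :-2]
        self._mid_mask = self._valid[:, 1:] & self._valid[:, :-1]

        self.fields: dict[str, VesselField] = {}
        for vid in vids:
            i, n = self._row[vid], self._n[vid]
            self.fields[vid] = VesselField(
                A=self._A[i, :n], u=self._u[i, :n], T=self._T[i, :n],
                A0=self._A0[i, :n], beta=self._beta[i, :n], dx=self._dx[i])

        # ---- boundary bookkeeping ------------------------------------------
        self._w0: dict[tuple[str, int], tuple[float, float]] = {}
        f_in = self.fields[network.inlet]
        w1, w2 = compute_characteristics(f_in.A[0], f_in.u[0], f_in.beta[0],
                                         self.rho)
        self._w0[(network.inlet, 0)] = (float(w1), float(w2))
        for tid in network.terminals:
            f = self.fields[tid]
            w1, w2 = compute_characteristics(f.A[-1], f.u[-1], f.beta[-1],
                                             self.rho)
            self._w0[(tid, -1)] = (float(w1), float(w2))

        groups: dict[int, _JunctionGroup] = {}
        for j in network.junctions:
            g = groups.setdefault(len(j.daughters),
                                  _JunctionGroup(len(j.daughters)))
            g.parents.append(j.parent)
            g.daughters.append(list(j.daughters))
        for g in groups.values():
            g.finalise(self._row, self._n, self._beta, self._A0, self._dx)
        self._groups = list(groups.values())
        self._term_rows = np.array([self._row[tid]
                                    for tid in network.terminals])
        self._term_n = np.array([self._n[tid] for tid in network.terminals])

        self._wall_cache_scalar = not isinstance(wall_temperature, dict)

    # -- helpers --------------------------------------------------------------
    def wall_T(self, vid: str):
        wt = self.wall_temperature
        if isinstance(wt, dict):
            return wt.get(vid, 37.0)
        return wt

    def _wall_matrix(self) -> np.ndarray | float:
        wt = self.wall_temperature
        if not isinstance(wt, dict):
            return float(wt)
        M = np.full((self._nv, self._nmax), 37.0)
        for vid, val in wt.items():
            i, n = self._row[vid], self._n[vid]
            val = np.asarray(val, dtype=float)
            if val.ndim == 0:
                M[i, :n] = float(val)
            else:
                M[i, :n] = val
        return M

    def cfl_dt(self) -> float:
        """Largest stable time step under the current state."""
        c = wave_speed(self._beta, self._A, self.rho)
        r = self._dxc / (np.abs(self._u) + c)
        return float(np.min(np.where(self._valid, r, np.inf)))

    # -- interior update -------------------------------------------------------
    def _interior(self) -> None:
        dt, rho = self.dt, self.rho
        A, u, T = self._A, self._u, self._T
        dxc = self._dxc

        sqA = np.sqrt(A)
        c = np.sqrt(self._beta * sqA / (2.0 * rho))
        speed = (np.abs(u) + c) * dt / dxc
        cfl = float(np.max(np.where(self._valid, speed, 0.0)))
        if cfl > self.cfl_limit + 1e-12:
            raise SolverError(
                f"CFL violation: (|u|+c)*dt/dx = {cfl:.3f} > {self.cfl_limit}")
        if np.any(np.where(self._valid, A, 1.0) <= 0):
            raise SolverError("negative cross-sectional area")

        p_rho = self._beta * (sqA - self._sqA0) / rho
        F1 = A * u
        F2 = 0.5 * u * u + p_rho
        Sm = -8.0 * math.pi * self.mu * u / (rho * A)

        # predictor: element midpoints at t + dt/2
        lam = 0.5 * dt / dxc
        A_m = 0.5 * (A[:, :-1] + A[:, 1:]) - lam * np.diff(F1, axis=1)
        u_m = (0.5 * (u[:, :-1] + u[:, 1:]) - lam * np.diff(F2, axis=1)
               + 0.25 * dt * (Sm[:, :-1] + Sm[:, 1:]))
        if np.any(np.where(self._mid_mask, A_m, 1.0) <= 0):
            raise SolverError("negative area in predictor step")
        beta_m = 0.5 * (self._beta[:, :-1] + self._beta[:, 1:])
        sqA0_m = 0.5 * (self._sqA0[:, :-1] + self._sqA0[:, 1:])
        p_rho_m = beta_m * (np.sqrt(np.abs(A_m)) - sqA0_m) / rho
        F1_m = A_m * u_m
        F2_m = 0.5 * u_m * u_m + p_rho_m
        Sm_m = -8.0 * math.pi * self.mu * u_m / (rho * np.abs(A_m))

        # corrector on interior nodes
        lam2 = dt / dxc
        dA = -lam2 * np.diff(F1_m, axis=1)
        du = (-lam2 * np.diff(F2_m, axis=1)
              + 0.5 * dt * (Sm_m[:, :-1] + Sm_m[:, 1:]))
        m = self._int_mask
        A[:, 1:-1][m] += dA[m]
        u[:, 1:-1][m] += du[m]

        # temperature: two-step advection + explicit diffusion + wall source
        T_m = 0.5 * (T[:, :-1] + T[:, 1:]) - lam * u_m * np.diff(T, axis=1)
        Tw = self._wall_matrix()
        h_src = (2.0 * self.h_in / (rho * self.cp * np.sqrt(A / math.pi))
                 * (np.asarray(Tw) - T))
        dT = (-lam2 * u[:, 1:-1] * np.diff(T_m, axis=1)
              + dt * self.alpha * (T[:, 2:] - 2 * T[:, 1:-1] + T[:, :-2])
              / dxc ** 2
              + dt * h_src[:, 1:-1])
        T[:, 1:-1][m] += dT[m]

    # -- characteristic extrapolation ------------------------------------------
    @staticmethod
    def _lin(w_end, w_prev, s, dx):
        """Value a clipped distance ``s`` inside the vessel from the end."""
        s = np.clip(s, 0.0, dx)
        return w_end + (w_prev - w_end) * s / dx

    def _extrap_w1_out_arrays(self, oldA, oldu, rows, n_nodes, dx):
        """Batched forward-characteristic extrapolation at vessel outlets."""
        iend = n_nodes - 1
        A_e, u_e = oldA[rows, iend], oldu[rows, iend]
        A_p, u_p = oldA[rows, iend - 1], oldu[rows, iend - 1]
        c_e = np.sqrt(self._beta[rows, iend] * np.sqrt(A_e) / (2 * self.rho))
        c_p = np.sqrt(self._beta[rows, iend - 1] * np.sqrt(A_p) / (2 * self.rho))
        w1_e, w1_p = u_e + 4 * c_e, u_p + 4 * c_p
        lam = u_e + c_e
        return self._lin(w1_e, w1_p, lam * self.dt, dx)

    def _extrap_w2_in_arrays(self, oldA, oldu, rows, dx):
        """Batched backward-characteristic extrapolation at vessel inlets."""
        A_e, u_e = oldA[rows, 0], oldu[rows, 0]
        A_p, u_p = oldA[rows, 1], oldu[rows, 1]
        c_e = np.sqrt(self._beta[rows, 0] * np.sqrt(A_e) / (2 * self.rho))
        c_p = np.sqrt(self._beta[rows, 1] * np.sqrt(A_p) / (2 * self.rho))
        w2_e, w2_p = u_e - 4 * c_e, u_p - 4 * c_p
        lam = u_e - c_e  # negative for subsonic flow
        return self._lin(w2_e, w2_p, -lam * self.dt, dx)

    # -- boundary updates --------------------------------------------------------
    def _terminal_update(self, oldA, oldu, oldT) -> None:
        rows, n_nodes = self._term_rows, self._term_n
        if rows.size == 0:
            return
        dx = self._dx[rows]
        w1_new = self._extrap_w1_out_arrays(oldA, oldu, rows, n_nodes, dx)
        for k, tid in enumerate(self.net.terminals):
            i, n = rows[k], n_nodes[k]
            R_R = self.net.terminals[tid]
            w1_0, w2_0 = self._w0[(tid, -1)]
            w2_new = w2_0 - R_R * (w1_new[k] - w1_0)
            A, u = invert_characteristics(w1_new[k], w2_new,
                                          self._beta[i, n - 1], self.rho)
            self._A[i, n - 1], self._u[i, n - 1] = float(A), float(u)
            if u > 0:
                self._T[i, n - 1] = self._lin(
                    oldT[i, n - 1], oldT[i, n - 2], u * self.dt, self._dx[i])
            else:
                tw = np.asarray(self.wall_T(tid), dtype=float)
                self._T[i, n - 1] = float(tw.ravel()[-1])

    def _inlet_update(self, oldA, oldu) -> None:
        vid = self.net.inlet
        i = self._row[vid]
        w1_0, w2_0 = self._w0[(vid, 0)]
        w2_new = float(self._extrap_w2_in_arrays(
            oldA, oldu, np.array([i]), self._dx[[i]])[0])
        if self.lv is not None:
            c0 = math.sqrt(self._beta[i, 0] * math.sqrt(oldA[i, 0])
                           / (2 * self.rho))
            w1_extrap = oldu[i, 0] + 4.0 * c0
            w1_new = inlet_w1(self.lv.p_LV_dyn, self._beta[i, 0],
                              self._A0[i, 0], self.p_ext, self.rho,
                              self.lv.R_AV, w1_0, w2_0, w1_extrap, w2_new)
        elif self.inlet_w1_fn is not None:
            w1_new = self.inlet_w1_fn(self.t + self.dt)
        else:
            w1_new = w1_0
        A, u = invert_characteristics(w1_new, w2_new, self._beta[i, 0],
                                      self.rho)
        self._A[i, 0], self._u[i, 0] = float(A), float(u)
        self._T[i, 0] = self.inlet_temperature

    def _junction_update(self, g: _JunctionGroup, oldA, oldu, oldT) -> None:
        rho, n, k = self.rho, g.n, g.k
        W1p = self._extrap_w1_out_arrays(oldA, oldu, g.ip, g.np_, g.dxp)
        W2d = np.empty((k, n))
        for j in range(n):
            W2d[:, j] = self._extrap_w2_in_arrays(oldA, oldu, g.id_[:, j],
                                                  g.dxd[:, j])
        m = 2 * (n + 1)
        x = np.empty((k, m))
        x[:, 0] = self._A[g.ip, g.np_ - 1]
        x[:, 1] = self._u[g.ip, g.np_ - 1]
        for j in range(n):
            x[:, 2 + 2 * j] = self._A[g.id_[:, j], 0]
            x[:, 3 + 2 * j] = self._u[g.id_[:, j], 0]
        scale = np.maximum(np.abs(W1p), 1.0)

        def residual(x):
            Ap, up = x[:, 0], x[:, 1]
            r = np.empty((k, m))
            sqAp = np.sqrt(Ap)
            cp_ = np.sqrt(g.beta_p * sqAp / (2 * rho))
            r[:, 0] = up + 4 * cp_ - W1p
            q = Ap * up
            pp = g.beta_p * (sqAp - g.sqA0p) / rho + 0.5 * up * up
            for j in range(n):
                Aj, uj = x[:, 2 + 2 * j], x[:, 3 + 2 * j]
                sqAj = np.sqrt(Aj)
                cj = np.sqrt(g.beta_d[:, j] * sqAj / (2 * rho))
                r[:, 1 + j] = uj - 4 * cj - W2d[:, j]
                q = q - Aj * uj
                pj = (g.beta_d[:, j] * (sqAj - g.sqA0d[:, j]) / rho
                      + 0.5 * uj * uj)
                r[:, 1 + n + j] = pp - pj
            r[:, 1 + 2 * n] = q
            return r

        def jacobian(x):
            Ap, up = x[:, 0], x[:, 1]
            J = np.zeros((k, m, m))
            sqAp = np.sqrt(Ap)
            cp_ = np.sqrt(g.beta_p * sqAp / (2 * rho))
            J[:, 0, 0] = cp_ / Ap
            J[:, 0, 1] = 1.0
            dpdA_p = g.beta_p / (2 * sqAp * rho)
            for j in range(n):
                Aj, uj = x[:, 2 + 2 * j], x[:, 3 + 2 * j]
                sqAj = np.sqrt(Aj)
                cj = np.sqrt(g.beta_d[:, j] * sqAj / (2 * rho))
                J[:, 1 + j, 2 + 2 * j] = -cj / Aj
                J[:, 1 + j, 3 + 2 * j] = 1.0
                J[:, 1 + n + j, 0] = dpdA_p
                J[:, 1 + n + j, 1] = up
                J[:, 1 + n + j, 2 + 2 * j] = -g.beta_d[:, j] / (2 * sqAj * rho)
                J[:, 1 + n + j, 3 + 2 * j] = -uj
                J[:, 1 + 2 * n, 2 + 2 * j] = -uj
                J[:, 1 + 2 * n, 3 + 2 * j] = -Aj
            J[:, 1 + 2 * n, 0] = up
            J[:, 1 + 2 * n, 1] = Ap
            return J

        converged = False
        for _ in range(50):
            r = residual(x)
            if float(np.max(np.abs(r) / scale[:, None])) < self.junction_tol:
                converged = True
                break
            try:
                dx_ = np.linalg.solve(jacobian(x), -r[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError as exc:
                raise SolverError("singular junction Newton system") from exc
            # damp steps that would drive any area towards non-positive
            areas = x[:, 0::2]
            dareas = dx_[:, 0::2]
            with np.errstate(divide="ignore", invalid="ignore"):
                lim = np.where(areas + dareas <= 0.1 * areas,
                               -0.9 * areas / dareas, 1.0)
            lam = np.minimum(1.0, np.min(lim, axis=1))
            x += lam[:, None] * dx_
        if not converged:
            raise SolverError(
                f"junction Newton did not converge in 50 iterations "
                f"(parents {g.parents})")

        self._A[g.ip, g.np_ - 1] = x[:, 0]
        self._u[g.ip, g.np_ - 1] = x[:, 1]
        for j in range(n):
            self._A[g.id_[:, j], 0] = x[:, 2 + 2 * j]
            self._u[g.id_[:, j], 0] = x[:, 3 + 2 * j]

        # temperature: flux-weighted upwind transport across the junction
        up = x[:, 1]
        T_par = self._lin(oldT[g.ip, g.np_ - 1], oldT[g.ip, g.np_ - 2],
                          np.maximum(up, 0.0) * self.dt, g.dxp)
        for idx in range(k):
            if up[idx] >= 0:
                self._T[g.ip[idx], g.np_[idx] - 1] = T_par[idx]
                for j in range(n):
                    self._T[g.id_[idx, j], 0] = T_par[idx]
            else:
                qs, Ts = [], []
                for j in range(n):
                    i_d = g.id_[idx, j]
                    u_d = self._u[i_d, 0]
                    Td = self._lin(oldT[i_d, 0], oldT[i_d, 1],
                                   max(-u_d, 0.0) * self.dt, g.dxd[idx, j])
                    self._T[i_d, 0] = Td
                    qs.append(max(-self._A[i_d, 0] * u_d, 0.0))
                    Ts.append(Td)
                qtot = sum(qs)
                self._T[g.ip[idx], g.np_[idx] - 1] = (
                    sum(q * T for q, T in zip(qs, Ts)) / qtot if qtot > 0
                    else oldT[g.ip[idx], g.np_[idx] - 1])

    # -- time stepping -----------------------------------------------------------
    def step(self) -> None:
        oldA = self._A.copy()
        oldu = self._u.copy()
        oldT = self._T.copy()
        self._interior()
        self._inlet_update(oldA, oldu)
        self._terminal_update(oldA, oldu, oldT)
        for g in self._groups:
            self._junction_update(g, oldA, oldu, oldT)
        self.t += self.dt
        self.step_count += 1
        if self.lv is not None:
            i = self._row[self.net.inlet]
            G_AV = float(self._A[i, 0] * self._u[i, 0])
            p_root = units.mmhg(float(pressure_from_area(
                self._A[i, 0], self._A0[i, 0], self._beta[i, 0], self.p_ext)))
            self.lv.step(self.dt, G_AV, p_root)

    def run(self, duration: float, probes: list[Probe] | None = None,
            record_every: int = 1) -> FlowRecord:
        """Advance ``duration`` seconds, recording probe time series."""
        probes = probes or [Probe(self.net.inlet, 0.0)]
        n_steps = int(round(duration / self.dt))
        n_rec = n_steps // record_every + 1
        t_r = np.empty(n_rec)
        shape = (n_rec, len(probes))
        p_r, q_r, u_r, a_r, T_r = (np.empty(shape) for _ in range(5))
        lv_trace = {"V": np.empty(n_rec), "p_LV": np.empty(n_rec),
                    "phase": [None] * n_rec} if self.lv else {}
        pn = [(self._row[pr.vessel], pr.node(self._n[pr.vessel]))
              for pr in probes]

        def record(kk):
            t_r[kk] = self.t
            for j, (i, nn) in enumerate(pn):
                a_r[kk, j] = self._A[i, nn]
                u_r[kk, j] = self._u[i, nn]
                q_r[kk, j] = self._A[i, nn] * self._u[i, nn]
                T_r[kk, j] = self._T[i, nn]
                p_r[kk, j] = units.mmhg(float(pressure_from_area(
                    self._A[i, nn], self._A0[i, nn], self._beta[i, nn],
                    self.p_ext)))
            if self.lv:
                lv_trace["V"][kk] = self.lv.V
                lv_trace["p_LV"][kk] = self.lv.p_LV
                lv_trace["phase"][kk] = self.lv.phase

        record(0)
        k = 1
        for s in range(1, n_steps + 1):
            self.step()
            if s % record_every == 0:
                record(k)
                k += 1
        return FlowRecord(t=t_r[:k], probes=probes, p_mmHg=p_r[:k],
                          Q=q_r[:k], u=u_r[:k], A=a_r[:k], T=T_r[:k],
                          lv={kk: (np.asarray(vv[:k]) if kk != "phase"
                                   else vv[:k])
                              for kk, vv in lv_trace.items()})

    # -- diagnostics ---------------------------------------------------------
    def total_volume(self) -> float:
        """Trapezoidal integral of A over the whole network [cm3]."""
        tot = 0.0
        for f in self.fields.values():
            tot += float(np.trapezoid(f.A, dx=f.dx))
        return tot
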