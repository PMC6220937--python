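"""1D pulse-wave solver: characteristics, propagation, boundaries, junctions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (INVISCID_FLUID, RHO, gaussian_w1, single_vessel_network,
                      uniform_vessel)
from hemotherm.flow1d import (FlowSolver, Probe, SolverError,
                              compute_characteristics, invert_characteristics)
from hemotherm.network import (ArterialNetwork, Junction, beta_from_wave_speed,
                               wave_speed)


class TestCharacteristics:
    @given(A=st.floats(0.05, 10.0), u=st.floats(-100.0, 100.0),
           beta=st.floats(1e4, 1e7))
    @settings(deadline=None, max_examples=100)
    def test_round_trip_and_speed_identity(self, A, u, beta):
        w1, w2 = compute_characteristics(A, u, beta, RHO)
        A2, u2 = invert_characteristics(w1, w2, beta, RHO)
        assert A2 == pytest.approx(A, rel=1e-12)
        assert u2 == pytest.approx(u, rel=1e-9, abs=1e-9)
        assert (w1 - w2) / 8.0 == pytest.approx(
            float(wave_speed(beta, A, RHO)), rel=1e-12)

    def test_rest_state_symmetry(self):
        w1, w2 = compute_characteristics(2.0, 0.0, 3e5, RHO)
        c = float(wave_speed(3e5, 2.0, RHO))
        assert w1 == pytest.approx(4 * c) and w2 == pytest.approx(-4 * c)

    def test_nonphysical_state_rejected(self):
        with pytest.raises(ValueError, match="w1 <= w2"):
            invert_characteristics(-10.0, 10.0, 1e5, RHO)
        with pytest.raises(ValueError):
            compute_characteristics(-1.0, 0.0, 1e5, RHO)


class TestInterior:
    def test_uniform_rest_is_fixed_point(self):
        net = single_vessel_network(n_elements=50)
        s = FlowSolver(net, dt=4e-4, wall_temperature=37.0)
        for _ in range(50):
            s.step()
        f = s.fields["v0"]
        assert np.allclose(f.A, f.A0, rtol=1e-12)
        assert np.allclose(f.u, 0.0, atol=1e-9)
        assert np.allclose(f.T, 37.0, atol=1e-10)

    def test_pulse_travels_at_intrinsic_wave_speed(self):
        net = single_vessel_network()
        s = FlowSolver(net, dt=4.5e-4, inlet_w1_fn=gaussian_w1(),
                       convect_heat=False)
        u1, u2, ts = [], [], []
        for _ in range(900):
            s.step()
            f = s.fields["v0"]
            ts.append(s.t)
            u1.append(f.u[100])
            u2.append(f.u[300])
        ts = np.asarray(ts)
        c_meas = 40.0 / (ts[np.argmax(u2)] - ts[np.argmax(u1)])
        assert c_meas == pytest.approx(400.0, rel=0.02)

    def test_poiseuille_pressure_gradient_balance(self):
        # steady viscous flow: dp/dx = -8 pi mu u / A
        net = single_vessel_network(length=20.0, A0=0.2, c0=300.0,
                                    n_elements=100, mu=0.035)
        w10 = 4 * 300.0
        s = FlowSolver(net, dt=2e-4, convect_heat=False,
                       inlet_w1_fn=lambda t: w10 + 10.0 * min(t / 0.05, 1.0))
        for _ in range(5000):
            s.step()
        f = s.fields["v0"]
        p = f.beta * (np.sqrt(f.A) - np.sqrt(f.A0))
        dpdx = (p[-1] - p[0]) / 20.0
        friction = -8 * math.pi * 0.035 * float(np.mean(f.u)) / float(np.mean(f.A))
        assert dpdx == pytest.approx(friction, rel=0.03)

    def test_second_order_grid_convergence(self):
        # L2 error vs the linear analytic pulse drops ~4x per refinement
        amp, t0, sig, c0 = 0.4, 0.03, 0.008, 400.0
        w10 = 4 * c0

        def err(ne, dt):
            net = single_vessel_network(length=60.0, n_elements=ne)
            net.fluid["alpha"] = 0.0
            s = FlowSolver(net, dt=dt, convect_heat=False,
                           inlet_w1_fn=lambda t: w10 + amp * math.exp(
                               -((t - t0) / sig) ** 2))
            for _ in range(int(round(0.1 / dt))):
                s.step()
            f = s.fields["v0"]
            x = np.linspace(0, 60.0, ne + 1)
            ua = (amp / 2) * np.exp(-((s.t - x / c0 - t0) / sig) ** 2)
            return float(np.sqrt(np.mean((f.u - ua) ** 2)) / (amp / 2))

        e_coarse = err(150, 4e-4)
        e_fine = err(300, 2e-4)
        assert e_coarse / e_fine > 3.0

    def test_cfl_violation_aborts_with_diagnostic(self):
        net = single_vessel_network(n_elements=400)  # dx = 0.2 cm
        s = FlowSolver(net, dt=1e-3)                 # nu = 2
        with pytest.raises(SolverError, match="CFL"):
            s.step()

    def test_volume_bookkeeping_during_transit(self):
        # network volume change equals net boundary influx (conservation)
        net = single_vessel_network(n_elements=200)
        s = FlowSolver(net, dt=4e-4, inlet_w1_fn=gaussian_w1(amp=4.0),
                       convect_heat=False)
        v0 = s.total_volume()
        influx = 0.0
        for _ in range(500):
            q_in0 = s.fields["v0"].A[0] * s.fields["v0"].u[0]
            q_out0 = s.fields["v0"].A[-1] * s.fields["v0"].u[-1]
            s.step()
            q_in1 = s.fields["v0"].A[0] * s.fields["v0"].u[0]
            q_out1 = s.fields["v0"].A[-1] * s.fields["v0"].u[-1]
            influx += 0.5 * ((q_in0 + q_in1) - (q_out0 + q_out1)) * s.dt
        dv = s.total_volume() - v0
        assert dv == pytest.approx(influx, abs=2e-3 * max(abs(dv), 1.0))


class TestTerminals:
    def make_solver(self, R_R, **kw):
        net = single_vessel_network(R_R=R_R)
        return FlowSolver(net, dt=4.5e-4, inlet_w1_fn=gaussian_w1(),
                          convect_heat=False, **kw)

    def test_nonreflective_outlet_keeps_w2_frozen(self):
        s = self.make_solver(0.0)
        c0 = 400.0
        for _ in range(1200):
            s.step()
            f = s.fields["v0"]
            w2_end = f.u[-1] - 4 * float(wave_speed(f.beta[-1], f.A[-1], RHO))
            assert w2_end == pytest.approx(-4 * c0, abs=1e-6)

    def test_total_reflection_amplitude(self):
        s = self.make_solver(1.0)
        inc, refl = [], []
        for _ in range(1400):
            s.step()
            f = s.fields["v0"]
            c = np.sqrt(f.beta * np.sqrt(f.A) / (2 * RHO))
            inc.append(float((f.u + 4 * c)[200]) - 1600.0)
            refl.append(float((f.u - 4 * c)[200]) + 1600.0)
        ratio = -min(refl) / max(inc)
        assert ratio == pytest.approx(1.0, abs=0.03)

    def test_partial_reflection_coefficient(self):
        R = 0.6
        s = self.make_solver(R)
        inc, refl = [], []
        for _ in range(1400):
            s.step()
            f = s.fields["v0"]
            c = np.sqrt(f.beta * np.sqrt(f.A) / (2 * RHO))
            inc.append(float((f.u + 4 * c)[200]) - 1600.0)
            refl.append(float((f.u - 4 * c)[200]) + 1600.0)
        assert -min(refl) / max(inc) == pytest.approx(R, rel=0.05)

    def test_outflow_temperature_extrapolated_else_tissue(self):
        s = self.make_solver(0.0, wall_temperature=35.0)
        s.fields["v0"].T[:] = 38.0
        for _ in range(200):
            s.step()
        f = s.fields["v0"]
        if f.u[-1] > 0:
            assert f.T[-1] > 36.0  # advected from the warm interior


class TestJunctions:
    def test_pass_through_degenerate_junction(self):
        # identical parent/daughter: a pulse crosses without reflection
        vp = uniform_vessel("p", length=40.0, n_elements=200)
        vd = uniform_vessel("d", length=40.0, n_elements=200)
        net = ArterialNetwork(vessels={"p": vp, "d": vd},
                              junctions=[Junction("p", ["d"])],
                              inlet="p", terminals={"d": 0.0},
                              fluid=dict(INVISCID_FLUID))
        s = FlowSolver(net, dt=4.5e-4, inlet_w1_fn=gaussian_w1(),
                       convect_heat=False)
        refl = []
        trans = []
        for _ in range(1200):
            s.step()
            fp, fd = s.fields["p"], s.fields["d"]
            cp = np.sqrt(fp.beta * np.sqrt(fp.A) / (2 * RHO))
            refl.append(float((fp.u - 4 * cp)[100]) + 1600.0)
            trans.append(float(fd.u[100]))
        assert max(abs(min(refl)), abs(max(refl))) < 0.02  # ~1% of du=1 cm/s
        assert max(trans) == pytest.approx(1.0, rel=0.02)

    def test_symmetric_bifurcation_conserves_mass(self):
        vp = uniform_vessel("p", length=40.0, n_elements=200)
        vd1 = uniform_vessel("d1", length=40.0, A0=0.6, c0=450.0,
                             n_elements=200)
        vd2 = uniform_vessel("d2", length=40.0, A0=0.6, c0=450.0,
                             n_elements=200)
        net = ArterialNetwork(vessels={"p": vp, "d1": vd1, "d2": vd2},
                              junctions=[Junction("p", ["d1", "d2"])],
                              inlet="p", terminals={"d1": 0.0, "d2": 0.0},
                              fluid=dict(INVISCID_FLUID))
        s = FlowSolver(net, dt=3e-4, inlet_w1_fn=gaussian_w1(),
                       convect_heat=False)
        worst_mass, worst_split = 0.0, 0.0
        for _ in range(1000):
            s.step()
            fp, f1, f2 = s.fields["p"], s.fields["d1"], s.fields["d2"]
            q_in = fp.A[-1] * fp.u[-1]
            q1, q2 = f1.A[0] * f1.u[0], f2.A[0] * f2.u[0]
            worst_mass = max(worst_mass, abs(q_in - q1 - q2))
            worst_split = max(worst_split, abs(q1 - q2))
        assert worst_mass < 1e-8
        assert worst_split < 1e-10

    def test_area_mismatch_matches_transmission_line_theory(self):
        A0p, cp = 1.0, 400.0
        A0d, cd = 0.5, 500.0
        vp = uniform_vessel("p", length=80.0, A0=A0p, c0=cp, n_elements=400)
        vd = uniform_vessel("d", length=100.0, A0=A0d, c0=cd, n_elements=400)
        net = ArterialNetwork(vessels={"p": vp, "d": vd},
                              junctions=[Junction("p", ["d"])],
                              inlet="p", terminals={"d": 0.0},
                              fluid=dict(INVISCID_FLUID))
        s = FlowSolver(net, dt=4.5e-4, inlet_w1_fn=gaussian_w1(t0=0.06),
                       convect_heat=False)
        hist = []
        for _ in range(1400):
            s.step()
            fp, fd = s.fields["p"], s.fields["d"]
            cpv = np.sqrt(fp.beta * np.sqrt(fp.A) / (2 * RHO))
            pp = fp.beta * (np.sqrt(fp.A) - np.sqrt(fp.A0))
            pd = fd.beta * (np.sqrt(fd.A) - np.sqrt(fd.A0))
            hist.append((s.t, float(pp[200]),
                         float((fp.u - 4 * cpv)[200]) + 4 * cp,
                         float(pd[200])))
        hist = np.array(hist)
        Yp, Yd = A0p / (RHO * cp), A0d / (RHO * cd)
        R_lin = (Yp - Yd) / (Yp + Yd)
        T_lin = 2 * Yp / (Yp + Yd)
        p_inc = hist[:, 1].max()
        p_refl_sig = -RHO * cp * hist[:, 2] / 2
        mask = hist[:, 0] > 0.06 + 70.0 / cp
        p_refl = p_refl_sig[mask][np.argmax(np.abs(p_refl_sig[mask]))]
        p_trans = hist[:, 3].max()
        assert p_refl / p_inc == pytest.approx(R_lin, rel=0.05)
        assert p_trans / p_inc == pytest.approx(T_lin, rel=0.05)


class TestMeanPressureVsReflection:
    def test_mean_inlet_pressure_monotone_in_R_R(self):
        means = []
        for R in (0.0, 0.4, 0.8):
            net = single_vessel_network(R_R=R, length=30.0, n_elements=150,
                                        A0=0.5, c0=350.0, mu=0.035)
            w10 = 4 * 350.0
            s = FlowSolver(net, dt=3e-4, convect_heat=False,
                           inlet_w1_fn=lambda t: w10 + 20.0 * min(t / 0.05, 1.0))
            for _ in range(3000):
                s.step()
            f = s.fields["v0"]
            p = f.beta * (np.sqrt(f.A) - np.sqrt(f.A0))
            means.append(float(p[0]))
        assert means[0] < means[1] < means[2]
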