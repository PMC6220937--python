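"""Layered-cylinder bioheat model: geometry, conduction, indicators, coupling."""

import math

import numpy as np
import pytest

from hemotherm import _tables as tbl
from hemotherm.ageing import tissue_scalings
from hemotherm.network import generate_synthetic_network
from hemotherm.thermal import (BodyModel, Cylinder, Environment, TissueLayer,
                               build_body, couple_arteries)


@pytest.fixture(scope="module")
def body30():
    return build_body(30)


@pytest.fixture(scope="module")
def body80():
    return build_body(80)


class TestGeometry:
    def test_reference_arm_matches_table(self, body30):
        arm = body30.by_name["arm_L"]
        assert arm.length == 29.6
        outer = [lay.r_out for lay in arm.layers]
        assert outer == pytest.approx([1.5, 3.4, 4.0, 4.2])

    def test_fourteen_cylinders(self, body30):
        assert len(body30.cylinders) == 14
        singles = {"head", "neck", "thorax", "abdomen"}
        assert singles <= set(body30.by_name)
        for seg in ("shoulder", "arm", "forearm", "thigh", "leg"):
            assert f"{seg}_L" in body30.by_name
            assert f"{seg}_R" in body30.by_name

    def test_global_skin_area_closed_form(self, body30):
        # independent hand sum over the geometry table (with multiplicities)
        expect = 0.0
        for seg, geom in tbl.BODY_GEOMETRY.items():
            r_ext = geom["layers"][-1][1]
            expect += (tbl.SEGMENT_MULT[seg]
                       * 2 * math.pi * r_ext * geom["length"])
        assert body30.A_sk_glob == pytest.approx(expect, rel=1e-10)

    def test_aged_muscle_thickness_scaled(self, body80):
        # thickness relative to the 30-year table row follows the fit ratio
        arm = body80.by_name["arm_L"]
        mus = next(l for l in arm.layers if l.tissue == "muscle")
        s80, s30 = tissue_scalings(80), tissue_scalings(30)
        assert mus.r_out - mus.r_in == pytest.approx(
            1.9 * s80.muscle_limb / s30.muscle_limb, rel=1e-10)

    def test_aged_fat_and_skin_thinner_bone_fixed(self, body30, body80):
        a30, a80 = body30.by_name["arm_L"], body80.by_name["arm_L"]
        th = {c: {l.tissue: l.r_out - l.r_in for l in cyl.layers}
              for c, cyl in (("y", a30), ("o", a80))}
        assert th["o"]["fat"] < th["y"]["fat"]
        assert th["o"]["skin"] < th["y"]["skin"]
        assert th["o"]["muscle"] < th["y"]["muscle"]
        assert th["o"]["bone"] == th["y"]["bone"]

    def test_nonpositive_layer_after_scaling_rejected(self):
        with pytest.raises(ValueError):
            TissueLayer(tissue="fat", r_in=2.0, r_out=2.0, k=0.0016,
                        rho=0.85, c=2.3, qv0=0.0, phi=0.0)

    def test_basal_production_matches_rmr_minus_respiration(self, body30):
        # normalisation target: RMR(30) in W, minus the lung respiration sink
        from hemotherm.ageing import resting_metabolic_rate
        rmr_w = resting_metabolic_rate(30) * 69.78
        assert body30.basal_production() == pytest.approx(0.91 * rmr_w,
                                                          rel=1e-6)


class TestConduction:
    def test_uniform_insulated_no_sources_is_steady(self):
        lay = TissueLayer(tissue="muscle", r_in=0.0, r_out=3.0, k=0.0042,
                          rho=1.0, c=4.0, qv0=0.0, phi=0.0)
        cyl = Cylinder("rod", "arm", [lay], length=10.0)
        cyl.T[:] = 36.5
        for _ in range(10):
            cyl.step(dt=5.0, T_pool=36.5, env=None, outer_mode="insulated")
        assert np.allclose(cyl.T, 36.5, atol=1e-12)

    def test_steady_annulus_matches_log_profile(self):
        lay = TissueLayer(tissue="muscle", r_in=2.0, r_out=5.0, k=0.0042,
                          rho=1.085, c=3.77, qv0=0.0, phi=0.0)
        cyl = Cylinder("ann", "arm", [lay], length=10.0, dr_target=0.05,
                       inner_radius=2.0)
        cyl.T[:] = 30.0
        for _ in range(5):
            cyl.step(dt=1e10, T_pool=30.0, env=None, outer_mode="dirichlet",
                     outer_value=20.0, inner_mode="dirichlet",
                     inner_value=40.0)
        analytic = 40.0 + (20.0 - 40.0) * np.log(cyl.r / 2.0) / math.log(2.5)
        assert np.max(np.abs(cyl.T - analytic)) / 20.0 < 0.005

    def test_uniform_source_insulated_heats_exactly(self):
        lay = TissueLayer(tissue="muscle", r_in=0.0, r_out=3.0, k=0.0042,
                          rho=1.0, c=4.0, qv0=0.01, phi=0.0)
        cyl = Cylinder("rod", "arm", [lay], length=10.0)
        cyl.T[:] = 37.0
        cyl.step(dt=2.0, T_pool=37.0, env=None, outer_mode="insulated")
        assert np.allclose(cyl.T, 37.0 + 2.0 * 0.01 / 4.0, atol=1e-10)

    def test_skin_flux_sign_and_magnitude(self):
        # Newton cooling against a hot environment drives heat inward
        lay = TissueLayer(tissue="skin", r_in=0.0, r_out=4.2, k=0.0047,
                          rho=1.085, c=3.68, qv0=0.0, phi=0.0)
        cyl = Cylinder("arm", "arm", [lay], length=29.6)
        cyl.T[:] = 35.0
        env = Environment(T_air=40.0, RH=40.0, h_con=5e-4, h_rad=0.0)
        E0 = float(np.sum(cyl.heat_capacity() * cyl.T))
        cyl.step(dt=1.0, T_pool=35.0, env=env)
        E1 = float(np.sum(cyl.heat_capacity() * cyl.T))
        assert E1 > E0  # inward flux
        # magnitude: h*A*(T_air - T_surface), hand evaluation
        flux = env.h_con * cyl.A_ext * (40.0 - cyl.T_surface)
        assert E1 - E0 == pytest.approx(flux * 1.0, rel=1e-6)

    def test_hand_flux_value_on_arm(self):
        # h_con = 0.0005 W/(cm2 degC), dT = 5 degC over the arm lateral area
        A_ext = 2 * math.pi * 4.2 * 29.6
        assert 5e-4 * A_ext * 5.0 == pytest.approx(1.953, abs=0.01)


class TestIndicatorsAndEnergy:
    def test_uniform_field_indicators(self, body30):
        body30.set_uniform_temperature(37.0)
        assert body30.thermal_indicators() == pytest.approx((37.0, 37.0))

    def test_skin_shift_moves_only_skin_indicator(self, body30):
        body30.set_uniform_temperature(37.0)
        for c in body30.cylinders:
            c.T_surface += 1.0
        T_cr, T_sk = body30.thermal_indicators()
        assert T_sk == pytest.approx(38.0)
        assert T_cr == pytest.approx(37.0)
        body30.set_uniform_temperature(37.0)

    def test_skin_area_weights_rederived(self, body30):
        # weighting must equal 2*pi*r_ext*l of each cylinder
        for c in body30.cylinders:
            assert c.A_ext == pytest.approx(
                2 * math.pi * c.faces[-1] * c.length, rel=1e-12)

    def test_global_energy_balance_per_step(self):
        body = build_body(30, environment=Environment(T_air=40.0, RH=42.0))
        body.set_uniform_temperature(37.0)
        dt = 1.0
        T_pool = body.blood_pool_temperature()
        E0 = body.total_energy()
        body.step(dt)
        E1 = body.total_energy()
        # backward-Euler bookkeeping with the pre-step pool temperature
        rhs = 0.0
        env = body.environment
        for c in body.cylinders:
            rhs += float(np.sum((c.qv0 + c.q_extra + c.q_shiv + c.q_vessel)
                                * c.V))
            w = body.rho_bl * body.cp_bl * c.effective_phi() * c.V
            rhs += float(np.sum(w * (T_pool - c.T)))
            h_area = env.h_tot * c.A_ext
            G_env = 1.0 / (1.0 / c.G_surf + 1.0 / h_area)
            rhs += G_env * (env.T_eff - c.T[-1])
        assert E1 - E0 == pytest.approx(rhs * dt, rel=1e-9)

    def test_respiration_sink_lowers_steady_core(self):
        def steady_T_cr(frac):
            body = build_body(30, environment=Environment(T_air=30.0),
                              respiration_fraction=frac)
            body.set_uniform_temperature(37.0)
            for _ in range(60):
                body.step(200.0)
            return body.thermal_indicators()[0]

        assert steady_T_cr(0.15) < steady_T_cr(0.05)

    def test_thermoneutral_steady_core_in_band(self):
        # basal sources, 30 degC air: the passive body settles near 36-38
        body = build_body(30, environment=Environment(T_air=30.0))
        body.set_uniform_temperature(37.0)
        for _ in range(80):
            body.step(200.0)
        T_cr, T_sk = body.thermal_indicators()
        assert 35.0 < T_cr < 38.5
        assert T_sk < T_cr


class TestArteryCoupling:
    def test_mapping_validation(self, body30, synthetic_net):
        with pytest.raises(ValueError, match="missing cylinder"):
            couple_arteries(synthetic_net, body30,
                            {"v0": {"cylinder": "tail", "class": "core"}})
        with pytest.raises(ValueError, match="unknown thermal class"):
            couple_arteries(synthetic_net, body30,
                            {"v0": {"cylinder": "thorax", "class": "bogus"}})
        with pytest.raises(ValueError, match="unknown vessel"):
            couple_arteries(synthetic_net, body30,
                            {"zz": {"cylinder": "thorax", "class": "core"}})

    def test_modes_resolve_cells(self, body30, synthetic_net):
        table = couple_arteries(synthetic_net, body30, {
            "v0": {"cylinder": "thorax", "class": "core"},
            "v1": {"cylinder": "abdomen", "class": "central"},
            "v2": {"cylinder": "arm_L", "class": "transversal"},
        })
        by_vessel = {t.vessel: t for t in table}
        assert by_vessel["v1"].cell_index == 0
        arm = body30.by_name["arm_L"]
        assert arm.tissue[by_vessel["v2"].cell_index] == "muscle"
        assert by_vessel["v0"].mode == "core"
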