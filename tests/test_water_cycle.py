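from types import SimpleNamespace

import numpy as np
import pytest

import sithv2 as s
from sithv2 import constraints as cs
from sithv2 import water_cycle as wc


def make_forcing_day(**kw):
    base = dict(ta=15.0, pa=100.0, precip=0.0, swd=15.0, swd_direct=10.0,
                lwd=28.0, tskin=288.15, albedo_black=0.18, albedo_white=0.23,
                emissivity=0.97, lai=2.0, vod=0.5)
    base.update(kw)
    return SimpleNamespace(**base)


@pytest.fixture(scope="module")
def params():
    return s.make_site_params("loam", "grassland").with_traits(t_opt=18.0, vod_max=0.8)


class TestInterception:
    def test_dry_day(self):
        assert wc.interception(0.0, 2.0, 3.0) == (0.0, 0.0, 0.0)

    def test_no_canopy(self):
        e_i, tf, f_wet = wc.interception(10.0, 0.0, 3.0)
        assert e_i == 0.0 and tf == 10.0 and f_wet == 0.0

    def test_energy_limited(self):
        e_i, tf, _ = wc.interception(10.0, 2.0, 3.0, chi=0.7)
        assert e_i == pytest.approx(3.0)  # min(0.7*20, 3)
        assert tf == pytest.approx(7.0)

    def test_supply_limited_throughfall_never_negative(self):
        # chi * P * LAI > P for dense canopy: interception capped at the rain
        e_i, tf, _ = wc.interception(1.0, 5.0, 10.0, chi=0.7)
        assert e_i <= 1.0
        assert tf >= 0.0


class TestActualFluxes:
    def test_full_stress_shuts_soil_and_plant_paths(self):
        stresses = cs.StressSet(0.0, 0.0, (0.0, 0.0, 0.0), 0.0, 0.0)
        e_s, t_r, *_ = wc.actual_fluxes(1.0, 5.0, stresses, (1, 1, 1), (0, 0, 0))
        assert e_s == 0.0 and t_r == 0.0

    def test_unconstrained_limit(self):
        stresses = cs.StressSet(0.0, 1.0, (1.0, 1.0, 1.0), 1.0, 1.0)
        e_s, t_r, *_ = wc.actual_fluxes(0.5, 2.0, stresses, (1, 1, 1), (0, 0, 0))
        assert e_s == 2.0 and t_r == pytest.approx(3.0)

    def test_saturated_share_bypasses_moisture_stress(self):
        # direct substitution: 1*1 + 0.5*1 + 0*1 + 0.5 = 2.0
        stresses = cs.StressSet(0.0, 1.0, (1.0, 0.5, 0.0), 1.0, 1.0)
        _, t_r, t_uns, t_sat = wc.actual_fluxes(
            0.0, 0.0, stresses, (1.0, 1.0, 1.0), (0.0, 0.0, 0.5))
        assert t_r == pytest.approx(2.0)
        assert sum(t_sat) == pytest.approx(0.5)


class TestSoilWaterUpdate:
    def test_identity_step(self, params):
        theta = (0.2, 0.2, 0.2)
        out, runoff, recharge, e_s, t_uns = wc.soil_water_update(
            theta, 0.0, 0.0, (0.0, 0.0, 0.0), params)
        assert out == pytest.approx(theta)
        assert runoff == 0.0 and recharge == 0.0

    def test_saturation_excess_runoff(self, params):
        theta = (params.soil.theta_s, 0.2, 0.2)
        _, runoff, *_ = wc.soil_water_update(theta, 500.0, 0.0, (0, 0, 0), params)
        assert runoff > 0.0

    def test_no_drainage_at_field_capacity(self, params):
        fc = params.soil.theta_fc
        out, runoff, recharge, *_ = wc.soil_water_update(
            (fc, fc, fc), 0.0, 0.0, (0, 0, 0), params)
        assert out == pytest.approx((fc, fc, fc))
        assert recharge == 0.0

    def test_drainage_capped_by_conductivity(self, params):
        ts = params.soil.theta_s
        _, _, recharge, *_ = wc.soil_water_update((ts, ts, ts), 0.0, 0.0,
                                                  (0, 0, 0), params)
        assert recharge <= params.soil.k_sat + 1e-12

    def test_extraction_clipped_to_available_water(self, params):
        theta = (0.02, 0.02, 0.02)
        out, _, _, e_s, t_uns = wc.soil_water_update(
            theta, 0.0, 50.0, (50.0, 50.0, 50.0), params)
        assert e_s < 50.0
        assert all(t < 50.0 for t in t_uns)
        assert all(t >= 0.0 for t in out)


class TestGroundwater:
    def test_zero_net_flux(self):
        assert wc.update_groundwater(100.0, 2.0, 2.0) == 100.0

    def test_recharge_raises_table(self):
        assert wc.update_groundwater(100.0, 5.0, 0.0, 0.05) == pytest.approx(90.0)

    def test_extraction_deepens_table(self):
        assert wc.update_groundwater(100.0, 0.0, 5.0, 0.05) == pytest.approx(110.0)

    def test_invalid_specific_yield(self):
        with pytest.raises(ValueError):
            wc.update_groundwater(100.0, 1.0, 0.0, specific_yield=0.0)


class TestStep:
    def test_conservation_on_random_days(self, params):
        rng = np.random.default_rng(42)
        state = wc.ModelState((0.25, 0.25, 0.25), 200.0)
        for _ in range(500):
            f = make_forcing_day(
                ta=rng.uniform(-5, 30), precip=rng.exponential(3.0),
                swd=rng.uniform(2, 25), lai=rng.uniform(0, 5),
                vod=rng.uniform(0, 0.8))
            f.swd_direct = 0.6 * f.swd
            f.tskin = f.ta + 273.15
            state, fx = wc.step(state, f, params)
            assert abs(fx.balance_residual) <= wc.BALANCE_TOL
            assert fx.et == fx.e_i + fx.e_s + fx.t_r

    def test_all_components_non_negative_and_below_potential(self, params):
        state = wc.ModelState((0.3, 0.3, 0.3), 150.0)
        f = make_forcing_day(precip=5.0)
        _, fx = wc.step(state, f, params)
        for v in (fx.et, fx.e_i, fx.e_s, fx.t_r, fx.runoff, fx.recharge):
            assert v >= 0.0
        assert fx.et <= fx.e_i + fx.e_ps + fx.t_p + 1e-12

    def test_wetter_surface_never_evaporates_less(self, params):
        f = make_forcing_day()
        _, dry = wc.step(wc.ModelState((0.15, 0.25, 0.25), 500.0), f, params)
        _, wet = wc.step(wc.ModelState((0.25, 0.25, 0.25), 500.0), f, params)
        assert wet.e_s >= dry.e_s

    def test_flux_continuity_across_layer_boundary(self, params):
        f = make_forcing_day()
        z2 = params.layer_bottoms[1]
        outs = []
        for z in (z2 - 1e-7, z2, z2 + 1e-7):
            _, fx = wc.step(wc.ModelState((0.25, 0.25, 0.25), z), f, params)
            outs.append(fx.et)
        assert abs(outs[0] - outs[1]) < 1e-9
        assert abs(outs[2] - outs[1]) < 1e-9

    def test_step_equals_hand_composition(self, params):
        """The orchestrated step must equal sequentially composed operations."""
        from sithv2 import pet as pt
        from sithv2 import radiation as rad
        from sithv2 import root_zone as rz

        f = make_forcing_day(precip=4.0)
        state = wc.ModelState((0.22, 0.26, 0.3), 120.0)
        _, fx = wc.step(state, f, params)

        budget = rad.radiation_budget(f.swd, f.swd_direct, f.lwd, f.tskin,
                                      f.emissivity, f.albedo_black,
                                      f.albedo_white, f.lai, params.k_rn)
        delta, lam = pt.svp_slope(f.ta), pt.latent_heat(f.ta)
        e_ps = pt.potential_soil_evaporation(budget.rns, 0.0, delta,
                                             params.gamma, lam, params.alpha)
        e_pc, _ = pt.potential_canopy_and_transpiration(budget.rnc, 0.0, delta,
                                                        params.gamma, lam,
                                                        params.alpha)
        e_i = min(params.chi * f.precip * f.lai, e_pc, f.precip)
        assert fx.e_ps == pytest.approx(e_ps, rel=1e-12)
        assert fx.e_pc == pytest.approx(e_pc, rel=1e-12)
        assert fx.e_i == pytest.approx(e_i, rel=1e-12)
        t_p = (1.0 - fx.f_wet) * e_pc
        assert fx.t_p == pytest.approx(t_p, rel=1e-12)
        # layer allocation reproduced independently
        bounds = (0.0, *params.layer_bottoms)
        theta_bar = tuple(rz.layer_mean_wetness(state.theta[i],
                                                params.soil.theta_s, state.z_gw,
                                                bounds[i], bounds[i + 1])
                          for i in range(3))
        t_p_i = rz.allocate_transpiration(t_p, params.root_r, theta_bar,
                                          params.soil.theta_s, params.soil.b)
        assert sum(t_p_i) == pytest.approx(t_p, abs=1e-12)

    def test_dry_down_reaches_wilting_and_shuts_soil_evaporation(self, params):
        state = wc.ModelState((params.soil.theta_s,) * 3, 3000.0)
        f = make_forcing_day(precip=0.0, swd=20.0, lai=1.0, vod=0.8)
        for _ in range(1000):
            state, fx = wc.step(state, f, params)
        assert state.theta[0] <= params.soil.theta_wp + 1e-9
        assert fx.e_s <= 1e-9

    def test_missing_traits_rejected(self):
        p = s.make_site_params("loam", "grassland")
        with pytest.raises(ValueError):
            wc.step(wc.ModelState((0.2, 0.2, 0.2), 100.0), make_forcing_day(), p)
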