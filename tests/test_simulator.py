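import numpy as np
import pandas as pd
import pytest

import sithv2 as s
from sithv2 import simulator as sim
from sithv2.water_cycle import ModelState, step


class TestSpinUp:
    def test_zero_cycles_returns_initial_state(self, temperate_forcing, loam_grass):
        state0 = sim.initial_state(loam_grass)
        res = sim.spin_up(temperate_forcing.iloc[:365], loam_grass, 0, state0)
        assert res.state == state0

    def test_year_over_year_change_shrinks(self, temperate_forcing, loam_grass):
        res = sim.spin_up(temperate_forcing.iloc[:365], loam_grass, 20)
        assert res.year_deltas[-1] < 1e-4
        # non-increasing envelope over the last cycles
        tail = res.year_deltas[-10:]
        assert max(tail) <= max(res.year_deltas[:10]) + 1e-12

    def test_distinct_initial_states_converge(self, temperate_forcing, loam_grass):
        soil = loam_grass.soil
        a = sim.spin_up(temperate_forcing.iloc[:365], loam_grass, 30,
                        ModelState((soil.theta_wp,) * 3, 3000.0)).state
        b = sim.spin_up(temperate_forcing.iloc[:365], loam_grass, 30,
                        ModelState((soil.theta_s,) * 3, 10.0)).state
        assert max(abs(x - y) for x, y in zip(a.theta, b.theta)) < 1e-3

    def test_partial_year_rejected(self, temperate_forcing, loam_grass):
        with pytest.raises(ValueError):
            sim.spin_up(temperate_forcing.iloc[:100], loam_grass, 1)


class TestRunPoint:
    def test_one_day_run_equals_single_step(self, temperate_forcing, loam_grass,
                                            equilibrated):
        day = temperate_forcing.iloc[:1]
        fluxes, states = sim.run_point(day, loam_grass, equilibrated)
        state1, fx = step(equilibrated, next(day.itertuples()), loam_grass)
        assert fluxes["et"].iloc[0] == fx.et
        assert tuple(states.iloc[0][["sm1", "sm2", "sm3"]]) == state1.theta

    def test_checkpoint_resume_reproduces_unsplit_run(self, temperate_forcing,
                                                      loam_grass, equilibrated):
        full, full_states = sim.run_point(temperate_forcing, loam_grass, equilibrated)
        k = 300
        head, head_states = sim.run_point(temperate_forcing.iloc[:k], loam_grass,
                                          equilibrated)
        mid = ModelState(tuple(head_states.iloc[-1][["sm1", "sm2", "sm3"]]),
                         head_states.iloc[-1]["z_gw"])
        tail, _ = sim.run_point(temperate_forcing.iloc[k:], loam_grass, mid)
        rejoined = pd.concat([head, tail])
        pd.testing.assert_frame_equal(rejoined, full)

    def test_cumulative_residual_stays_tiny(self, temperate_forcing, loam_grass,
                                            equilibrated):
        fluxes, _ = sim.run_point(temperate_forcing, loam_grass, equilibrated)
        assert fluxes["balance_residual"].abs().sum() < 1e-2

    def test_gap_in_dates_rejected(self, temperate_forcing, loam_grass, equilibrated):
        gappy = temperate_forcing.drop(index=5)
        with pytest.raises(ValueError):
            sim.run_point(gappy, loam_grass, equilibrated)


class TestRunGrid:
    @pytest.fixture(scope="class")
    def small_cube(self):
        return s.generate_grid_fixture([["temperate", "arid"],
                                        ["humid_tropical", "temperate"]], 1, seed=6)

    def test_single_cell_grid_reduces_to_run_point(self):
        cube = s.generate_grid_fixture([["temperate"]], 1, seed=8)
        params = s.make_site_params("loam", "grassland")
        cfg = sim.RunConfig(spin_up_years=3)
        grid = sim.run_grid(cube, params, cfg)

        fields = ["ta", "pa", "precip", "swd", "swd_direct", "lwd", "tskin",
                  "albedo_black", "albedo_white", "emissivity", "lai", "vod"]
        df = pd.DataFrame({f: cube[f][:, 0, 0].to_numpy() for f in fields})
        for c in ("year", "month", "doy"):
            df[c] = cube[c].to_numpy()
        p = sim.derive_traits(df, params)
        state = sim.spin_up(df.iloc[:365], p, 3).state
        fluxes, _ = sim.run_point(df, p, state)
        np.testing.assert_array_equal(grid["ET"][:, 0, 0], fluxes["et"])

    def test_serial_and_parallel_runs_bit_identical(self, small_cube):
        params = s.make_site_params("loam", "grassland")
        serial = sim.run_grid(small_cube, params, sim.RunConfig(spin_up_years=2, n_jobs=1))
        parallel = sim.run_grid(small_cube, params, sim.RunConfig(spin_up_years=2, n_jobs=2))
        assert serial.equals(parallel)

    def test_missing_params_masks_cell(self, small_cube):
        params = s.make_site_params("loam", "grassland")
        pgrid = {(iy, ix): params for iy in range(2) for ix in range(2)}
        del pgrid[(1, 1)]
        with pytest.warns(UserWarning, match="masked"):
            out = sim.run_grid(small_cube, pgrid, sim.RunConfig(spin_up_years=1))
        assert np.isnan(out["ET"][:, 1, 1]).all()
        assert np.isfinite(out["ET"][:, 0, 0]).all()


class TestAggregate:
    @pytest.fixture()
    def daily(self):
        f = s.generate_forcing(s.REGIMES["temperate"], 2, seed=1)
        return pd.DataFrame({"year": f["year"], "month": f["month"],
                             "doy": f["doy"], "flux": 1.0, "state": 0.3})

    def test_constant_flux_sums_to_period_length(self, daily):
        monthly = sim.aggregate(daily[["year", "month", "doy", "flux"]],
                                "monthly", "flux")
        jan = monthly[(monthly["year"] == 1) & (monthly["month"] == 1)]
        assert jan["flux"].iloc[0] == pytest.approx(31.0)

    def test_constant_state_averages_unchanged(self, daily):
        annual = sim.aggregate(daily[["year", "doy", "state"]], "annual", "state")
        np.testing.assert_allclose(annual["state"], 0.3)

    def test_monthly_totals_resum_to_annual(self, daily):
        monthly = sim.aggregate(daily[["year", "month", "doy", "flux"]],
                                "monthly", "flux")
        annual = sim.aggregate(daily[["year", "doy", "flux"]], "annual", "flux")
        resummed = monthly.groupby("year")["flux"].sum().reset_index()
        pd.testing.assert_frame_equal(resummed, annual, check_dtype=False)

    def test_partial_trailing_period_dropped_with_warning(self, daily):
        clipped = daily.iloc[:-10]
        with pytest.warns(UserWarning, match="incomplete"):
            annual = sim.aggregate(clipped[["year", "doy", "flux"]], "annual", "flux")
        assert set(annual["year"]) == {1}


def test_state_round_trip(tmp_path):
    st0 = ModelState((0.21, 0.22, 0.23), 145.5)
    p = tmp_path / "state.json"
    sim.save_state(st0, p)
    assert sim.load_state(p) == st0
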