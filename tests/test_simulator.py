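import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greenfeedback.simulator import (
    LATENT_HEAT_VAPORIZATION,
    SECONDS_PER_MONTH,
    SimParams,
    aerodynamic_resistance_from_lai,
    air_emissivity,
    albedo_from_lai,
    evaporative_fraction,
    simulate_run,
    solve_surface_temperature,
    step_soil_moisture,
)

P = SimParams()


class TestAlbedo:
    def test_bare_ground_and_snow(self):
        assert albedo_from_lai(0.0, False, P) == pytest.approx(P.alpha_ground)
        assert albedo_from_lai(0.0, True, P) == pytest.approx(P.alpha_snow)

    def test_dense_canopy_limit(self):
        assert albedo_from_lai(100.0, True, P) == pytest.approx(P.alpha_canopy)

    def test_hand_value_snow_lai2(self):
        p = SimParams(k_ext=0.5, alpha_canopy=0.15, alpha_snow=0.70)
        expect = 0.15 + 0.55 * np.exp(-1.0)
        assert albedo_from_lai(2.0, True, p) == pytest.approx(expect, rel=1e-12)

    @given(st.floats(0, 10), st.floats(0.01, 5))
    @settings(max_examples=30, deadline=None)
    def test_monotone_decreasing(self, lai, dlai):
        assert albedo_from_lai(lai + dlai, False, P) < albedo_from_lai(lai, False, P)


class TestAerodynamicResistance:
    def test_bare_value_and_hand_case(self):
        assert aerodynamic_resistance_from_lai(0.0, P) == pytest.approx(P.r_a0)
        p = SimParams(r_a0=100.0, c_ra=0.25)
        assert aerodynamic_resistance_from_lai(4.0, p) == pytest.approx(50.0)

    def test_monotone_positive(self):
        sweep = aerodynamic_resistance_from_lai(np.linspace(0, 10, 50), P)
        assert (np.diff(sweep) < 0).all() and (sweep > 0).all()


class TestEvaporativeFraction:
    def test_empty_bucket_no_evaporation(self):
        beta, _ = evaporative_fraction(3.0, 0.0, 290.0, P)
        assert beta == 0.0

    def test_bare_soil_disabled_share_zero(self):
        p = SimParams(soil_evap=0.0)
        beta, share = evaporative_fraction(0.0, 0.8, 290.0, p)
        assert beta == 0.0 and share == 0.0

    def test_warmer_air_evaporates_more(self):
        b_cold, _ = evaporative_fraction(2.0, 0.8, 278.0, P)
        b_warm, _ = evaporative_fraction(2.0, 0.8, 298.0, P)
        assert b_warm > b_cold

    def test_bounded_below_one(self):
        beta, _ = evaporative_fraction(50.0, 1.0, 320.0, P)
        assert 0.0 <= beta < 1.0

    def test_increasing_in_lai_and_moisture(self):
        b1, _ = evaporative_fraction(1.0, 0.3, 290.0, P)
        b2, _ = evaporative_fraction(2.0, 0.3, 290.0, P)
        b3, _ = evaporative_fraction(2.0, 0.4, 290.0, P)
        assert b2 > b1 and b3 > b2


class TestSurfaceSolver:
    def test_radiative_limit_matches_quartic_root(self):
        """beta=0, r_a -> inf: closed-form fourth root is the oracle."""
        sol = solve_surface_temperature(
            200.0, 0.0, 0.8, 280.0, r_a=1e12, beta=0.0, p=P
        )
        exact = (200.0 / (P.eps_s * P.sigma) + 0.8 * 280.0**4) ** 0.25
        assert abs(float(sol["t_s"]) - exact) < 1e-4
        assert exact == pytest.approx(304.8, abs=0.1)

    def test_constructed_fixed_point(self):
        """S_dn=0, eps_a=1, beta=0: T_s = T_a exactly balances."""
        sol = solve_surface_temperature(0.0, 0.2, 1.0, 285.0, r_a=80.0, beta=0.0, p=P)
        assert float(sol["t_s"]) == pytest.approx(285.0, abs=1e-6)
        resid = sol["s_net"] + sol["l_net"] - sol["h"] - sol["lam_e"]
        assert abs(float(resid)) < 1e-9

    def test_energy_closure_contract(self):
        rng = np.random.default_rng(3)
        n = 200
        sol = solve_surface_temperature(
            rng.uniform(20, 350, n), rng.uniform(0.1, 0.7, n),
            rng.uniform(0.6, 1.0, n), rng.uniform(240, 310, n),
            r_a=rng.uniform(30, 300, n), beta=rng.uniform(0, 0.7, n), p=P,
        )
        resid = sol["s_net"] + sol["l_net"] - sol["h"] - sol["lam_e"]
        assert np.max(np.abs(resid)) < 1e-3

    def test_nonconvergence_raises_with_residual(self):
        p = SimParams(newton_max_iter=1)
        with pytest.raises(RuntimeError, match="residual"):
            solve_surface_temperature(300.0, 0.2, 0.8, 280.0, r_a=50.0,
                                      beta=0.3, p=p)


class TestBucket:
    def test_steady_state(self):
        p = SimParams(runoff_coef=0.0)
        lam = 40.0
        precip = lam * SECONDS_PER_MONTH / LATENT_HEAT_VAPORIZATION
        sm, _ = step_soil_moisture(0.5, precip, lam, p)
        assert sm == pytest.approx(0.5, abs=1e-12)

    def test_drawdown_without_rain(self):
        sm, _ = step_soil_moisture(0.5, 0.0, 30.0, P)
        assert sm < 0.5

    def test_budget_closes_over_a_year(self):
        """inflow - outflow = storage change * capacity, to 1e-12 mm."""
        rng = np.random.default_rng(1)
        sm = 0.6
        in_mm = out_mm = 0.0
        for _ in range(12):
            precip = rng.uniform(0, 120)
            lam = rng.uniform(0, 80)
            sm_new, diag = step_soil_moisture(sm, precip, lam, P)
            in_mm += precip
            out_mm += float(diag["evap_mm"]) + float(diag["runoff_mm"])
            sm = sm_new
        assert in_mm - out_mm == pytest.approx((sm - 0.6) * P.capacity_mm, abs=1e-12)

    def test_negative_precip_rejected(self):
        with pytest.raises(ValueError):
            step_soil_moisture(0.5, -1.0, 0.0, P)


class TestAirHumidity:
    def test_dry_baseline(self):
        assert air_emissivity(0.0, P) == pytest.approx(P.eps_dry)

    def test_cap(self):
        assert air_emissivity(1e9, P) == P.eps_max


@pytest.fixture(scope="module")
def short_run(small_grid, smooth_lai, wet_forcing, params):
    return simulate_run(smooth_lai, wet_forcing, params, seed=21)


class TestSimulateRun:
    def test_bit_determinism(self, smooth_lai, wet_forcing, params, short_run):
        again = simulate_run(smooth_lai, wet_forcing, params, seed=21)
        for var in short_run.variables:
            np.testing.assert_array_equal(again[var].values, short_run[var].values)

    def test_distinct_seeds_spread(self, smooth_lai, wet_forcing, params, short_run):
        other = simulate_run(smooth_lai, wet_forcing, params, seed=22)
        assert np.max(np.abs(other["t_a"].values - short_run["t_a"].values)) > 0

    def test_energy_closure_every_month(self, short_run, params):
        es_sig = params.eps_s * params.sigma
        t_s, t_a = short_run["t_s"].values, short_run["t_a"].values
        s_net = short_run["s_dn"].values * (1 - short_run["alpha"].values)
        l_net = es_sig * (short_run["eps_a"].values * t_a**4 - t_s**4)
        h = params.rho * params.cp * (t_s - t_a) / short_run["r_a"].values
        resid = s_net + l_net - h - short_run["lam_e"].values
        assert np.max(np.abs(resid)) < 1e-3

    def test_latent_heat_nonnegative_and_h_sign(self, short_run):
        assert (short_run["lam_e"].values >= 0).all()
        h = short_run["h"].values
        dt = short_run["t_s"].values - short_run["t_a"].values
        assert np.all(np.sign(h) == np.sign(dt))

    def test_annual_cycle_settles_under_constant_forcing(
        self, small_grid, wet_forcing, quiet_params
    ):
        """Constant LAI, no noise: the state cycle repeats within 3 years."""
        from greenfeedback.grids import GriddedField, month_range
        lat, lon = small_grid
        months = month_range(2000, 2005)
        lai = GriddedField(np.full((len(months), 8, 8), 2.0), lat, lon,
                          months=months, units="m2 m-2")
        out = simulate_run(lai, wet_forcing, quiet_params, seed=5,
                           discard_years=0)
        ts = out["t_s"].values
        y3 = ts[36:48]
        y5 = ts[60:72]
        assert np.max(np.abs(y3 - y5)) < 0.05

    def test_jja_transpiration_share_exceeds_shoulder_seasons(self, short_run):
        """Summer canopies dominate ET more than spring/autumn ones do."""
        share = short_run["t_share"]
        by_season = {}
        for s in ("MAM", "JJA", "SON"):
            from greenfeedback.grids import Season, seasonal_series
            ser = seasonal_series(share, Season(s))
            by_season[s] = np.nanmean(ser.values)
        assert by_season["JJA"] > by_season["MAM"]
        assert by_season["JJA"] > by_season["SON"]

    def test_greener_run_wetter_fluxes(self, small_grid, smooth_lai,
                                       wet_forcing, quiet_params, ):
        """More leaves: more latent heat, darker and rougher surface (JJA)."""
        base = simulate_run(smooth_lai, wet_forcing, quiet_params, seed=9)
        green = simulate_run(
            smooth_lai.copy_with(values=smooth_lai.values * 1.3),
            wet_forcing, quiet_params, seed=9,
        )
        jja = [i for i, (_, m) in enumerate(base["t_s"].months) if m in (6, 7, 8)]
        assert np.mean(green["lam_e"].values[jja] - base["lam_e"].values[jja]) > 0
        assert np.all(green["alpha"].values[jja] <= base["alpha"].values[jja])
        assert np.all(green["r_a"].values[jja] <= base["r_a"].values[jja])
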