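import numpy as np
import pytest

from greenfeedback import decomposition as dec
from greenfeedback.decomposition import (
    Constants,
    decompose_delta_ta,
    decompose_delta_ts,
    forcing_components,
    group_r_nr,
    redistribution_factor_fa,
    redistribution_factor_fs,
)

C = Constants()


class TestRedistributionFactors:
    def test_fs_hand_value(self):
        """rho*Cp/r_a + 4*eps_s*sigma*T_s^3 at T_s=288.15 K, r_a=50 s/m."""
        fs = redistribution_factor_fs(288.15, 50.0)
        expect = 1.205 * 1013.0 / 50.0 + 4 * 0.95 * 5.67e-8 * 288.15**3
        assert fs == pytest.approx(expect, rel=1e-14)
        assert fs == pytest.approx(29.57, abs=0.01)

    def test_fs_limit_large_ra(self):
        fs = redistribution_factor_fs(288.15, 1e15)
        assert fs == pytest.approx(4 * C.eps_s * C.sigma * 288.15**3, rel=1e-9)

    def test_fs_monotonicity(self):
        assert redistribution_factor_fs(300.0, 50.0) > redistribution_factor_fs(280.0, 50.0)
        assert redistribution_factor_fs(288.0, 40.0) > redistribution_factor_fs(288.0, 60.0)

    def test_fa_equals_fs_at_unit_emissivity(self):
        t_s, r_a = np.array([250.0, 288.15, 310.0]), np.array([20.0, 50.0, 200.0])
        np.testing.assert_array_equal(
            redistribution_factor_fa(t_s, r_a, 1.0),
            redistribution_factor_fs(t_s, r_a),
        )

    def test_fa_hand_value(self):
        fa = redistribution_factor_fa(288.15, 50.0, 0.8)
        assert fa == pytest.approx(24.413 + 0.8 * 5.155, abs=0.01)

    def test_fa_never_exceeds_fs(self):
        rng = np.random.default_rng(0)
        t_s = rng.uniform(240, 320, 100)
        r_a = rng.uniform(10, 500, 100)
        eps = rng.uniform(0, 1, 100)
        assert np.all(
            redistribution_factor_fa(t_s, r_a, eps)
            <= redistribution_factor_fs(t_s, r_a) + 1e-12
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            redistribution_factor_fs(-1.0, 50.0)
        with pytest.raises(ValueError):
            redistribution_factor_fa(288.0, 50.0, 1.5)


BASE = {"s_dn": 200.0, "alpha": 0.2, "r_a": 50.0, "t_s": 290.0, "t_a": 288.0}
ZERO = {k: 0.0 for k in ("alpha", "s_dn", "lam_e", "r_a", "eps_a")}


class TestForcingComponents:
    def test_albedo_brightening_cools(self):
        comps = forcing_components(BASE, {**ZERO, "alpha": +0.01})
        assert comps.alpha == pytest.approx(-2.0)

    def test_emissivity_hand_value(self):
        base = dict(BASE, t_a=280.0)
        comps = forcing_components(base, {**ZERO, "eps_a": +0.01})
        assert comps.eps_a == pytest.approx(0.95 * 5.67e-8 * 280.0**4 * 0.01,
                                            rel=1e-12)
        assert comps.eps_a == pytest.approx(3.31, abs=0.01)

    def test_zero_deltas_zero_components(self):
        comps = forcing_components(BASE, ZERO)
        for v in comps.as_dict().values():
            assert v == 0.0
        assert comps.total == 0.0

    def test_greening_sign_convention(self):
        """Darkening warms, extra latent heat cools, moister air warms."""
        comps = forcing_components(
            BASE, {**ZERO, "alpha": -0.01, "lam_e": +5.0, "eps_a": +0.005}
        )
        assert comps.alpha > 0
        assert comps.lam_e < 0
        assert comps.eps_a > 0


class TestDecomposeTs:
    def test_division_example(self):
        comps = forcing_components(BASE, {**ZERO, "alpha": +0.01})
        fs = 29.57
        dts = decompose_delta_ts(comps, fs, 0.0, BASE["t_s"], BASE["t_a"],
                                 BASE["r_a"], 0.8)
        assert dts == pytest.approx(-2.0 / 29.57, rel=1e-9)

    def test_coefficient_collapses_when_air_is_surface(self):
        comps = forcing_components(BASE, ZERO)
        fs = redistribution_factor_fs(290.0, 50.0)
        dts = decompose_delta_ts(comps, fs, 0.3, 290.0, 290.0, 50.0, 1.0)
        assert dts == pytest.approx(0.3, rel=1e-12)

    def test_linearity(self):
        d = {**ZERO, "alpha": -0.01, "lam_e": 4.0, "r_a": -2.0}
        fs = redistribution_factor_fs(BASE["t_s"], BASE["r_a"])
        one = decompose_delta_ts(forcing_components(BASE, d), fs, 0.1,
                                 BASE["t_s"], BASE["t_a"], BASE["r_a"], 0.8)
        two = decompose_delta_ts(
            forcing_components(BASE, {k: 2 * v for k, v in d.items()}), fs,
            0.2, BASE["t_s"], BASE["t_a"], BASE["r_a"], 0.8)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_ta_vs_ts_coefficient_switch(self):
        comps = forcing_components(BASE, ZERO)
        fs = redistribution_factor_fs(BASE["t_s"], BASE["r_a"])
        a = decompose_delta_ts(comps, fs, 0.5, 300.0, 280.0, 50.0, 0.8,
                               ta_coefficient="ta")
        b = decompose_delta_ts(comps, fs, 0.5, 300.0, 280.0, 50.0, 0.8,
                               ta_coefficient="ts")
        assert a != b
        with pytest.raises(ValueError):
            decompose_delta_ts(comps, fs, 0.5, 300.0, 280.0, 50.0, 0.8,
                               ta_coefficient="nope")


class TestDecomposeTa:
    def test_exact_reconstruction(self):
        rng = np.random.default_rng(4)
        shape = (24, 6, 6)
        comps = forcing_components(
            {k: rng.uniform(0.5, 1.0, shape) * v for k, v in BASE.items()},
            {k: rng.normal(0, 1, shape) for k in ZERO},
        )
        fa = redistribution_factor_fa(
            rng.uniform(260, 300, shape), rng.uniform(30, 100, shape), 0.8
        )
        actual = rng.normal(0, 0.5, shape)
        out = decompose_delta_ta(actual, comps, fa)
        np.testing.assert_allclose(out.t_a_rad + out.t_a_cir, actual,
                                   atol=1e-12, rtol=0)

    def test_perfectly_explained_delta_has_zero_residual(self):
        comps = forcing_components(BASE, {**ZERO, "lam_e": 3.0})
        fa = redistribution_factor_fa(BASE["t_s"], BASE["r_a"], 0.8)
        out = decompose_delta_ta(comps.total / fa, comps, fa)
        assert out.t_a_cir == pytest.approx(0.0, abs=1e-15)

    def test_no_forcing_all_residual(self):
        comps = forcing_components(BASE, ZERO)
        fa = redistribution_factor_fa(BASE["t_s"], BASE["r_a"], 0.8)
        out = decompose_delta_ta(0.42, comps, fa)
        assert out.t_a_cir == pytest.approx(0.42)

    def test_component_contributions_sum_to_rad(self):
        comps = forcing_components(
            BASE, {"alpha": -0.01, "s_dn": 2.0, "lam_e": 4.0, "r_a": -1.0,
                   "eps_a": 0.004})
        fa = redistribution_factor_fa(BASE["t_s"], BASE["r_a"], 0.8)
        out = decompose_delta_ta(0.0, comps, fa)
        assert sum(out.per_component.values()) == pytest.approx(out.t_a_rad,
                                                                rel=1e-12)


class TestGrouping:
    def test_worked_example(self):
        comps = dec.ForcingComponents(
            alpha=np.array(-2.0), s_dn=np.array(1.0), lam_e=np.array(-5.0),
            r_a=np.array(0.5), eps_a=np.array(3.0),
        )
        g = group_r_nr(comps)
        assert g["R"] == pytest.approx(2.0)
        assert g["NR"] == pytest.approx(-4.5)
        assert g["All"] == pytest.approx(-2.5)

    def test_additivity_machine_precision(self):
        rng = np.random.default_rng(8)
        comps = dec.ForcingComponents(*(rng.normal(0, 5, (10, 4, 4))
                                        for _ in range(5)))
        g = group_r_nr(comps)
        np.testing.assert_allclose(g["All"], g["R"] + g["NR"], atol=1e-12, rtol=0)
        np.testing.assert_allclose(g["All"], comps.total, atol=1e-12, rtol=0)

    def test_zero_vector(self):
        comps = dec.ForcingComponents(*(np.zeros(3) for _ in range(5)))
        g = group_r_nr(comps)
        assert all(np.all(v == 0) for v in g.values())


def _paired_runs(eps, small_grid, smooth_lai, wet_forcing, quiet_params):
    from greenfeedback.simulator import simulate_run
    base = simulate_run(smooth_lai, wet_forcing, quiet_params, seed=7)
    pert = simulate_run(
        smooth_lai.copy_with(values=smooth_lai.values * (1.0 + eps)),
        wet_forcing, quiet_params, seed=7,
    )
    dv = {k: pert[k].values - base[k].values
          for k in ("alpha", "s_dn", "lam_e", "r_a", "eps_a", "t_a", "t_s")}
    bl = {k: base[k].values for k in ("s_dn", "alpha", "r_a", "t_s", "t_a",
                                      "eps_a")}
    return bl, dv


def _closure_error(eps, small_grid, smooth_lai, wet_forcing, quiet_params):
    bl, dv = _paired_runs(eps, small_grid, smooth_lai, wet_forcing, quiet_params)
    comps = forcing_components(bl, dv)
    fs = redistribution_factor_fs(bl["t_s"], bl["r_a"])
    pred = decompose_delta_ts(comps, fs, dv["t_a"], bl["t_s"], bl["t_a"],
                              bl["r_a"], bl["eps_a"])
    return float(np.max(np.abs(dv["t_s"] - pred)))


class TestFirstOrderFidelity:
    def test_residual_is_second_order(self, small_grid, smooth_lai,
                                      wet_forcing, quiet_params):
        """Halving the LAI perturbation shrinks the closure error ~4x."""
        e2 = _closure_error(0.02, small_grid, smooth_lai, wet_forcing, quiet_params)
        e1 = _closure_error(0.01, small_grid, smooth_lai, wet_forcing, quiet_params)
        assert e2 / e1 >= 3.5

    def test_circulation_residual_shrinks_with_perturbation(
        self, small_grid, smooth_lai, wet_forcing, quiet_params
    ):
        """With circulation noise off, dT_a_cir is the linearisation error
        plus humidity-forced z500 response, both O(perturbation)."""
        bl, dv = _paired_runs(0.02, small_grid, smooth_lai, wet_forcing,
                              quiet_params)
        comps = forcing_components(bl, dv)
        fa = redistribution_factor_fa(bl["t_s"], bl["r_a"], bl["eps_a"])
        out = decompose_delta_ta(dv["t_a"], comps, fa)
        # the residual exists but is small relative to the raw signal
        assert np.max(np.abs(out.t_a_cir)) < np.max(np.abs(dv["t_a"]))
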