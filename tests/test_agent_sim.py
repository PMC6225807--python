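"""Stochastic ensemble dynamics: stepping, boundaries, averaging, geometry."""

from dataclasses import replace

import numpy as np
import pytest

from gcsteer.agent_sim import (
    SimConfig,
    _angle_rng,
    init_ensemble,
    leading_edge_fraction,
    net_protrusion_angle,
    simulate_angle,
    simulate_growth_cone,
    steady_state_summary,
    step_ensemble,
    sweep,
)
from gcsteer.model_core import MTParams, ParameterError, retrograde_speed, validate_params


class TestEnsembleBasics:
    def test_initialization_contract(self, default_params):
        ens = init_ensemble(1000, default_params)
        assert ens.n_mt == 1000
        assert np.all(ens.r == 0.0)
        assert np.all(ens.growing)
        assert ens.vr == default_params.actin.v0
        assert leading_edge_fraction(ens, default_params) == 0.0

    def test_single_mt(self, default_params):
        ens = init_ensemble(1, default_params)
        assert ens.n_mt == 1 and ens.r[0] == 0.0

    def test_leading_edge_fraction_counts_strictly_past_cutoff(self, default_params):
        R = default_params.geom.R
        ens = init_ensemble(4, default_params)
        ens.r[:] = np.array([0.8, 0.5, 0.9, 0.1]) * R
        assert leading_edge_fraction(ens, default_params) == 0.5
        ens.r[:] = R
        assert leading_edge_fraction(ens, default_params) == 1.0
        ens.r[:] = 0.75 * R  # exactly on the line does not count
        assert leading_edge_fraction(ens, default_params) == 0.0

    def test_empty_ensemble_rejected(self, default_params):
        with pytest.raises(ParameterError):
            init_ensemble(0, default_params)


class TestStepping:
    def test_pure_polymerization_advance(self, default_params):
        """Without coupling or switching, a growing tip advances v_plus*dt."""
        params = default_params.replace(mt=MTParams(f_cat=1e-12, f_res=1e-12))
        cfg = SimConfig(dt=0.01, n_mt=1)
        rng = np.random.default_rng(0)
        ens = init_ensemble(1, params)
        step_ensemble(ens, 0.0, params, cfg, rng)
        assert ens.r[0] == pytest.approx(0.06)

    @pytest.mark.parametrize("mode", ["mean", "bernoulli"])
    def test_mean_drift_matches_effective_speed(self, default_params, mode):
        """Growing-tip drift is v_plus - pr*vr in both coupling modes."""
        pr, t_run = 0.3, 1.0
        params = default_params.replace(
            mt=MTParams(f_cat=1e-12, f_res=1e-12, v_plus=6.0, v_minus=9.6),
            beta=0.0,
        )
        cfg = SimConfig(dt=0.005, n_mt=1000, coupling_mode=mode)
        rng = np.random.default_rng(5)
        ens = init_ensemble(cfg.n_mt, params)
        n_steps = int(round(t_run / cfg.dt))
        for _ in range(n_steps):
            step_ensemble(ens, pr, params, cfg, rng)
        expected = params.mt.v_plus - pr * params.actin.v0
        drift = ens.r.mean() / t_run
        se = ens.r.std(ddof=1) / np.sqrt(cfg.n_mt) / t_run
        assert drift == pytest.approx(expected, abs=max(3 * se, 1e-9))

    def test_mt_count_conserved_and_positions_in_domain(self, gradient_params, fast_cfg):
        cfg = fast_cfg
        rng = np.random.default_rng(cfg.seed)
        ens = init_ensemble(cfg.n_mt, gradient_params)
        for _ in range(500):
            step_ensemble(ens, 0.5, gradient_params, cfg, rng)
            assert ens.n_mt == cfg.n_mt
            assert ens.r.min() >= 0.0 and ens.r.max() <= gradient_params.geom.R

    def test_feedback_disabled_keeps_flow_at_max(self, default_params, fast_cfg):
        params = default_params.replace(A=0.9, beta=0.0)
        ts = simulate_angle(40.0, params, fast_cfg)
        assert np.all(ts.vr == params.actin.v0)

    def test_recorded_flow_consistent_with_force_balance(self, gradient_params, fast_cfg):
        """At every recorded sample vr equals v0/(1+beta*p) bit-for-bit."""
        ts = simulate_angle(30.0, gradient_params, fast_cfg)
        expected = retrograde_speed(ts.p, gradient_params.actin)
        assert np.array_equal(ts.vr, expected)

    def test_run_level_determinism(self, gradient_params, fast_cfg):
        a = simulate_angle(60.0, gradient_params, fast_cfg)
        b = simulate_angle(60.0, gradient_params, fast_cfg)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.vr, b.vr)

    def test_angle_streams_independent_of_grid(self, gradient_params):
        """A slice's RNG substream is keyed on the angle value, not its index."""
        r1 = _angle_rng(3, 40.0).random(4)
        r2 = _angle_rng(3, 40.0).random(4)
        r3 = _angle_rng(3, 50.0).random(4)
        assert np.array_equal(r1, r2)
        assert not np.array_equal(r1, r3)

    def test_dt_invariant_enforced(self, default_params):
        with pytest.raises(ParameterError, match="dt"):
            SimConfig(dt=0.2).validate(default_params)


class TestSteadyStateSummary:
    def test_constant_series(self, default_params):
        from gcsteer.agent_sim import AngleTimeSeries

        cfg = SimConfig(t_total=20.0, burn_in=5.0)
        t = np.linspace(0.05, 20.0, 400)
        ts = AngleTimeSeries(theta_deg=0.0, t=t, p=np.full_like(t, 0.5),
                             vr=np.full_like(t, 4.0))
        s = steady_state_summary(ts, default_params, cfg)
        assert s["p_mean"] == 0.5 and s["p_se"] == 0.0
        assert s["vcell_mean"] == pytest.approx(default_params.actin.vp - 4.0)

    def test_requires_enough_samples(self, default_params):
        from gcsteer.agent_sim import AngleTimeSeries

        cfg = SimConfig(t_total=20.0, burn_in=19.0)
        t = np.linspace(0.05, 20.0, 400)
        ts = AngleTimeSeries(0.0, t, np.zeros_like(t), np.full_like(t, 5.0))
        with pytest.raises(ParameterError, match="samples"):
            steady_state_summary(ts, default_params, cfg)


class TestNetProtrusionAngle:
    def test_uniform_protrusion_points_along_original_axis(self):
        grid = np.arange(0.0, 181.0, 10.0)
        assert net_protrusion_angle(grid, np.ones_like(grid), 5.0) == pytest.approx(90.0)

    @pytest.mark.parametrize(
        "hot, expected",
        [((0.0,), 0.0), ((0.0, 90.0), 45.0), ((180.0,), 180.0)],
    )
    def test_localized_protrusion(self, hot, expected):
        grid = np.arange(0.0, 181.0, 10.0)
        v = np.isin(grid, hot).astype(float)
        assert net_protrusion_angle(grid, v, 5.0) == pytest.approx(expected)

    def test_zero_protrusion_undefined(self):
        grid = np.arange(0.0, 181.0, 10.0)
        assert net_protrusion_angle(grid, np.zeros_like(grid), 5.0) is None


class TestCouplingModes:
    def test_modes_statistically_indistinguishable(self, gradient_params):
        """Mean-coupling and per-MT Bernoulli coupling share steady state."""
        base = SimConfig(t_total=40.0, burn_in=15.0, n_mt=500, seed=9)
        out = {}
        for mode in ("mean", "bernoulli"):
            cfg = replace(base, coupling_mode=mode, seed=base.seed + (mode == "bernoulli"))
            ts = simulate_angle(90.0, gradient_params, cfg)
            out[mode] = steady_state_summary(ts, gradient_params, cfg)
        diff = abs(out["mean"]["p_mean"] - out["bernoulli"]["p_mean"])
        se = np.hypot(out["mean"]["p_se"], out["bernoulli"]["p_se"])
        assert diff <= 3.0 * se


class TestConeAndSweep:
    def test_profile_shapes_and_bounds(self, gradient_params):
        cfg = SimConfig(t_total=20.0, burn_in=8.0, n_mt=200, seed=2)
        prof = simulate_growth_cone(gradient_params, cfg)
        n = len(gradient_params.geom.theta_grid)
        for arr in (prof.p_mean, prof.vr_mean, prof.vcell_mean, prof.p_se):
            assert arr.shape == (n,)
        assert np.all((prof.p_mean >= 0) & (prof.p_mean <= 1))
        v0, beta = gradient_params.actin.v0, gradient_params.actin.beta
        assert np.all(prof.vr_mean <= v0 + 1e-12)
        assert np.all(prof.vr_mean >= v0 / (1 + beta) - 1e-12)
        assert prof.theta_p is not None and 0.0 <= prof.theta_p <= 180.0

    def test_single_point_sweep_matches_direct_call(self, gradient_params):
        cfg = SimConfig(t_total=15.0, burn_in=6.0, n_mt=100, seed=4)
        table = sweep(gradient_params, cfg, A_values=[0.9], beta_values=[0.1])
        assert len(table) == 1
        prof = simulate_growth_cone(gradient_params, cfg)
        assert table.loc[0, "theta_p"] == pytest.approx(prof.theta_p)
        assert table.loc[0, "seed"] == cfg.seed

    def test_empty_axis_rejected(self, gradient_params, fast_cfg):
        with pytest.raises(ParameterError):
            sweep(gradient_params, fast_cfg, A_values=[])
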