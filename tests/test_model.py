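"""Core ODE system: volume law, derivative terms, integration."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gliotwin import (
    InvalidStateError,
    ModelParams,
    PopulationState,
    Schedule,
    rhs,
    simulate,
    standard_course,
    volume,
)


class TestVolume:
    def test_empty_system_has_zero_volume(self, params):
        assert volume(PopulationState(0, 0, 0, 0), params) == 0.0

    def test_single_compartment_identity(self):
        p = ModelParams(v_T=1e-6, v_M=1e-6)
        state = PopulationState(T=1e6, P1=0, P2=0, A=0)
        assert volume(state, p) == pytest.approx(1.0, rel=1e-12)

    def test_weighted_sum_of_counts(self):
        p = ModelParams(v_T=1e-6, v_M=1e-6)
        state = PopulationState(T=1e6, P1=0, P2=0, A=5e5)
        assert volume(state, p) == pytest.approx(1.5, rel=1e-12)

    def test_damaged_pools_contribute(self, params):
        live = PopulationState(T=1e5, P1=1e3, P2=1e3, A=1e4)
        shifted = PopulationState(T=5e4, P1=1e3, P2=1e3, A=1e4, TD=5e4)
        assert volume(live, params) == pytest.approx(
            volume(shifted, params), rel=1e-12
        )


class TestRhs:
    def test_tumor_free_limit_decays_macrophages(self, params):
        state = PopulationState(T=0, P1=200, P2=100, A=400)
        d = rhs(0.0, state, params)
        assert d[0] == 0.0  # dT
        assert d[1] + d[2] == pytest.approx(-300 / params.tau_M, rel=1e-12)
        assert d[3] == pytest.approx(-400 / params.tau_M, rel=1e-12)

    def test_growth_vanishes_at_carrying_capacity(self, params):
        # construct a state with V = K exactly and a live P pool, so the
        # only surviving term in dT/dt is the kill term
        P1 = P2 = 500.0
        A = 1e3
        T = (params.K - params.v_M * (P1 + P2 + A)) / params.v_T
        state = PopulationState(T=T, P1=P1, P2=P2, A=A)
        d = rhs(0.0, state, params)
        assert d[0] == pytest.approx(-params.mu * T * A, rel=1e-12)

    def test_term_by_term_hand_evaluation(self, params):
        """Each derivative equals an independent term-by-term sum."""
        p = params
        T, P1, P2, A, TD, MD = 2.0e4, 400.0, 150.0, 900.0, 1.0e3, 50.0
        state = PopulationState(T, P1, P2, A, TD, MD)
        P = P1 + P2
        V = p.v_T * (T + TD) + p.v_M * (P + A + MD)
        lnKV = math.log(p.K / V)
        conv = p.lam * A * T * p.K_lam / (p.K_lam + T)
        dT = p.rho_T * T * P * lnKV - p.mu * T * A
        dP1 = p.rho_P * P1 * T * lnKV + conv - P1 / p.tau_M
        dP2 = p.rho_P * P2 * T * lnKV + p.phi * T - P2 / p.tau_M
        dA = (
            p.rho_A * A * T * lnKV
            - conv
            + p.xi * max(dT, 0.0)
            + p.phi_D * (TD + MD)  # inflammation active post-IR
            - A / p.tau_M
        )
        dTD = -TD / p.tau_TD
        dMD = -MD / p.tau_MD
        got = rhs(0.0, state, p, ir_active=True)
        np.testing.assert_allclose(
            got, [dT, dP1, dP2, dA, dTD, dMD], rtol=1e-14
        )

    def test_inflammation_flux_only_when_ir_active(self, params):
        state = PopulationState(1e4, 100, 100, 500, TD=1e3, MD=100)
        d_pre = rhs(0.0, state, params, ir_active=False)
        d_post = rhs(0.0, state, params, ir_active=True)
        assert d_post[3] - d_pre[3] == pytest.approx(
            params.phi_D * 1100, rel=1e-12
        )

    def test_michaelis_conversion_variant(self):
        p = ModelParams(conversion_form="michaelis")
        T, A = 5e4, 1e3
        state = PopulationState(T, 0, 0, A)
        d = rhs(0.0, state, p)
        d_sat = rhs(0.0, state, ModelParams())
        expected_ratio = 1.0 / p.K_lam  # T/(K+T) vs T*K/(K+T)
        assert (d[1]) / (d_sat[1]) == pytest.approx(expected_ratio, rel=1e-9)

    def test_nonfinite_state_raises(self, params):
        with pytest.raises(InvalidStateError):
            rhs(0.0, PopulationState(float("nan"), 0, 0, 0), params)


class TestSimulate:
    def test_tumor_free_macrophages_decay_exponentially(self, params):
        """With T=0 every coupling term vanishes: exact exp(-t/tau_M)."""
        init = PopulationState(T=0, P1=500, P2=250, A=1000)
        grid = np.linspace(0, 30, 31)
        traj = simulate(
            init, params, horizon=30, output_grid=grid, rtol=1e-10, atol=1e-8
        )
        expected = np.exp(-grid / params.tau_M)
        np.testing.assert_allclose(traj.states[:, 1], 500 * expected, rtol=1e-6)
        np.testing.assert_allclose(traj.states[:, 2], 250 * expected, rtol=1e-6)
        np.testing.assert_allclose(traj.states[:, 3], 1000 * expected, rtol=1e-6)

    def test_neutral_ir_event_is_identity(self, control_initial, params):
        """S_T=1 with S_M=1 transfers nothing: same curve as untreated."""
        p = params.replace(S_M=1.0)
        grid = np.linspace(0, 10, 41)
        base = simulate(control_initial, p, horizon=10, output_grid=grid)
        sched = Schedule(ir_times=(5.0,), s_t=1.0)
        treated = simulate(
            control_initial, p, schedule=sched, horizon=10, output_grid=grid
        )
        np.testing.assert_allclose(
            treated.volumes(), base.volumes(), rtol=1e-7
        )

    def test_damaged_pools_decay_closed_form(self, treated_params):
        """Between events TD and MD decay as exact exponentials."""
        init = PopulationState(T=1e5, P1=500, P2=500, A=5e3, TD=2e5, MD=1e4)
        grid = np.linspace(0, 12, 25)
        traj = simulate(init, treated_params, horizon=12, output_grid=grid)
        np.testing.assert_allclose(
            traj.states[:, 4],
            2e5 * np.exp(-grid / treated_params.tau_TD),
            rtol=1e-6,
        )
        np.testing.assert_allclose(
            traj.states[:, 5],
            1e4 * np.exp(-grid / treated_params.tau_MD),
            rtol=1e-6,
        )

    def test_gompertz_ceiling(self, control_initial):
        """With negligible killing and no events, volume stays at K.

        The proliferation terms all carry ln(K/V) and shut off at K; the
        MDM influx phi*T does not, so the macrophage pool can push the
        volume past K by a margin bounded by v_M*phi*T*tau_M — a relative
        overshoot of order 1e-4 here, independent of solver tolerance.
        """
        p = ModelParams(mu=1e-300)
        traj = simulate(
            control_initial, p, horizon=80,
            output_grid=np.linspace(0, 80, 161), rtol=1e-10, atol=1e-6,
        )
        assert traj.volumes().max() <= p.K * (1 + 1e-4)

    def test_nonnegativity_random_parameter_sweep(self):
        """Compartments stay non-negative across 100 random draws."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = ModelParams(
                rho_T=10 ** rng.uniform(-5, -3),
                rho_P=10 ** rng.uniform(-8, -6),
                rho_A=10 ** rng.uniform(-8, -6),
                mu=10 ** rng.uniform(-7, -4),
                lam=10 ** rng.uniform(-7, -5),
                phi=10 ** rng.uniform(-5, -3),
                xi=10 ** rng.uniform(-4, -2),
                S_M=rng.uniform(0.2, 1.0),
            )
            init = PopulationState(
                T=10 ** rng.uniform(3, 5),
                P1=10 ** rng.uniform(1, 3),
                P2=10 ** rng.uniform(1, 3),
                A=10 ** rng.uniform(2, 4),
            )
            sched = standard_course(s_t=rng.uniform(0.3, 1.0))
            traj = simulate(
                init, p, schedule=sched, horizon=8.0,
                output_grid=np.linspace(0, 8, 17), rtol=1e-6, atol=1.0,
            )
            assert (traj.states >= 0).all()

    def test_pooled_p_equals_split_p(self, treated_params):
        """Integrating P as one pooled equation reproduces P1+P2."""
        p = treated_params
        init = PopulationState(T=4e5, P1=900, P2=1200, A=1.4e4)
        grid = np.linspace(0, 25, 51)
        traj = simulate(init, p, horizon=25, output_grid=grid, rtol=1e-10,
                        atol=1e-6)

        def pooled_rhs(t, y):
            T, P, A = y
            V = p.v_T * T + p.v_M * (P + A)
            lnKV = math.log(p.K / V)
            conv = p.lam * A * T * p.K_lam / (p.K_lam + T)
            dT = p.rho_T * T * P * lnKV - p.mu * T * A
            dP = p.rho_P * P * T * lnKV + conv + p.phi * T - P / p.tau_M
            dA = (
                p.rho_A * A * T * lnKV - conv + p.xi * max(dT, 0.0)
                - A / p.tau_M
            )
            return [dT, dP, dA]

        sol = solve_ivp(
            pooled_rhs, (0, 25), [4e5, 2100, 1.4e4], t_eval=grid,
            rtol=1e-10, atol=1e-6,
        )
        split_P = traj.states[:, 1] + traj.states[:, 2]
        np.testing.assert_allclose(split_P, sol.y[1], rtol=1e-6)

    def test_rk4_oracle_equivalence(self, control_initial, params):
        """Adaptive solution matches a fixed-step RK4 oracle to 0.1 %."""
        horizon = 40.0
        grid = np.arange(0.0, horizon + 1.0, 1.0)
        traj = simulate(
            control_initial, params, horizon=horizon, output_grid=grid
        )

        dt = 1e-3
        y = control_initial.as_array()
        t = 0.0
        oracle = {0.0: y.copy()}
        n_steps = int(round(horizon / dt))
        check = set(grid.tolist())
        for k in range(n_steps):
            k1 = rhs(t, y, params)
            k2 = rhs(t + dt / 2, y + dt / 2 * k1, params)
            k3 = rhs(t + dt / 2, y + dt / 2 * k2, params)
            k4 = rhs(t + dt, y + dt * k3, params)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t = round((k + 1) * dt, 9)
            if t in check:
                oracle[t] = y.copy()
        v_oracle = np.array(
            [volume(PopulationState.from_array(oracle[g]), params)
             for g in grid]
        )
        np.testing.assert_allclose(traj.volumes(), v_oracle, rtol=1e-3)

    def test_invalid_horizon_rejected(self, control_initial, params):
        with pytest.raises(ValueError):
            simulate(control_initial, params, horizon=-1.0)

    def test_event_outside_horizon_rejected(self, control_initial, params):
        sched = Schedule(ir_times=(50.0,), s_t=0.5)
        with pytest.raises(ValueError):
            simulate(control_initial, params, schedule=sched, horizon=10.0)


class TestModelParams:
    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(rho_T=0.0)

    def test_survival_fraction_bounds(self):
        with pytest.raises(ValueError):
            ModelParams(S_M=1.5)

    def test_group_presets(self):
        p = ModelParams()
        assert p.for_group("control").mu == pytest.approx(1.2e-4)
        assert p.for_group("treated").mu == pytest.approx(5e-7)
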