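"""Integration engine tests: steady state, method of steps, oracle agreement."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from stresscircuit import (
    CircuitError,
    CircuitParameters,
    InductionSchedule,
    STANDARD_VARIANTS,
    SolverSettings,
    euler_oracle,
    find_preinduction_steady_state,
    simulate,
)
from stresscircuit.dde import SteadyStateError
from stresscircuit.model import N_SPECIES, rhs


class TestPreinductionSteadyState:
    def test_extinct_fixed_point(self, settings):
        p = CircuitParameters().with_updates(basal_T7=0.0, basal_R=0.0)
        ss = find_preinduction_steady_state(p, settings)
        assert ss.to_vector()[:N_SPECIES] == pytest.approx(np.zeros(N_SPECIES), abs=1e-9)

    def test_leaky_expression_nonzero(self, params, settings):
        ss = find_preinduction_steady_state(params, settings)
        assert ss.p_T7 > 0 and ss.g_N > 0 and ss.p_R > 0
        # stationarity
        sched = InductionSchedule(iptg_conc=0.0, t_induce=0.0, t_end=1.0)
        y = ss.to_vector()
        d = rhs(0.0, y, lambda tq: y, params, sched)
        assert np.max(np.abs(d[:N_SPECIES])) < 10 * settings.steady_state_tol

    def test_burn_in_extension_changes_nothing(self, params, settings):
        import dataclasses

        ss1 = find_preinduction_steady_state(params, settings)
        ss2 = find_preinduction_steady_state(
            params, dataclasses.replace(settings, burn_in_factor=100.0)
        )
        a, b = ss1.to_vector()[:N_SPECIES], ss2.to_vector()[:N_SPECIES]
        assert np.max(np.abs(a - b)) < 1e-5 * (1 + np.max(np.abs(a)))

    def test_nonconvergence_reported_with_species(self, settings):
        import dataclasses

        tight = dataclasses.replace(settings, steady_state_tol=1e-300, burn_in_factor=1.0)
        with pytest.raises(SteadyStateError, match="slowest species"):
            find_preinduction_steady_state(CircuitParameters(), tight)


class TestSimulate:
    def test_horizon_and_event(self, variant_trajectories, schedule):
        tr = variant_trajectories["WT_STRONG"]
        assert tr.times[0] == 0.0
        assert tr.times[-1] == pytest.approx(schedule.t_end)
        assert tr.events[0][0] == pytest.approx(schedule.t_induce)

    def test_initial_state_is_steady_history(self, params, schedule, settings, variant_trajectories):
        tr = variant_trajectories["NO_FB"]
        p = STANDARD_VARIANTS["NO_FB"].apply(params)
        ss = find_preinduction_steady_state(p, settings)
        assert tr.states[0][:N_SPECIES] == pytest.approx(ss.to_vector()[:N_SPECIES], rel=1e-8)

    def test_determinism(self, params, schedule, settings):
        a = simulate(params, STANDARD_VARIANTS["MUT_WEAK"], schedule, settings)
        b = simulate(params, STANDARD_VARIANTS["MUT_WEAK"], schedule, settings)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)

    def test_nonnegativity_random_parameter_draws(self, schedule):
        rng = np.random.default_rng(42)
        base = CircuitParameters()
        for _ in range(5):
            mults = rng.lognormal(0.0, 0.3, size=8)
            p = base.with_updates(
                k_tx_T7=base.k_tx_T7 * mults[0],
                k_tx_G=base.k_tx_G * mults[1],
                k_tx_R=base.k_tx_R * mults[2],
                k_tl_G=base.k_tl_G * mults[3],
                k_tl_R=base.k_tl_R * mults[4],
                k_fold=base.k_fold * mults[5],
                k_agg=base.k_agg * mults[6],
                K_tetR=base.K_tetR * mults[7],
            )
            tr = simulate(p, STANDARD_VARIANTS["WT_STRONG"], schedule)
            assert tr.states[:, :N_SPECIES].min() >= 0.0

    def test_feedback_strength_ordering(self, variant_trajectories, schedule):
        end = {
            lab: tr.observable("total_gfp", schedule.t_end)
            for lab, tr in variant_trajectories.items()
        }
        assert end["NO_FB"] >= end["MUT_WEAK"] >= end["MUT_STRONG"] >= end["WT_STRONG"]

    def test_no_feedback_equivalence(self, params, schedule, settings):
        """NO_FB trajectory matches a model with TetR genes removed entirely."""
        tr_variant = simulate(params, STANDARD_VARIANTS["NO_FB"], schedule, settings)
        stripped = params.with_updates(k_tx_R=0.0, basal_R=0.0, k_tl_R=0.0)
        from stresscircuit.model import FeedbackVariant

        tr_stripped = simulate(
            stripped, FeedbackVariant("bare", promoter_scale=0.0), schedule, settings
        )
        grid = np.linspace(0, schedule.t_end, 49)
        a = tr_variant.at(grid)[:, :N_SPECIES]
        b = tr_stripped.at(grid)[:, :N_SPECIES]
        assert np.max(np.abs(a - b)) < 1e-6 * (1 + np.abs(a).max())

    def test_history_continuity_at_nodes(self, variant_trajectories):
        tr = variant_trajectories["WT_STRONG"]
        idx = np.linspace(1, len(tr.times) - 2, 25).astype(int)
        interp = tr.at(tr.times[idx])
        assert np.allclose(interp, tr.states[idx], rtol=1e-9, atol=1e-9)

    def test_grid_refinement_convergence(self, params, schedule):
        import dataclasses

        s1 = SolverSettings(rel_tol=1e-6, abs_tol=1e-8)
        s2 = dataclasses.replace(s1, rel_tol=5e-7, abs_tol=5e-9)
        a = simulate(params, STANDARD_VARIANTS["WT_STRONG"], schedule, s1)
        b = simulate(params, STANDARD_VARIANTS["WT_STRONG"], schedule, s2)
        ga = a.observable("total_gfp", schedule.t_end)
        gb = b.observable("total_gfp", schedule.t_end)
        assert abs(ga - gb) / gb < 10 * s1.rel_tol


class TestMassBalance:
    def test_gfp_mass_balance(self, variant_trajectories):
        """Translated GFP = pools gained + degraded + diluted, to solver tolerance."""
        for tr in variant_trajectories.values():
            y_end = tr.states[-1]
            y_start = tr.states[0]
            pools_delta = y_end[3:6].sum() - y_start[3:6].sum()
            translated, degraded, diluted = y_end[8:11]
            residual = translated - (pools_delta + degraded + diluted)
            assert abs(residual) < 1e-5 * max(translated, 1.0)


class TestEulerOracle:
    def test_refuses_dt_above_delay(self, params, schedule):
        with pytest.raises(CircuitError):
            euler_oracle(params, STANDARD_VARIANTS["NO_FB"], schedule, dt=0.5)

    def test_zero_rate_parameters_constant(self, schedule):
        p = CircuitParameters().with_updates(
            mu0=0.0, k_tx_T7=0.0, k_tx_G=0.0, k_tx_R=0.0, basal_T7=0.0, basal_R=0.0
        )
        tr = euler_oracle(p, STANDARD_VARIANTS["NO_FB"], schedule, dt=1e-2)
        assert np.allclose(tr.states, tr.states[0])

    def test_first_order_convergence(self, params, schedule):
        """Halving dt roughly halves the deviation from the adaptive solution."""
        sched = InductionSchedule(iptg_conc=1.0, t_induce=0.5, t_end=3.0)
        ref = simulate(params, STANDARD_VARIANTS["NO_FB"], sched)
        grid = np.linspace(0, 3.0, 13)
        R = ref.at(grid)[:, :N_SPECIES]
        errs = []
        for dt in (2e-3, 1e-3):
            tr = euler_oracle(params, STANDARD_VARIANTS["NO_FB"], sched, dt=dt)
            idx = np.round(grid / dt).astype(int)
            E = tr.states[idx][:, :N_SPECIES]
            errs.append(np.max(np.abs(E - R) / (np.abs(R).max(axis=0) + 1e-12)))
        ratio = errs[0] / errs[1]
        assert 1.5 < ratio < 2.6

    def test_cross_integrator_agreement_moderate_step(self, params, schedule):
        """Coarse check; the strict dt=1e-4 comparison runs in the acceptance suite."""
        tr = simulate(params, STANDARD_VARIANTS["WT_STRONG"], schedule)
        eo = euler_oracle(params, STANDARD_VARIANTS["WT_STRONG"], schedule, dt=1e-3)
        grid = np.linspace(0, schedule.t_end, 49)
        idx = np.round(grid / 1e-3).astype(int)
        A = tr.at(grid)[:, :N_SPECIES]
        B = eo.states[idx][:, :N_SPECIES]
        rel = np.abs(A - B).max(axis=0) / (np.abs(B).max(axis=0) + 1e-12)
        assert rel.max() < 1e-2


class TestZeroDelayLimit:
    def test_matches_stiff_ode_reference(self, params, schedule):
        p0 = params.with_updates(tau_tx=0.0, tau_tl=0.0)
        strict = SolverSettings(rel_tol=1e-10, abs_tol=1e-12)
        tr = simulate(p0, STANDARD_VARIANTS["WT_STRONG"], schedule, strict)
        pv = STANDARD_VARIANTS["WT_STRONG"].apply(p0)
        ss = find_preinduction_steady_state(pv, strict)
        y0 = ss.to_vector()

        def f(t, y):
            yc = y.copy()
            yc[:N_SPECIES] = np.maximum(yc[:N_SPECIES], 0.0)
            return rhs(t, yc, lambda tq: yc, pv, schedule)

        r1 = solve_ivp(f, (0, schedule.t_induce), y0, method="Radau", rtol=1e-11, atol=1e-13,
                       dense_output=True)
        r2 = solve_ivp(f, (schedule.t_induce, schedule.t_end), r1.y[:, -1], method="Radau",
                       rtol=1e-11, atol=1e-13, dense_output=True)
        grid = np.linspace(0, schedule.t_end, 97)
        A = tr.at(grid)[:, :N_SPECIES]
        R = np.stack(
            [(r1.sol(t) if t <= schedule.t_induce else r2.sol(t))[:N_SPECIES] for t in grid]
        )
        rel = np.abs(A - R).max(axis=0) / np.abs(R).max(axis=0)
        assert rel.max() < 1e-6
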