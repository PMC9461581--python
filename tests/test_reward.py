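"""Tests of reward accounting and strategy evaluation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from patchforage import (
    AgentStrategy,
    GroupModel,
    PatchEnvironment,
    SimulationSettings,
    evaluate_strategy,
    optimize_partner,
    reward_rate,
    sweep_symmetric,
    total_food_consumed,
)
from patchforage.model import counting_function, depletion_exponent
from patchforage.reward import moving_average


def consumption_quadrature(times, env, n):
    """Independent oracle: integrate N(t) * rho * e^{-Lambda(t)} between
    decision times with adaptive quadrature."""
    total = 0.0
    knots = [0.0] + list(times)
    for k in range(len(times)):
        lo, hi = knots[k], knots[k + 1]
        if hi <= lo:
            continue
        val, _ = quad(
            lambda t: counting_function(times, t, n)
            * env.rho
            * np.exp(-depletion_exponent(times, t, env.tau, n)),
            lo,
            hi,
            limit=200,
        )
        total += val
    return total


class TestTotalFoodConsumed:
    def test_single_agent_eats_whole_patch(self, env):
        assert total_food_consumed(np.array([500.0]), env) == pytest.approx(
            env.rho * env.tau, rel=1e-6
        )

    def test_instant_departure_consumes_nothing(self, env):
        assert total_food_consumed(np.array([0.0, 0.0]), env) == 0.0

    def test_simultaneous_pair_closed_form(self, env):
        t = 3.0
        expected = env.rho * env.tau * (1 - np.exp(-2 * t / env.tau))
        assert total_food_consumed(np.array([t, t]), env) == pytest.approx(expected)

    def test_unsorted_times_rejected(self, env):
        with pytest.raises(ValueError):
            total_food_consumed(np.array([2.0, 1.0]), env)

    @given(
        times=st.lists(st.floats(0.01, 20.0), min_size=1, max_size=4).map(sorted)
    )
    def test_telescoping_matches_quadrature_and_bound(self, times):
        env = PatchEnvironment(rho=2.0, tau=5.0, alpha=1.0, travel_time=5.0)
        times = np.asarray(times)
        n = len(times)
        closed = total_food_consumed(times, env)
        oracle = consumption_quadrature(times, env, n)
        assert closed == pytest.approx(oracle, rel=1e-6, abs=1e-9)
        assert closed <= env.rho * env.tau + 1e-9


class TestRewardRate:
    def test_break_even(self, env):
        t = 4.0
        r = env.alpha * (env.travel_time + t)
        assert reward_rate(r, t, env) == 0.0

    def test_pure_cost(self, env):
        assert reward_rate(0.0, 4.0, env) == pytest.approx(-env.alpha)

    def test_linear_in_reward(self, env):
        t = 4.0
        base = reward_rate(3.0, t, env)
        doubled = reward_rate(6.0, t, env)
        assert doubled - base == pytest.approx(3.0 / (env.travel_time + t))

    def test_degenerate_denominator_rejected(self):
        env = PatchEnvironment(travel_time=0.0)
        with pytest.raises(ValueError):
            reward_rate(1.0, 0.0, env)


class TestEvaluateStrategy:
    def test_decoupled_equals_mode_none_exactly(self, env):
        s = SimulationSettings(dt=0.005, t_max=300, n_trials=500, seed=5)
        a = evaluate_strategy(GroupModel.symmetric("none", 2, -1.0, 0.0, 1.0, env), s)
        b = evaluate_strategy(
            GroupModel.symmetric("diffusive", 2, -1.0, 0.0, 1.0, env), s
        )
        assert a.rr == b.rr
        assert a.mean_group_time == b.mean_group_time

    def test_stderr_shrinks_with_trials(self, env):
        m = GroupModel.symmetric("none", 2, -1.0, 0.0, 1.0, env)
        se = [
            evaluate_strategy(
                m, SimulationSettings(dt=0.005, t_max=300, n_trials=n, seed=5)
            ).rr_stderr
            for n in (200, 1800)
        ]
        assert se[1] < se[0] / 2  # ~1/sqrt(9)

    def test_label_permutation_invariance_within_noise(self, env):
        s = SimulationSettings(dt=0.005, t_max=300, n_trials=2000, seed=8)
        a = GroupModel(mode="diffusive",
                       agents=(AgentStrategy(-1.0, 1.0), AgentStrategy(-2.0, 0.5)),
                       noise_scale=1.0, env=env)
        b = GroupModel(mode="diffusive",
                       agents=(AgentStrategy(-2.0, 0.5), AgentStrategy(-1.0, 1.0)),
                       noise_scale=1.0, env=env)
        ea, eb = evaluate_strategy(a, s), evaluate_strategy(b, s)
        assert abs(ea.rr - eb.rr) < 3 * (ea.rr_stderr + eb.rr_stderr)


class TestSweeps:
    def test_single_cell_sweep_equals_evaluate(self, env):
        s = SimulationSettings(dt=0.005, t_max=300, n_trials=300, seed=4)
        res = sweep_symmetric("diffusive", np.array([-1.0]), np.array([0.5]),
                              1.0, env, s, include_infinite_kappa=False)
        direct = evaluate_strategy(
            GroupModel.symmetric("diffusive", 2, -1.0, 0.5, 1.0, env), s
        )
        assert res.rr_surface[0, 0] == direct.rr

    def test_smoothing_preserves_constant_curve(self):
        assert np.allclose(moving_average(np.full(7, -1.3), 3), -1.3)

    def test_empty_grid_rejected(self, env):
        s = SimulationSettings(n_trials=10)
        with pytest.raises(ValueError):
            sweep_symmetric("diffusive", np.array([]), np.array([1.0]), 1.0, env, s)

    def test_infinite_kappa_column_present(self, env):
        s = SimulationSettings(dt=0.01, t_max=300, n_trials=200, seed=4)
        res = sweep_symmetric("pulsatile", np.array([-1.5, -1.0]), np.array([1.0]),
                              1.0, env, s)
        assert res.rr_infinite_kappa is not None
        assert res.rr_infinite_kappa.shape == (2,)


class TestOptimizePartner:
    def test_degenerate_grid_returns_that_cell(self, env):
        s = SimulationSettings(dt=0.01, t_max=300, n_trials=100, seed=4)
        best, rr, surface = optimize_partner(
            AgentStrategy(-1.0, 1.0), np.array([-2.0]), np.array([0.5]),
            "diffusive", 1.0, env, s,
        )
        assert best.theta == -2.0 and best.kappa == 0.5
        assert surface.shape == (1, 1)

    def test_argmax_is_on_surface_maximum(self, env):
        s = SimulationSettings(dt=0.01, t_max=300, n_trials=400, seed=4)
        th2 = np.linspace(-2.5, -0.5, 3)
        ka2 = np.linspace(0.0, 2.0, 3)
        best, rr, surface = optimize_partner(
            AgentStrategy(-1.0, 1.0), th2, ka2, "diffusive", 1.0, env, s
        )
        assert rr == surface.max()
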