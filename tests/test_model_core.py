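"""Unit tests for the domain types and shared dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from patchforage import (
    AgentStrategy,
    DepartureRecord,
    GroupModel,
    PatchEnvironment,
    apply_pulse,
    counting_function,
    coupling_drift_diffusive,
    depletion_exponent,
    drift,
)

sorted_times = st.lists(
    st.floats(0.01, 30.0), min_size=0, max_size=4
).map(sorted)


class TestTypes:
    def test_environment_requires_profitable_patch(self):
        with pytest.raises(ValueError):
            PatchEnvironment(rho=1.0, alpha=2.0)
        with pytest.raises(ValueError):
            PatchEnvironment(tau=-1.0)

    def test_strategy_requires_negative_threshold(self):
        with pytest.raises(ValueError):
            AgentStrategy(theta=0.5)
        with pytest.raises(ValueError):
            AgentStrategy(theta=-1.0, kappa=-0.1)

    def test_group_model_validation(self):
        with pytest.raises(ValueError):
            GroupModel(mode="telepathic", agents=(AgentStrategy(-1.0),), noise_scale=1.0)
        with pytest.raises(ValueError):
            GroupModel(mode="none", agents=(), noise_scale=1.0)
        with pytest.raises(ValueError):
            GroupModel(mode="none", agents=(AgentStrategy(-1.0),), noise_scale=0.0)

    def test_mode_none_ignores_kappa(self):
        m = GroupModel(mode="none", agents=(AgentStrategy(-1.0, kappa=3.0),),
                       noise_scale=1.0)
        assert m.kappas.tolist() == [0.0]

    def test_departure_record_invariants(self):
        with pytest.raises(ValueError):
            DepartureRecord([2.0, 1.0], [0, 1], [False, False])
        rec = DepartureRecord([1.0, 2.5], [1, 0], [False, False])
        assert rec.group_time == 2.5


class TestCountingFunction:
    @pytest.mark.parametrize(
        "times,t,n,expected",
        [
            ([], 3.7, 2, 2),        # no decisions yet
            ([1.0], 1.5, 2, 1),     # between first and second decision
            ([1.0, 2.0], 5.0, 2, 0),  # all decided
            ([1.0], 1.0, 2, 1),     # right-continuous at the decision time
        ],
    )
    def test_examples(self, times, t, n, expected):
        assert counting_function(times, t, n) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            counting_function([], -0.1, 2)

    @given(times=sorted_times, t=st.floats(0.0, 40.0))
    def test_bounds_and_monotonicity(self, times, t):
        n = 4
        c = counting_function(times, t, n)
        assert 0 <= len(times) <= n or True
        assert counting_function(times, 0.0, n) == n - sum(x <= 0 for x in times)
        later = counting_function(times, t + 1.0, n)
        assert later <= c
        if times and t > max(times):
            assert c == n - len(times)


class TestDepletionExponent:
    def test_single_agent_linear(self):
        assert depletion_exponent([], 3.0, 5.0, 1) == pytest.approx(3.0 / 5.0)

    def test_two_agents_double_rate(self):
        assert depletion_exponent([], 3.0, 5.0, 2) == pytest.approx(6.0 / 5.0)

    def test_post_decision_slope_drops(self):
        # after T1, one of two agents forages: Lambda = (2 T1 + (t-T1))/tau
        tau, t1, t = 5.0, 1.0, 4.0
        assert depletion_exponent([t1], t, tau, 2) == pytest.approx(
            (2 * t1 + (t - t1)) / tau
        )

    @given(times=sorted_times, t=st.floats(0.0, 40.0))
    def test_continuous_nondecreasing_piecewise_linear(self, times, t):
        tau, n = 5.0, 4
        lam = depletion_exponent(times, t, tau, n)
        assert lam >= 0
        assert depletion_exponent(times, t + 0.5, tau, n) >= lam
        # continuity across a decision time
        for t_dec in times:
            lo = depletion_exponent(times, max(t_dec - 1e-9, 0.0), tau, n)
            hi = depletion_exponent(times, t_dec + 1e-9, tau, n)
            assert hi - lo < 1e-6


class TestDrift:
    def test_initial_drift(self, env):
        assert drift([], 0.0, env, 3) == pytest.approx(env.rho - env.alpha)

    def test_late_drift_negative(self, env):
        # rho=2, alpha=1, tau=5 at t=5*tau: 2 e^-5 - 1 < 0
        val = drift([], 25.0, env, 1)
        assert val == pytest.approx(2 * math.exp(-5) - 1)
        assert val < 0

    def test_two_agents_equal_single_at_double_time(self, env):
        for t in (0.5, 2.0, 7.0):
            assert drift([], t, env, 2) == pytest.approx(drift([], 2 * t, env, 1))

    def test_drift_continuous_across_decisions(self, env):
        times = [1.5]
        lo = drift(times, 1.5 - 1e-9, env, 2)
        hi = drift(times, 1.5 + 1e-9, env, 2)
        assert abs(hi - lo) < 1e-6


class TestDiffusiveCoupling:
    def test_equal_gaps_zero(self):
        ss = [AgentStrategy(-1.0, 2.0), AgentStrategy(-2.0, 1.0)]
        # x - theta equal for both
        inc = coupling_drift_diffusive(np.array([0.0, -1.0]), ss)
        assert np.allclose(inc, 0.0)

    def test_decided_neighbor_pulls_toward_threshold(self):
        ss = [AgentStrategy(-1.0, 1.5), AgentStrategy(-2.0, 1.0)]
        d = 0.7
        states = np.array([-1.0 + d, -2.0])  # agent 2 decided (at threshold)
        inc = coupling_drift_diffusive(states, ss)
        assert inc[0] == pytest.approx(-1.5 * d)

    @given(
        gaps=st.lists(st.floats(-3, 3), min_size=3, max_size=5),
        kappas=st.lists(st.floats(0, 4), min_size=5, max_size=5),
    )
    def test_matches_pairwise_sum_oracle(self, gaps, kappas):
        n = len(gaps)
        ss = [AgentStrategy(-1.0, kappas[i]) for i in range(n)]
        states = np.array(gaps) - 1.0
        inc = coupling_drift_diffusive(states, ss)
        for i in range(n):
            brute = ss[i].kappa * sum(gaps[j] - gaps[i] for j in range(n) if j != i)
            assert inc[i] == pytest.approx(brute, abs=1e-9)


class TestApplyPulse:
    def test_zero_kappa_no_effect(self):
        ss = [AgentStrategy(-1.0, 0.0), AgentStrategy(-1.0, 0.0)]
        states, cascade = apply_pulse(np.array([-1.0, 0.5]), ss, 0)
        assert cascade == []
        assert states[1] == 0.5

    def test_single_step_cascade(self):
        # agent 2 sits 0.5 above threshold; pulse of 1.0 pushes it past
        ss = [AgentStrategy(-1.0, 1.0), AgentStrategy(-1.0, 1.0)]
        states, cascade = apply_pulse(np.array([-1.0, -0.5]), ss, 0)
        assert cascade == [1]
        assert states[1] == -1.0

    def test_chain_cascade_order(self):
        # pulse from 0 triggers 1 but not 2; 1's pulse then triggers 2
        ss = [
            AgentStrategy(-1.0, 0.0),
            AgentStrategy(-1.0, 0.6),   # at -0.5: one pulse of 0.6 crosses
            AgentStrategy(-1.0, 0.45),  # at -0.2: needs two pulses (0.9)
        ]
        states, cascade = apply_pulse(np.array([-1.0, -0.5, -0.2]), ss, 0)
        assert cascade == [1, 2]
        assert np.allclose(states, [-1.0, -1.0, -1.0])

    def test_already_decided_rejected(self):
        ss = [AgentStrategy(-1.0, 1.0), AgentStrategy(-1.0, 1.0)]
        with pytest.raises(ValueError):
            apply_pulse(np.array([-1.0, 0.0]), ss, 0,
                        decided=np.array([True, False]))

    @given(
        xs=st.lists(st.floats(-0.99, 3.0), min_size=2, max_size=5),
        kappas=st.lists(st.floats(0.0, 2.0), min_size=6, max_size=6),
    )
    def test_terminates_and_clamps(self, xs, kappas):
        n = len(xs) + 1
        ss = [AgentStrategy(-1.0, kappas[i]) for i in range(n)]
        states = np.array([-1.0] + xs)
        out, cascade = apply_pulse(states, ss, 0)
        assert len(cascade) <= n - 1
        for i in cascade:
            assert out[i] == -1.0
        # non-cascaded agents moved down by at least one pulse round
        for i in range(1, n):
            if i not in cascade:
                assert out[i] <= states[i]
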