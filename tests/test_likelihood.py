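"""Tests of the ordered-pair likelihood backends."""

import math

import numpy as np
import pytest

from patchforage import (
    GroupModel,
    LikelihoodSettings,
    SimulationSettings,
    dataset_loglik,
    dataset_pairs,
    pair_density_table,
    pair_loglik_diffusive,
    pair_loglik_none,
    pair_loglik_pulsatile,
    simulate_dataset,
)
from patchforage.likelihood import clear_cache


@pytest.fixture(scope="module")
def settings():
    return LikelihoodSettings()


@pytest.fixture(scope="module")
def nc_data(env):
    m = GroupModel.symmetric("none", 2, -1.5, 0.0, 1.0, env)
    df = simulate_dataset(m, SimulationSettings(dt=0.005, t_max=300,
                                                n_trials=400, seed=31))
    return dataset_pairs(df)


class TestExactPropagationTable:
    def test_joint_density_integrates_to_one(self, env, settings):
        for cls, kappa in (("none", 0.0), ("pulsatile", 1.5)):
            tab = pair_density_table(cls, -1.5, kappa, 1.0, env, settings)
            assert tab.total_probability() == pytest.approx(1.0, abs=0.04)

    def test_survivor_mass_conserved_per_node(self, env, settings):
        # continuous flux + atom from each first-decision node accounts
        # for the survivor's conditional mass
        tab = pair_density_table("pulsatile", -1.5, 2.0, 1.0, env, settings)
        g_int = np.trapezoid(np.exp(tab.log_g_table), tab.s_grid, axis=1)
        s_at_nodes = np.interp(tab.t1_nodes, tab.t_grid, tab.survival)
        mid = slice(2, -2)  # skip extreme quantile nodes
        assert np.allclose((g_int + tab.atom)[mid], s_at_nodes[mid],
                           rtol=0.08, atol=0.01)

    def test_pulsatile_zero_kappa_reduces_to_none(self, env, settings):
        for t1, t2 in [(2.0, 4.0), (1.0, 9.0), (5.0, 5.5)]:
            a = pair_loglik_none(t1, t2, -1.5, 1.0, env, settings)
            b = pair_loglik_pulsatile(t1, t2, -1.5, 0.0, 1.0, env,
                                      simultaneous=False, settings=settings)
            assert a == pytest.approx(b, abs=1e-9)

    def test_spanning_pulse_sends_all_mass_to_atom(self, env, settings):
        # kappa far above the belief excursion: the atom holds the
        # survivor's entire conditional mass at every node
        tab = pair_density_table("pulsatile", -1.0, 50.0, 1.0, env, settings)
        s_at_nodes = np.interp(tab.t1_nodes, tab.t_grid, tab.survival)
        assert np.allclose(tab.atom, s_at_nodes, rtol=0.05, atol=0.01)
        g_int = np.trapezoid(np.exp(tab.log_g_table), tab.s_grid, axis=1)
        assert np.all(g_int < 0.01)

    def test_ordering_and_horizon_errors(self, env, settings):
        tab = pair_density_table("none", -1.5, 0.0, 1.0, env, settings)
        with pytest.raises(ValueError):
            tab.loglik(np.array([3.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            tab.loglik(np.array([2.0]), np.array([settings.horizon + 5.0]))

    def test_theta_profile_peaks_at_truth(self, env, settings, nc_data):
        t1, t2, tie = nc_data
        grid = np.linspace(-3.0, -0.5, 11)
        lls = [dataset_loglik(t1, t2, tie, "none", th, 0.0, 1.0, env, settings)
               for th in grid]
        assert abs(grid[int(np.argmax(lls))] - (-1.5)) <= 0.3


class TestDiffusiveBackend:
    def test_zero_kappa_agrees_with_exact_backend(self, env, settings, nc_data):
        t1, t2, tie = nc_data
        tab_nc = pair_density_table("none", -1.5, 0.0, 1.0, env, settings)
        tab_d = pair_density_table("diffusive", -1.5, 1e-6, 1.0, env, settings)
        a = tab_nc.loglik(t1, t2)
        b = tab_d.loglik(t1, t2)
        # histogram estimate vs exact propagation: agree on average
        assert abs(np.mean(a - b)) < 0.25

    def test_strong_coupling_concentrates_near_diagonal(self, env, settings):
        m = GroupModel.symmetric("diffusive", 2, -1.5, 5.0, 1.0, env)
        df = simulate_dataset(m, SimulationSettings(dt=0.005, t_max=300,
                                                    n_trials=200, seed=33))
        t1, t2, _ = dataset_pairs(df)
        assert np.median(t2 - t1) < 0.5
        ll_strong = dataset_loglik(t1, t2, None, "diffusive", -1.5, 5.0, 1.0,
                                   env, settings)
        ll_weak = dataset_loglik(t1, t2, None, "diffusive", -1.5, 0.3, 1.0,
                                 env, settings)
        assert ll_strong > ll_weak

    def test_deterministic_given_likelihood_seed(self, env, settings):
        clear_cache()
        a = pair_loglik_diffusive(2.0, 2.5, -1.5, 2.0, 1.0, env, settings)
        clear_cache()
        b = pair_loglik_diffusive(2.0, 2.5, -1.5, 2.0, 1.0, env, settings)
        assert a == b


class TestDatasetLoglik:
    def test_bin_convention_reduces_to_pair_sum(self, env, settings):
        t1 = np.array([2.0, 3.0])
        t2 = np.array([4.0, 3.5])
        tie = np.array([False, False])
        total = dataset_loglik(t1, t2, tie, "none", -1.5, 0.0, 1.0, env,
                               settings, data_resolution=0.01)
        pairs = sum(pair_loglik_none(a, b, -1.5, 1.0, env, settings)
                    for a, b in zip(t1, t2))
        assert total == pytest.approx(pairs + 4 * math.log(0.01))

    def test_tie_scores_atom_with_single_bin_factor(self, env, settings):
        t1 = np.array([2.0])
        t2 = np.array([2.0])
        tie = np.array([True])
        total = dataset_loglik(t1, t2, tie, "pulsatile", -1.0, 50.0, 1.0, env,
                               settings, data_resolution=0.01)
        pair = pair_loglik_pulsatile(2.0, 2.0, -1.0, 50.0, 1.0, env,
                                     simultaneous=True, settings=settings)
        assert total == pytest.approx(pair + math.log(0.01))

    def test_negative_kappa_rejected(self, env, settings):
        with pytest.raises(ValueError):
            pair_loglik_pulsatile(2.0, 3.0, -1.0, -0.5, 1.0, env,
                                  settings=settings)
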