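"""Tests of MAP estimation, Bayes factors, and the confusion machinery."""

import math

import numpy as np
import pytest

from patchforage import (
    GroupModel,
    PriorBox,
    SimulationSettings,
    dataset_pairs,
    log_bayes_factor,
    log_marginal_likelihood,
    log_posterior,
    map_estimate,
    pair_loglik_none,
    relative_error,
    simulate_dataset,
)
from patchforage.inference import MODEL_CLASSES, SearchSpec


@pytest.fixture(scope="module")
def nc_data(env):
    m = GroupModel.symmetric("none", 2, -1.5, 0.0, 1.0, env)
    df = simulate_dataset(m, SimulationSettings(dt=0.005, t_max=300,
                                                n_trials=300, seed=71))
    return dataset_pairs(df)


class TestPriorBox:
    def test_defaults_match_reference_ranges(self):
        p = PriorBox()
        assert p.theta_range == (-5.0, -0.1)
        assert p.kappa_range == (0.1, 6.0)
        assert p.b_range == (0.1, 4.0)

    def test_volume_excludes_kappa_for_nc(self):
        p = PriorBox()
        assert p.log_volume("none") < p.log_volume("diffusive")

    def test_entirely_negative_theta_required(self):
        with pytest.raises(ValueError):
            PriorBox(theta_range=(-1.0, 0.5))

    def test_sampling_stays_in_box(self, rng):
        p = PriorBox()
        for cls in MODEL_CLASSES:
            s = p.sample(rng, cls)
            assert p.contains(s["theta"], s["kappa"], s["b"], cls)


class TestLogPosterior:
    def test_outside_prior_is_minus_inf(self, env, nc_data):
        p = PriorBox()
        assert log_posterior(nc_data, -9.0, None, 1.0, "none", p, env) == -math.inf
        assert log_posterior(nc_data, -1.0, None, 9.0, "none", p, env) == -math.inf

    def test_single_observation_equals_pair_loglik_plus_prior(self, env):
        p = PriorBox()
        single = (np.array([2.0]), np.array([4.0]), np.array([False]))
        lp = log_posterior(single, -1.5, None, 1.0, "none", p, env,
                           data_resolution=0.005)
        pair = pair_loglik_none(2.0, 4.0, -1.5, 1.0, env)
        assert lp == pytest.approx(
            pair + 2 * math.log(0.005) - p.log_volume("none")
        )

    def test_empty_dataset_rejected(self, env):
        with pytest.raises(ValueError):
            log_posterior((np.array([]), np.array([]), None), -1.0, None, 1.0,
                          "none", PriorBox(), env)


class TestRelativeError:
    def test_exact_estimate_is_zero(self):
        t = {"theta": -1.0, "b": 1.0, "kappa": 2.0}
        assert relative_error(t, t, "pulsatile") == 0.0

    def test_doubled_theta_gives_one_third(self):
        truth = {"theta": -1.0, "b": 1.0, "kappa": 2.0}
        est = {"theta": -2.0, "b": 1.0, "kappa": 2.0}
        assert relative_error(est, truth, "diffusive") == pytest.approx(1 / 3)

    def test_nc_two_term_analogue(self):
        truth = {"theta": -1.0, "b": 1.0}
        est = {"theta": -1.0, "b": 1.5}
        assert relative_error(est, truth, "none") == pytest.approx(0.25)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            relative_error({"theta": -1.0, "b": 1.0}, {"theta": -1.0, "b": 0.0},
                           "none")

    def test_joint_rescaling_invariance(self):
        truth = {"theta": -1.2, "b": 0.8, "kappa": 2.0}
        est = {"theta": -1.5, "b": 1.0, "kappa": 1.5}
        scaled_t = {k: 3 * v for k, v in truth.items()}
        scaled_e = {k: 3 * v for k, v in est.items()}
        assert relative_error(est, truth, "pulsatile") == pytest.approx(
            relative_error(scaled_e, scaled_t, "pulsatile")
        )


class TestMapEstimate:
    def test_deterministic_on_identical_datasets(self, env, nc_data):
        p = PriorBox()
        a = map_estimate(nc_data, "none", p, env=env)
        b = map_estimate(nc_data, "none", p, env=env)
        assert a.estimate == b.estimate
        assert a.log_posterior == b.log_posterior

    def test_recovers_generating_parameters(self, env, nc_data):
        fit = map_estimate(nc_data, "none", PriorBox(), env=env)
        assert fit.theta == pytest.approx(-1.5, abs=0.45)
        assert fit.noise_scale == pytest.approx(1.0, abs=0.45)
        assert fit.kappa is None

    def test_estimate_stays_in_prior_box(self, env, nc_data):
        p = PriorBox()
        fit = map_estimate(nc_data, "none", p, env=env)
        assert p.contains(fit.theta, fit.kappa, fit.noise_scale, "none")

    def test_unknown_class_rejected(self, env, nc_data):
        with pytest.raises(ValueError):
            map_estimate(nc_data, "psychic", PriorBox(), env=env)


class TestMarginalsAndBayesFactors:
    def test_single_prior_sample_reduces_to_its_loglik(self, env, nc_data):
        p = PriorBox()
        sample = {"theta": -1.5, "kappa": None, "b": 1.0}
        lm, se = log_marginal_likelihood(nc_data, "none", p,
                                         prior_samples=[sample], env=env)
        from patchforage import dataset_loglik

        t1, t2, tie = nc_data
        expected = dataset_loglik(t1, t2, tie, "none", -1.5, 0.0, 1.0, env)
        assert lm == pytest.approx(expected)

    def test_too_few_samples_rejected(self, env, nc_data):
        with pytest.raises(ValueError):
            log_marginal_likelihood(nc_data, "none", PriorBox(),
                                    n_prior_samples=1, env=env)

    def test_self_comparison_is_exactly_zero(self, env, nc_data):
        bf = log_bayes_factor(nc_data, "none", "none", PriorBox(), seed=3,
                              n_prior_samples=8, env=env)
        assert bf == 0.0

    def test_antisymmetry(self, env, nc_data):
        kw = dict(prior=PriorBox(), seed=3, n_prior_samples=8, env=env)
        ab = log_bayes_factor(nc_data, "none", "pulsatile", **kw)
        ba = log_bayes_factor(nc_data, "pulsatile", "none", **kw)
        assert ab == pytest.approx(-ba)

    def test_nc_data_favors_nc_over_pulsatile(self, env, nc_data):
        bf = log_bayes_factor(nc_data, "none", "pulsatile", PriorBox(), seed=3,
                              n_prior_samples=48, env=env)
        assert bf > 0

    def test_stderr_decreases_with_samples(self, env, nc_data):
        p = PriorBox()
        _, se_small = log_marginal_likelihood(nc_data, "none", p,
                                              n_prior_samples=8, seed=1, env=env)
        _, se_large = log_marginal_likelihood(nc_data, "none", p,
                                              n_prior_samples=128, seed=1, env=env)
        assert se_large < se_small
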