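"""Weight formulas, the MCMC conflict-model fit, and its deterministic oracle."""

import numpy as np
import pytest

from avcue.conflict_model import (
    McmcConfig,
    credible_interval,
    fit_conflict_model,
    fit_switching_model,
    least_squares_oracle,
    optimal_weight,
    suboptimal_insensitive_weight,
)
from conftest import make_conflict_data, make_switching_data

# reduced schedule for unit tests; the default schedule is exercised in the
# acceptance suite
FAST = McmcConfig(burn_in=400, n_samples=1200, thin=2, seed=11)


class TestWeightFormulas:
    def test_equal_variances_give_half(self):
        assert optimal_weight(0.004, 0.004) == 0.5

    def test_three_to_one_ratio(self):
        assert optimal_weight(1.0, 3.0) == pytest.approx(0.75)

    def test_noiseless_visual_cue_gets_full_weight(self):
        assert optimal_weight(0.0, 0.003) == 1.0

    def test_strictly_decreasing_in_visual_variance(self):
        variances = np.linspace(0.0001, 0.02, 50)
        weights = [optimal_weight(v, 0.005) for v in variances]
        assert all(a > b for a, b in zip(weights, weights[1:]))
        assert all(0 < w < 1 for w in weights)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            optimal_weight(0.0, 0.0)

    def test_insensitive_weight_exceeds_optimal(self):
        sigma_l2, sigmaE2, sigma_a2 = 0.0016, 0.0036, 0.005
        w_sub = suboptimal_insensitive_weight(sigma_l2, sigma_a2)
        w_opt = optimal_weight(sigma_l2 + sigmaE2, sigma_a2)
        assert w_sub > w_opt
        assert w_sub == pytest.approx(0.005 / 0.0066)

    def test_printed_example(self):
        assert suboptimal_insensitive_weight(0.001, 0.003) == pytest.approx(0.75)


class TestLeastSquaresOracle:
    def test_noiseless_exact_recovery(self):
        x_v, x_a, r = make_conflict_data(100, w_p=0.25, w_v=0.6, sigma_n=0.0, seed=1)
        est = least_squares_oracle((x_v, x_a, r))
        assert est["w_p"] == pytest.approx(0.25, abs=1e-10)
        assert est["w_v"] == pytest.approx(0.6, abs=1e-10)
        assert est["sigma_n"] == pytest.approx(0.0, abs=1e-10)

    def test_label_swap_symmetry(self):
        x_v, x_a, r = make_conflict_data(150, w_p=0.2, w_v=0.7, sigma_n=0.02, seed=2)
        est = least_squares_oracle((x_v, x_a, r))
        swapped = least_squares_oracle((x_a, x_v, r))
        assert swapped["w_v"] == pytest.approx(1 - est["w_v"], abs=1e-10)
        assert swapped["w_p"] == pytest.approx(est["w_p"], abs=1e-10)

    def test_rank_deficiency_error(self):
        x = np.full(20, 0.5)
        with pytest.raises(ValueError):
            least_squares_oracle((x, x + 0.1, x))


@pytest.fixture(scope="module")
def fitted():
    x_v, x_a, r = make_conflict_data(200, w_p=0.2, w_v=0.7, sigma_n=0.02, seed=5)
    fit = fit_conflict_model((x_v, x_a, r), FAST)
    return (x_v, x_a, r), fit


class TestConflictModelFit:
    def test_posterior_means_near_truth(self):
        # average over replicate datasets so the check isolates sampler bias
        # from single-dataset sampling noise
        est = {"w_p": [], "w_v": [], "sigma_n": []}
        for seed in range(50, 54):
            data = make_conflict_data(200, w_p=0.2, w_v=0.7, sigma_n=0.02, seed=seed)
            fit = fit_conflict_model(data, FAST)
            for k, v in fit.point_estimates.items():
                est[k].append(v)
        assert np.mean(est["w_v"]) == pytest.approx(0.7, abs=0.05)
        assert np.mean(est["w_p"]) == pytest.approx(0.2, abs=0.05)
        assert np.mean(est["sigma_n"]) == pytest.approx(0.02, abs=0.01)

    def test_agrees_with_least_squares(self, fitted):
        data, fit = fitted
        ls = least_squares_oracle(data)
        for name in ("w_p", "w_v", "sigma_n"):
            assert abs(fit.point_estimates[name] - ls[name]) < 3 * fit.posterior_sd[name]

    def test_draws_respect_prior_supports(self, fitted):
        _, fit = fitted
        for name, (lo, hi) in (("w_p", (0, 1)), ("w_v", (0, 1)),
                               ("sigma_n", FAST.sigma_prior)):
            flat = fit.flat(name)
            assert flat.min() >= lo and flat.max() <= hi

    def test_convergence_diagnostic_reported(self, fitted):
        _, fit = fitted
        assert set(fit.rhat) == {"w_p", "w_v", "sigma_n"}
        assert fit.converged
        assert all(v < 1.05 for v in fit.rhat.values())

    def test_draw_shape_follows_schedule(self, fitted):
        _, fit = fitted
        assert fit.draws["w_v"].shape == (FAST.n_chains, FAST.n_samples)

    def test_degenerate_center_responses_push_wp_to_one(self):
        rng = np.random.default_rng(3)
        x_v = rng.choice([0.37, 0.43, 0.57, 0.63], 100)
        x_a = np.where(x_v < 0.5, x_v + 0.2, x_v - 0.2)
        r = np.full(100, 0.5)
        fit = fit_conflict_model((x_v, x_a, r), FAST)
        assert fit.point_estimates["w_p"] > 0.9

    def test_too_few_trials_error(self):
        x_v, x_a, r = make_conflict_data(8, 0.2, 0.7, 0.02, seed=1)
        with pytest.raises(ValueError, match="at least 10"):
            fit_conflict_model((x_v, x_a, r), FAST)

    def test_same_seed_reproduces_fit(self):
        data = make_conflict_data(50, 0.2, 0.6, 0.03, seed=9)
        a = fit_conflict_model(data, McmcConfig(burn_in=100, n_samples=200, thin=2, seed=4))
        b = fit_conflict_model(data, McmcConfig(burn_in=100, n_samples=200, thin=2, seed=4))
        assert a.point_estimates == b.point_estimates


class TestSwitchingModel:
    def test_pure_averaging_gives_low_p_switch(self):
        data = make_conflict_data(300, 0.15, 0.6, 0.02, seed=21)
        fit = fit_switching_model(data, FAST)
        assert fit.point_estimates["p_switch"] < 0.2

    def test_pure_switching_gives_high_p_switch(self):
        data = make_switching_data(300, 0.15, 0.6, 0.02, p_switch=1.0, seed=22)
        fit = fit_switching_model(data, FAST)
        assert fit.point_estimates["p_switch"] > 0.8

    def test_p_switch_draws_in_unit_interval(self):
        data = make_switching_data(100, 0.1, 0.5, 0.03, p_switch=0.5, seed=23)
        fit = fit_switching_model(data, McmcConfig(burn_in=200, n_samples=300, thin=2, seed=6))
        flat = fit.flat("p_switch")
        assert flat.min() >= 0 and flat.max() <= 1


class TestCredibleInterval:
    def test_level_validation(self):
        data = make_conflict_data(50, 0.2, 0.6, 0.03, seed=9)
        fit = fit_conflict_model(data, McmcConfig(burn_in=100, n_samples=200, thin=2, seed=4))
        with pytest.raises(ValueError):
            credible_interval(fit, level=1.5)

    def test_interval_contains_stated_mass(self):
        data = make_conflict_data(200, 0.2, 0.7, 0.02, seed=5)
        fit = fit_conflict_model(data, FAST)
        ci = credible_interval(fit, 0.95)["w_v"]
        flat = fit.flat("w_v")
        inside = np.mean((flat >= ci.lower) & (flat <= ci.upper))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_reference_exclusion(self):
        data = make_conflict_data(400, w_p=0.1, w_v=0.6, sigma_n=0.02, seed=31)
        fit = fit_conflict_model(data, FAST)
        cis = credible_interval(fit, 0.95, references={"w_v": 1.0})
        assert cis["w_v"].reference_excluded is True
        cis2 = credible_interval(fit, 0.95,
                                 references={"w_v": fit.point_estimates["w_v"]})
        assert cis2["w_v"].reference_excluded is False


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        McmcConfig(n_chains=0)
    with pytest.raises(ValueError):
        McmcConfig(sigma_prior=(0.2, 0.001))
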