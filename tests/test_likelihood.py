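"""Binned log-likelihood and ML fitting: hand-computed values, grid-search
oracle agreement, likelihood dominance, degenerate inputs."""

import numpy as np
import pytest

from coversad import (
    ClassCounts,
    FitOptions,
    bin_cover_values,
    fit_model,
    get_model,
    initial_values,
    log_likelihood,
    pareto_fixed_xm,
    simulate_community,
)

from conftest import grid_search_1param


def counts_from(londo, per_class: dict[int, int]) -> ClassCounts:
    c = np.zeros(londo.n_classes, dtype=int)
    for idx, n in per_class.items():
        c[idx] = n
    return ClassCounts(londo, c)


class TestLogLikelihood:
    def test_all_zero_counts_gives_zero(self, londo):
        assert log_likelihood(counts_from(londo, {}), get_model("exp"), [50.0]) == 0.0

    def test_closed_form_two_class_example(self, londo):
        # 2 species in (0, 0.01], 1 in (0.01, 0.03] under exponential rate 100:
        # 2 ln(1 - e^-1) + 1 ln(e^-1 - e^-3)
        cc = counts_from(londo, {0: 2, 1: 1})
        expected = 2 * np.log(1 - np.exp(-1)) + np.log(np.exp(-1) - np.exp(-3))
        assert log_likelihood(cc, get_model("exp"), [100.0]) == pytest.approx(
            expected, abs=1e-12
        )

    def test_single_species_half_probability_class(self, londo):
        # exponential with rate ln(2)/0.01 puts mass 1/2 on the first class
        rate = np.log(2) / 0.01
        cc = counts_from(londo, {0: 1})
        assert log_likelihood(cc, get_model("exp"), [rate]) == pytest.approx(
            np.log(0.5), abs=1e-12
        )

    def test_zero_probability_occupied_class_is_minus_inf(self, londo):
        cc = counts_from(londo, {0: 3})  # below Pareto support x_m = 0.02
        ll = log_likelihood(cc, get_model("pareto", xm=0.02), [1.0])
        assert ll == -np.inf

    def test_loglik_never_positive(self, londo):
        cc = counts_from(londo, {0: 5, 3: 2, 8: 1})
        for name, theta in [("exp", [60.0]), ("weibull", [1.2, 0.05])]:
            assert log_likelihood(cc, get_model(name), theta) <= 0


class TestInitialValues:
    def test_exponential_inverse_mean_midpoint(self, londo):
        cc = counts_from(londo, {0: 7})  # all species at midpoint 0.005
        assert initial_values(cc, get_model("exp"))[0] == pytest.approx(200.0)

    def test_weibull_starts_at_shape_one(self, londo):
        cc = counts_from(londo, {0: 3, 4: 2})
        theta0 = initial_values(cc, get_model("weibull"))
        assert theta0[0] == 1.0

    def test_gamma_moment_match_on_two_midpoints(self, londo):
        # equal weight on midpoints 0.02 and 0.075: hand moment computation
        cc = counts_from(londo, {1: 5, 3: 5})
        mean = (0.02 + 0.075) / 2
        var = ((0.02 - mean) ** 2 + (0.075 - mean) ** 2) / 2
        alpha0, beta0 = initial_values(cc, get_model("gamma"))
        assert alpha0 == pytest.approx(mean**2 / var)
        assert beta0 == pytest.approx(mean / var)

    def test_empty_counts_raise(self, londo):
        with pytest.raises(ValueError, match="S = 0"):
            initial_values(counts_from(londo, {}), get_model("exp"))

    def test_pareto_fixed_xm_conventions(self, londo):
        assert pareto_fixed_xm(counts_from(londo, {1: 3})) == pytest.approx(0.01)
        # class 1 occupied (lower limit 0): first positive breakpoint
        assert pareto_fixed_xm(counts_from(londo, {0: 2, 3: 1})) == pytest.approx(0.01)
        assert pareto_fixed_xm(counts_from(londo, {4: 1})) == pytest.approx(0.10)


class TestFitModel:
    def test_exponential_recovery_and_grid_oracle(self, londo):
        sample = simulate_community("exponential", [50.0], 500, londo, seed=7)
        fit = fit_model(sample.counts, get_model("exp"))
        assert fit.converged
        assert abs(fit.theta_hat[0] - 50) / 50 < 0.15
        _, ll_grid = grid_search_1param(sample.counts, get_model("exp"))
        assert fit.loglik >= ll_grid - 1e-4

    def test_weibull_dominates_nested_exponential(self, londo):
        sample = simulate_community("exponential", [50.0], 500, londo, seed=7)
        ll_exp = fit_model(sample.counts, get_model("exp")).loglik
        ll_wei = fit_model(sample.counts, get_model("weibull")).loglik
        assert ll_wei >= ll_exp - 1e-6

    @pytest.mark.parametrize("name", ["exp", "gamma", "lognormal", "weibull"])
    def test_fit_dominates_starting_values(self, londo, name):
        sample = simulate_community("lognormal", [-3.5, 1.0], 200, londo, seed=11)
        model = get_model(name)
        fit = fit_model(sample.counts, model)
        ll0 = log_likelihood(sample.counts, model, initial_values(sample.counts, model))
        assert fit.loglik >= ll0 - 1e-9

    def test_single_occupied_class_flagged_divergent(self, londo):
        cc = ClassCounts(londo, np.eye(14, dtype=int)[0] * 20)
        fit = fit_model(cc, get_model("exp"))
        assert not fit.converged
        assert "boundary" in fit.message or not np.isfinite(fit.aicc)

    def test_empty_counts_raise(self, londo):
        with pytest.raises(ValueError, match="S = 0"):
            fit_model(ClassCounts(londo, np.zeros(14, dtype=int)), get_model("exp"))

    def test_reported_fields_consistent(self, londo):
        sample = simulate_community("gamma", [1.5, 40.0], 300, londo, seed=3)
        fit = fit_model(sample.counts, get_model("gamma"))
        assert fit.k == 2 and fit.n == 300
        assert fit.loglik <= 0
        assert np.all(fit.se > 0)
        assert fit.params.keys() == {"shape", "rate"}

    def test_deterministic_given_options_seed(self, londo):
        sample = simulate_community("weibull", [1.4, 0.08], 150, londo, seed=5)
        f1 = fit_model(sample.counts, get_model("weibull"), FitOptions(seed=9))
        f2 = fit_model(sample.counts, get_model("weibull"), FitOptions(seed=9))
        assert np.array_equal(f1.theta_hat, f2.theta_hat)


def test_weibull_shape_ci_covers_one_under_exponential_truth(londo):
    """Fitting Weibull to exponential data: the 2-SE interval around the
    fitted shape should cover 1 in at least 80% of replicates."""
    hits = total = 0
    for seed in range(100):
        sample = simulate_community("exponential", [60.0], 200, londo, seed=seed)
        fit = fit_model(sample.counts, get_model("weibull"))
        if not fit.converged or not np.isfinite(fit.se[0]):
            continue
        total += 1
        phi, se = fit.theta_hat[0], fit.se[0]
        hits += phi - 2 * se <= 1.0 <= phi + 2 * se
    assert total >= 90
    assert hits / total >= 0.80
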