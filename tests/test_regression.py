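"""Likelihood, priors, posterior sampling and the hurdle MLE."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from microzinb import (
    ModelSpec,
    RegressionParams,
    fit_hurdle_mle,
    fit_variant,
    log_prior,
    sample_posterior,
    zinb_loglik,
)
from microzinb.simulate import ScenarioConfig, simulate_counts, simulate_scenario

from conftest import make_tau_link_data


def _tau_link_loglik_oracle(beta, tau, theta, B, y):
    """Independent per-observation oracle: scipy NB pmf + explicit mixture."""
    mu = np.exp(B @ beta)
    phi = special.expit(-tau * np.log(mu))
    p = theta / (theta + mu)
    total = 0.0
    for yi, mi, pi, fi in zip(y, mu, p, phi):
        if yi == 0:
            total += np.log(fi + (1 - fi) * stats.nbinom.pmf(0, theta, pi))
        else:
            total += np.log1p(-fi) + stats.nbinom.logpmf(yi, theta, pi)
    return total


class TestLoglik:
    def test_matches_per_observation_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n, p = 20, 3
            B = np.column_stack([np.ones(n), rng.normal(0, 0.5, (n, p - 1))])
            beta = rng.normal(0, 0.7, p)
            tau, theta = rng.uniform(0.3, 2.0), rng.uniform(0.5, 3.0)
            y = rng.poisson(5.0, n)
            params = RegressionParams(beta=beta, theta=theta, tau=tau)
            assert zinb_loglik(params, B, y) == pytest.approx(
                _tau_link_loglik_oracle(beta, tau, theta, B, y), abs=1e-8
            )

    def test_empty_response_gives_zero(self):
        params = RegressionParams(beta=[0.0], theta=1.0, tau=1.0)
        assert zinb_loglik(params, np.empty((0, 1)), np.array([], dtype=int)) == 0.0

    def test_large_theta_approaches_zip(self):
        rng = np.random.default_rng(3)
        n = 25
        B = np.column_stack([np.ones(n), rng.normal(0, 0.4, n)])
        beta = np.array([1.2, 0.5])
        tau = 0.8
        y = rng.poisson(4.0, n)
        ll = zinb_loglik(RegressionParams(beta=beta, theta=1e8, tau=tau), B, y)
        mu = np.exp(B @ beta)
        phi = special.expit(-tau * np.log(mu))
        zip_ll = sum(
            np.log(f + (1 - f) * np.exp(-m)) if yi == 0
            else np.log1p(-f) + stats.poisson.logpmf(yi, m)
            for yi, m, f in zip(y, mu, phi)
        )
        assert ll == pytest.approx(zip_ll, abs=1e-4)

    def test_dimension_mismatch(self):
        params = RegressionParams(beta=[0.0, 0.0], theta=1.0, tau=1.0)
        with pytest.raises(ValueError):
            zinb_loglik(params, np.ones((5, 2)), np.zeros(4, dtype=int))


class TestLogPrior:
    spec = ModelSpec()

    def test_gamma_closed_form_on_theta(self):
        a = b = 0.001
        expected_gamma = a * np.log(b) - special.gammaln(a) + (a - 1) * np.log(1.0) - b * 1.0
        got = log_prior(RegressionParams(beta=[], theta=1.0), self.spec)
        assert got == pytest.approx(expected_gamma, abs=1e-10)

    def test_beta_prior_peaks_at_zero(self):
        at0 = log_prior(RegressionParams(beta=[0.0]), self.spec)
        off = log_prior(RegressionParams(beta=[2.0]), self.spec)
        assert at0 > off

    def test_additivity(self):
        full = log_prior(RegressionParams(beta=[0.3, -1.0], theta=2.0, tau=0.5), self.spec)
        parts = (
            log_prior(RegressionParams(beta=[0.3]), self.spec)
            + log_prior(RegressionParams(beta=[-1.0]), self.spec)
            + log_prior(RegressionParams(beta=[], theta=2.0), self.spec)
            + log_prior(RegressionParams(beta=[], tau=0.5), self.spec)
        )
        assert full == pytest.approx(parts, abs=1e-10)

    def test_nonpositive_shape_parameters_give_minus_inf(self):
        assert log_prior(RegressionParams(beta=[], theta=-1.0), self.spec) == -np.inf
        assert log_prior(RegressionParams(beta=[], tau=0.0), self.spec) == -np.inf


class TestSamplePosterior:
    def test_seed_reproducibility(self, fast_spec):
        data = make_tau_link_data(100, seed=5)
        f1 = sample_posterior(fast_spec, data["B"], data["y"])
        f2 = sample_posterior(fast_spec, data["B"], data["y"])
        pd.testing.assert_frame_equal(f1.summary, f2.summary)

    def test_all_zero_response_is_a_structural_error(self, fast_spec):
        B = np.column_stack([np.ones(30), np.random.default_rng(0).normal(size=30)])
        with pytest.raises(ValueError, match="all zeros"):
            sample_posterior(fast_spec, B, np.zeros(30, dtype=int))

    def test_too_few_observations(self, fast_spec):
        B = np.ones((3, 2))
        with pytest.raises(ValueError):
            sample_posterior(fast_spec, B, np.array([1, 0, 2]))

    def test_quantile_ordering(self, fast_spec):
        data = make_tau_link_data(100, seed=6)
        fit = sample_posterior(fast_spec, data["B"], data["y"])
        if not fit.failed:
            assert (fit.summary["q2.5"] <= fit.summary["q97.5"]).all()


class TestVariants:
    def test_unknown_variant_lists_valid_names(self):
        with pytest.raises(ValueError, match="ZINB_tau"):
            fit_variant("ZINB_gibberish", np.ones((10, 1)), np.ones(10, dtype=int))

    def test_invalid_modelspec_schedule(self):
        with pytest.raises(ValueError):
            ModelSpec(adapt=0)

    def test_poisson_and_nb_agree_under_the_null(self, fast_spec):
        # pure Poisson data: both models are consistent for beta
        scen = ScenarioConfig(n=400, effect_level=0.5, phi=0.0, inv_theta=0.0, seed=21)
        sim = simulate_scenario(scen)
        truth = sim["beta"][1:]
        errs = {}
        for v in ("P", "NB"):
            fit = fit_variant(v, sim["B"], sim["y"], fast_spec, param_names=sim["names"])
            assert not fit.failed
            est = fit.beta.reindex(sim["names"][1:]).to_numpy()
            errs[v] = np.median(np.abs(est - truth) / np.abs(truth))
        assert errs["P"] < 0.25 and errs["NB"] < 0.25

    def test_free_intercept_link_detects_absence_of_extra_zeros(self, fast_spec):
        # phi_true = 0: the zero-model intercept should sit at a large negative logit
        scen = ScenarioConfig(n=400, effect_level=0.5, phi=0.0, inv_theta=0.5, seed=22)
        sim = simulate_scenario(scen)
        fit = fit_variant("ZINB_inter", sim["B"], sim["y"], fast_spec, param_names=sim["names"])
        assert not fit.failed
        theta0 = float(fit.summary.set_index("parameter").loc["theta0", "mean"])
        assert theta0 < -1.0

    def test_nb_intercept_biased_low_under_ignored_zero_inflation(self):
        # phi = 0.5 of the counts zeroed out: NB treats them as real -> intercept shrinks
        scen = ScenarioConfig(n=400, effect_level=0.5, phi=0.5, inv_theta=1.0, seed=23)
        sim = simulate_scenario(scen, zero_mech="intercept")
        spec = ModelSpec(seed=23)
        nb = fit_variant("NB", sim["B"], sim["y"], spec, param_names=sim["names"])
        zinb = fit_variant("ZINB_inter", sim["B"], sim["y"], spec, param_names=sim["names"])
        assert not nb.failed and not zinb.failed
        assert nb.beta["intercept"] < zinb.beta["intercept"] - 0.2


class TestHurdle:
    def test_intercept_only_zero_model_matches_zero_fraction(self):
        rng = np.random.default_rng(9)
        n = 400
        B = np.ones((n, 1))
        y = rng.poisson(1.0, n)
        fit = fit_hurdle_mle(B, y, zero_design=np.ones((n, 1)))
        gamma0 = float(fit.summary.set_index("parameter").loc["gamma:0", "mean"])
        phi_hat = special.expit(-gamma0)  # logit(phi) = -(G gamma)
        assert phi_hat == pytest.approx(float(np.mean(y == 0)), abs=1e-6)

    def test_coefficient_recovery_within_three_standard_errors(self):
        scen = ScenarioConfig(n=1000, effect_level=1.0, phi=0.3, inv_theta=1.0, seed=11)
        sim = simulate_scenario(scen, zero_mech="covariate")
        fit = fit_hurdle_mle(sim["B"], sim["y"], param_names=sim["names"])
        assert not fit.failed
        s = fit.summary.set_index("parameter")
        for j, nm in enumerate(sim["names"]):
            row = s.loc[f"beta:{nm}"]
            assert abs(row["mean"] - sim["beta"][j]) < 3 * row["sd"]

    def test_degenerate_parts_are_named_errors(self):
        B = np.ones((20, 1))
        with pytest.raises(ValueError, match="zero part"):
            fit_hurdle_mle(B, np.arange(1, 21))
        with pytest.raises(ValueError, match="count part"):
            fit_hurdle_mle(B, np.zeros(20, dtype=int))
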