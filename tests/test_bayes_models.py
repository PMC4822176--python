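import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from ppscct.bayes_models import (
    HypothesisSpec,
    LinearModelParams,
    LogitModelParams,
    OrdinalProblem,
    Prior,
    RegressionProblem,
    analytic_log_marginal_normal,
    category_probabilities,
    loglik_linear,
    loglik_ordinal_logit,
    ordinal_problem_from_table,
    sample_posterior_linear,
    sample_posterior_logit,
    split_rhat,
)
from ppscct.product_space import MCMCConfig, mc_se


class TestLoglikLinear:
    def test_standard_normal_at_zero(self):
        data = pd.DataFrame({"condition": ["c"], "d_ms": [0.0]})
        params = LinearModelParams(mu={"c": 0.0}, tau_ms=0.0, sigma_ms=1.0)
        assert loglik_linear(data, params) == pytest.approx(
            -0.5 * math.log(2 * math.pi))

    def test_translation_invariance(self, rng):
        y = rng.normal(10, 20, size=12)
        params = LinearModelParams(mu={"c": 5.0}, tau_ms=8.0, sigma_ms=15.0)
        shifted = LinearModelParams(mu={"c": 105.0}, tau_ms=8.0,
                                    sigma_ms=15.0)
        d1 = pd.DataFrame({"condition": "c", "d_ms": y,
                           "participant_id": np.arange(12) % 4})
        d2 = d1.assign(d_ms=y + 100.0)
        assert loglik_linear(d1, params) == pytest.approx(
            loglik_linear(d2, shifted), abs=1e-9)

    def test_matches_quadrature_oracle(self, rng):
        """3 participants x 2 observations vs fine-grid integration over
        each participant effect."""
        tau, sigma, mu = 12.0, 18.0, 30.0
        y = rng.normal(mu, 20, size=6)
        data = pd.DataFrame({
            "participant_id": ["a", "a", "b", "b", "c", "c"],
            "condition": "c", "d_ms": y})
        params = LinearModelParams(mu={"c": mu}, tau_ms=tau, sigma_ms=sigma)

        total = 0.0
        for p in ("a", "b", "c"):
            yp = data[data.participant_id == p].d_ms.to_numpy()

            def integrand(b, yp=yp):
                lik = np.prod(stats.norm.pdf(yp, mu + b, sigma))
                return lik * stats.norm.pdf(b, 0, tau)

            val, _ = integrate.quad(integrand, -8 * tau, 8 * tau,
                                    limit=200)
            total += math.log(val)
        assert loglik_linear(data, params) == pytest.approx(total, abs=1e-6)

    def test_unimodality_along_mu(self):
        data = pd.DataFrame({"condition": "c", "d_ms": [40.0, 42.0, 38.0]})
        lls = [loglik_linear(
            data, LinearModelParams(mu={"c": m}, tau_ms=0.0, sigma_ms=10.0))
            for m in np.linspace(-50, 130, 37)]
        peak = int(np.argmax(lls))
        assert all(np.diff(lls[:peak + 1]) > 0)
        assert all(np.diff(lls[peak:]) < 0)

    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            LinearModelParams(mu={}, tau_ms=1.0, sigma_ms=0.0)
        with pytest.raises(ValueError):
            LinearModelParams(mu={}, tau_ms=-1.0, sigma_ms=1.0)


class TestAnalyticLogMarginal:
    def test_empty_product(self):
        assert analytic_log_marginal_normal(np.empty(0), 1.0, 0.0, 1.0) == 0.0

    def test_single_observation_convolution(self):
        y = 0.7
        lm = analytic_log_marginal_normal(np.array([y]), 1.0, 0.0, 1.0)
        assert lm == pytest.approx(stats.norm.logpdf(y, 0.0, math.sqrt(2)))

    def test_matches_quadrature(self, rng):
        y = rng.normal(20, 25, size=5)
        sigma, m0, s0 = 25.0, 10.0, 30.0

        def integrand(mu):
            return (np.prod(stats.norm.pdf(y, mu, sigma))
                    * stats.norm.pdf(mu, m0, s0))

        val, _ = integrate.quad(integrand, m0 - 10 * s0, m0 + 10 * s0,
                                limit=400, points=[float(y.mean())],
                                epsabs=1e-14, epsrel=1e-12)
        assert analytic_log_marginal_normal(y, sigma, m0, s0) \
            == pytest.approx(math.log(val), abs=1e-8)

    def test_validation(self):
        with pytest.raises(ValueError):
            analytic_log_marginal_normal(np.array([1.0]), 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            analytic_log_marginal_normal(np.array([1.0]), 1.0, 0.0, -1.0)


class TestSamplePosteriorLinear:
    def test_conjugate_normal_normal_closed_form(self, rng):
        """Known sigma, no hierarchy: posterior of mu has a textbook
        closed form."""
        sigma, m0, s0 = 20.0, 0.0, 30.0
        y = rng.normal(35, sigma, size=15)
        prob = RegressionProblem(y=y, columns={"mu": np.ones(y.size)},
                                 sigma=sigma)
        hyp = HypothesisSpec("m", {"mu": "eff"},
                             priors={"eff": Prior(m0, s0)})
        cfg = MCMCConfig(n_chains=2, burn_in=200, n_samples=3000)
        draws = sample_posterior_linear(prob, hyp, cfg, seed=1)
        pooled = draws.pooled("mu")

        prec = y.size / sigma ** 2 + 1.0 / s0 ** 2
        post_mean = (y.sum() / sigma ** 2 + m0 / s0 ** 2) / prec
        post_sd = 1.0 / math.sqrt(prec)
        se = 3 * mc_se(pooled, min_batches=20)
        assert abs(pooled.mean() - post_mean) < max(se, 3 * post_sd
                                                    / math.sqrt(pooled.size))
        assert abs(pooled.std(ddof=1) - post_sd) < 0.1 * post_sd

    def test_degenerate_prior_pins_mu(self, rng):
        y = rng.normal(50, 5, size=10)
        prob = RegressionProblem(y=y, columns={"mu": np.ones(10)}, sigma=5.0)
        hyp = HypothesisSpec("m", {"mu": "pin"},
                             priors={"pin": Prior(0.0, 1e-6)})
        draws = sample_posterior_linear(
            prob, hyp, MCMCConfig(n_chains=1, burn_in=100, n_samples=500),
            seed=2)
        assert np.max(np.abs(draws.pooled("mu"))) < 1e-3

    def test_prior_only_run_recovers_prior(self):
        """Detailed-balance smoke: no data -> draws follow the prior."""
        prob = RegressionProblem(y=np.empty(0),
                                 columns={"mu": np.empty(0)}, sigma=1.0)
        hyp = HypothesisSpec("m", {"mu": "eff"},
                             priors={"eff": Prior(40.0, 20.0)})
        draws = sample_posterior_linear(
            prob, hyp, MCMCConfig(n_chains=1, burn_in=100, n_samples=4000),
            seed=3)
        pooled = draws.pooled("mu")
        assert abs(pooled.mean() - 40.0) < 3 * 20.0 / math.sqrt(pooled.size)
        assert abs(pooled.std(ddof=1) - 20.0) < 1.5

    def test_rhat_reported(self, rng):
        y = rng.normal(0, 1, size=8)
        prob = RegressionProblem(y=y, columns={"mu": np.ones(8)}, sigma=1.0)
        hyp = HypothesisSpec("m", {"mu": "eff"},
                             priors={"eff": Prior(0.0, 10.0)})
        draws = sample_posterior_linear(
            prob, hyp, MCMCConfig(n_chains=2, burn_in=100, n_samples=400),
            seed=4)
        assert np.isfinite(draws.rhat["mu"])
        assert draws.rhat["mu"] < 1.05


class TestOrdinalLogit:
    def test_probabilities_sum_to_one(self, rng):
        etas = rng.normal(0, 3, size=1000)
        p = category_probabilities(etas)
        assert np.max(np.abs(p.sum(axis=-1) - 1.0)) < 1e-12

    def test_zero_coefficients_symmetric(self):
        p = category_probabilities(0.0)[0]
        assert np.allclose(p, p[::-1], atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_large_coefficient_concentrates_on_top_category(self):
        p = category_probabilities(40.0)[0]
        assert p[-1] > 1 - 1e-10

    def test_loglik_matches_brute_force(self, rng):
        scores = rng.integers(1, 11, size=30)
        cells = rng.choice(["a", "b"], size=30)
        table = pd.DataFrame({"condition": cells, "time": "before",
                              "score": scores})
        coef = {"a:before": 0.8, "b:before": -1.1}
        params = LogitModelParams(coef=coef)
        ll = loglik_ordinal_logit(table, params)

        # brute force: cumulative-logistic arithmetic per observation
        cuts = np.arange(1, 10) - 5.0
        expected = 0.0
        for s, c in zip(scores, cells):
            eta = coef[f"{c}:before"]
            cdf = np.concatenate([[0.0],
                                  1 / (1 + np.exp(-(cuts - eta))), [1.0]])
            expected += math.log(cdf[s] - cdf[s - 1])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1..10"):
            OrdinalProblem(scores=np.array([0]), columns={"c": np.ones(1)})

    def test_nonfinite_coefficient_rejected(self):
        with pytest.raises(ValueError):
            LogitModelParams(coef={"c": math.inf})

    def test_posterior_direction_with_ceiling_data(self):
        table = pd.DataFrame({"condition": "real", "time": "before",
                              "score": [10] * 40,
                              "participant_id": list(range(8)) * 5})
        hyp = HypothesisSpec("h", {"real:before": "high"},
                             priors={"high": Prior(4.0, 2.0),
                                     "low": Prior(-4.0, 2.0)})
        draws = sample_posterior_logit(
            table, hyp, MCMCConfig(n_chains=1, burn_in=200, n_samples=800),
            seed=5)
        assert draws.pooled("real:before").mean() > -4.0
        assert draws.pooled("real:before").mean() > 2.0

    def test_posterior_symmetric_for_symmetric_data(self):
        scores = [1, 10, 2, 9, 3, 8, 4, 7, 5, 6] * 6
        table = pd.DataFrame({"condition": "c", "time": "t",
                              "score": scores})
        hyp = HypothesisSpec("h", {"c:t": "sym"},
                             priors={"sym": Prior(0.0, 2.0)})
        draws = sample_posterior_logit(
            table, hyp, MCMCConfig(n_chains=2, burn_in=300, n_samples=2000),
            seed=6)
        pooled = draws.pooled("c:t")
        assert abs(pooled.mean()) < 3 * mc_se(pooled, min_batches=20) + 0.05

    def test_parameter_recovery(self):
        """Data generated from known coefficients: posterior means land
        within 3 posterior SDs of truth."""
        rng = np.random.default_rng(7)
        true = {"a:t": 1.5, "b:t": -1.0}
        rows = []
        for cell, beta in true.items():
            cond = cell.split(":")[0]
            p = category_probabilities(beta)[0]
            draws = rng.choice(np.arange(1, 11), size=250, p=p)
            for s in draws:
                rows.append({"condition": cond, "time": "t",
                             "score": int(s)})
        table = pd.DataFrame(rows)
        hyp = HypothesisSpec("h", {"a:t": "sym", "b:t": "sym"},
                             priors={"sym": Prior(0.0, 3.0)})
        post = sample_posterior_logit(
            table, hyp, MCMCConfig(n_chains=2, burn_in=300, n_samples=1500),
            seed=8)
        for cell, beta in true.items():
            pooled = post.pooled(cell)
            assert abs(pooled.mean() - beta) < 3 * pooled.std(ddof=1)

    def test_prior_only_run_recovers_prior_mh(self):
        prob = OrdinalProblem(scores=np.empty(0, dtype=int),
                              columns={"c": np.empty(0)})
        hyp = HypothesisSpec("h", {"c": "high"},
                             priors={"high": Prior(4.0, 2.0)})
        draws = sample_posterior_logit(
            prob, hyp, MCMCConfig(n_chains=2, burn_in=500, n_samples=5000),
            seed=9)
        pooled = draws.pooled("c")
        se = mc_se(pooled, min_batches=20)
        assert abs(pooled.mean() - 4.0) < 3 * se
        assert abs(pooled.std(ddof=1) - 2.0) < 0.2


class TestSplitRhat:
    def test_identical_chains_near_one(self, rng):
        x = rng.normal(size=(3, 500))
        assert split_rhat(x) < 1.05

    def test_separated_chains_flagged(self, rng):
        x = rng.normal(size=(2, 500))
        x[1] += 10.0
        assert split_rhat(x) > 1.5

    def test_constant_series(self):
        assert split_rhat(np.ones((2, 100))) == 1.0
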