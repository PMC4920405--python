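"""MAP search, prior guards, adaptive Metropolis correctness, summaries."""

import numpy as np
import pytest

from guts import (
    ModelConfig,
    PosteriorSample,
    default_bounds,
    find_map,
    log_posterior,
    make_experiment,
    run_mcmc,
    summarise_posterior,
)
from guts.inference import hooke_jeeves_max, ram_sampler


class TestLogPosterior:
    def test_killing_rate_above_prior_bound_is_rejected(self, diazinon, diazinon_map):
        vec = diazinon_map.copy()
        vec[2] = 31.0
        assert log_posterior(vec, diazinon) == -np.inf

    def test_negative_parameter_is_rejected(self, diazinon, diazinon_map):
        vec = diazinon_map.copy()
        vec[0] = -1e-9
        assert log_posterior(vec, diazinon) == -np.inf

    def test_equals_log_likelihood_inside_the_box(self, diazinon, diazinon_map):
        from guts import total_log_likelihood

        cfg = ModelConfig(N=100, M=1000)
        assert log_posterior(diazinon_map, diazinon, config=cfg) == pytest.approx(
            total_log_likelihood(diazinon, diazinon_map, cfg).value)


class TestHookeJeeves:
    def test_finds_quadratic_maximum(self):
        target = np.array([0.3, 0.7, 0.1])
        x, fx, _ = hooke_jeeves_max(lambda x: -np.sum((x - target) ** 2),
                                    np.array([0.5, 0.5, 0.5]),
                                    np.zeros(3), np.ones(3))
        np.testing.assert_allclose(x, target, atol=1e-5)

    def test_respects_bounds(self):
        x, _, _ = hooke_jeeves_max(lambda x: x[0], np.array([0.5]),
                                   np.array([0.0]), np.array([2.0]))
        assert x[0] == pytest.approx(2.0, abs=1e-6)

    def test_ascent_property(self):
        f = lambda x: -((x[0] - 0.2) ** 2) - abs(x[1] - 0.4)
        start = np.array([0.9, 0.9])
        x, fx, _ = hooke_jeeves_max(f, start, np.zeros(2), np.ones(2))
        assert fx >= f(start)

    def test_infeasible_start_raises(self):
        with pytest.raises(ValueError, match="feasible"):
            hooke_jeeves_max(lambda x: -np.inf, np.array([0.5]),
                             np.array([0.0]), np.array([1.0]))

    def test_background_rate_recovered_from_background_only_data(self):
        # closed-form MLE of hb from exponential survival: deaths only from hb
        counts = [50, 40, 33, 27, 22, 18]
        times = [0.0, 1, 2, 3, 4, 5]
        exp = make_experiment([0, 0], [0, 5], counts, times)
        cfg = ModelConfig(N=50, M=200)
        x, _ = find_map([0.05, 0.1, 3.0, 20.0, 10.0], [exp], config=cfg)
        # y_i = 50 exp(-hb t_i) with hb = 0.2 roughly; MLE near ln-slope
        from scipy.optimize import minimize_scalar

        def nll(hb):
            S = np.exp(-hb * np.asarray(times))
            d = -np.diff(counts)
            return -(np.sum(d * np.log(S[:-1] - S[1:])) + counts[-1] * -hb * times[-1])

        hb_mle = minimize_scalar(nll, bounds=(0.01, 1.0), method="bounded").x
        assert x[0] == pytest.approx(hb_mle, rel=0.02)


class TestRamSampler:
    def test_recovers_known_gaussian_target(self):
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        prec = np.linalg.inv(cov)

        def logp(x):
            return -0.5 * x @ prec @ x

        draws, lps, acc = ram_sampler(logp, np.array([0.5, -0.5]), n_iter=40000,
                                      n_adapt=10000, target_accept=0.4, seed=3)
        kept = draws[10000:]
        assert abs(acc - 0.4) < 0.1
        np.testing.assert_allclose(kept.mean(axis=0), 0.0, atol=0.1)
        np.testing.assert_allclose(np.cov(kept.T), cov, atol=0.3)

    def test_infeasible_init_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            ram_sampler(lambda x: -np.inf, np.array([1.0]), n_iter=10, n_adapt=5)

    def test_same_seed_reproduces_chain(self, diazinon, diazinon_map):
        cfg = ModelConfig(N=50, M=500)
        a = run_mcmc(diazinon_map, diazinon, config=cfg, n_iter=300, n_adapt=100, seed=11)
        b = run_mcmc(diazinon_map, diazinon, config=cfg, n_iter=300, n_adapt=100, seed=11)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_retained_draws_satisfy_prior_bounds(self, diazinon, diazinon_map):
        cfg = ModelConfig(N=50, M=500)
        sample = run_mcmc(diazinon_map, diazinon, config=cfg, n_iter=500,
                          n_adapt=200, seed=4)
        bounds = default_bounds(cfg)
        assert np.all(sample.draws >= bounds.lower)
        assert np.all(sample.draws <= bounds.upper)
        assert np.all(np.isfinite(sample.logp))


class TestSummaries:
    def test_quantiles_of_constant_chain_collapse(self):
        draws = np.tile([1.0, 2.0], (100, 1))
        sample = PosteriorSample(draws=draws, logp=np.zeros(100),
                                 acceptance_rate=0.4, param_names=("a", "b"))
        summary = summarise_posterior(sample, burn_in=10)
        for col in ("maxpost", "q0.025", "q0.5", "q0.975"):
            np.testing.assert_array_equal(summary[col].to_numpy(), [1.0, 2.0])

    def test_maxpost_is_argmax_of_logp(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(50, 2))
        logp = rng.normal(size=50)
        sample = PosteriorSample(draws=draws, logp=logp, acceptance_rate=0.4,
                                 param_names=("a", "b"))
        summary = summarise_posterior(sample, burn_in=5)
        np.testing.assert_array_equal(summary["maxpost"].to_numpy(),
                                      draws[np.argmax(logp)])

    def test_quantile_ordering(self):
        rng = np.random.default_rng(1)
        sample = PosteriorSample(draws=rng.normal(size=(500, 3)),
                                 logp=rng.normal(size=500),
                                 acceptance_rate=0.4, param_names=("a", "b", "c"))
        s = summarise_posterior(sample, burn_in=100)
        assert np.all(s["q0.025"] <= s["q0.5"])
        assert np.all(s["q0.5"] <= s["q0.975"])

    def test_burn_in_beyond_chain_raises(self):
        sample = PosteriorSample(draws=np.zeros((10, 1)), logp=np.zeros(10),
                                 acceptance_rate=0.4, param_names=("a",))
        with pytest.raises(ValueError):
            summarise_posterior(sample, burn_in=10)
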