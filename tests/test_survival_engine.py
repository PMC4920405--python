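"""Fast survival recursion: threshold grids, invariants, limits, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from guts import (
    ModelConfig,
    ParameterSet,
    ValidationError,
    it_survival,
    make_experiment,
    survival_probabilities,
)
from guts.damage_kinetics import refine_time_grid
from guts.survival_engine import (
    delta_threshold,
    lognormal_mu_sigma,
    lognormal_threshold_grid,
    lognormal_threshold_sample,
)
from guts.reference_oracle import naive_survival_sum
from conftest import DIAZINON_MAP, random_instance


class TestThresholdGrids:
    def test_lognormal_parameters_at_diazinon_map(self):
        mn, sd = DIAZINON_MAP[3], DIAZINON_MAP[4]
        mu, sigma = lognormal_mu_sigma(mn, sd)
        assert sigma**2 == pytest.approx(np.log(1 + sd**2 / mn**2))
        assert sigma**2 == pytest.approx(0.1380, abs=5e-4)
        assert mu == pytest.approx(2.6805, abs=5e-4)

    def test_weight_is_maximal_at_the_log_mean(self):
        grid = lognormal_threshold_grid(15.0, 6.0, 1001)  # odd N puts a point at mu
        mu, _ = lognormal_mu_sigma(15.0, 6.0)
        j = np.argmin(np.abs(np.log(grid.z) - mu))
        assert grid.logw[j] == pytest.approx(0.0, abs=1e-20)
        assert np.all(grid.logw <= 0)

    def test_weighted_grid_mean_matches_lognormal_mean(self):
        mn, sd = 15.634, 6.011
        grid = lognormal_threshold_grid(mn, sd, 1000)
        w = np.exp(grid.logw)
        mean = np.sum(grid.z * w) / np.sum(w)
        assert mean == pytest.approx(mn, rel=1e-3)

    def test_grid_is_log_uniform_over_mu_pm_4_sigma(self):
        grid = lognormal_threshold_grid(20.0, 5.0, 100)
        x = np.log(grid.z)
        mu, sigma = lognormal_mu_sigma(20.0, 5.0)
        assert x[0] == pytest.approx(mu - 4 * sigma)
        assert x[-1] == pytest.approx(mu + 4 * sigma)
        np.testing.assert_allclose(np.diff(x), np.diff(x)[0], rtol=1e-9)

    def test_delta_threshold(self):
        grid = delta_threshold(20.0)
        np.testing.assert_array_equal(grid.z, [20.0])
        np.testing.assert_array_equal(grid.logw, [0.0])

    def test_improper_grid_parameters_raise(self):
        with pytest.raises(ValidationError):
            lognormal_threshold_grid(-1.0, 5.0, 10)
        with pytest.raises(ValidationError):
            delta_threshold(-2.0)


class TestSurvivalCurves:
    def test_zero_exposure_is_pure_background(self, diazinon):
        exp = make_experiment([0, 0], [0, 22], diazinon[0].survival.counts,
                              diazinon[0].survival.times)
        for cfg in (ModelConfig(N=100, M=500), ModelConfig(dist="delta", N=1, M=500),
                    ModelConfig(model="it", N=100, M=500)):
            p = ParameterSet(hb=0.07, ke=0.1, kk=2.0, mn=10.0, sd=4.0)
            S = survival_probabilities(exp, p, cfg).S
            np.testing.assert_allclose(S, np.exp(-0.07 * exp.survival.times), rtol=1e-12)

    def test_no_hazard_means_certain_survival(self, diazinon):
        p = ParameterSet(hb=0.0, ke=0.1, kk=0.0, mn=10.0, sd=4.0)
        S = survival_probabilities(diazinon[0], p, ModelConfig(N=100, M=500)).S
        np.testing.assert_allclose(S, 1.0, atol=1e-14)

    def test_improper_parameters_flagged_not_raised(self, diazinon):
        p = [-0.1, 0.1, 3.0, 20.0, 10.0]
        curve = survival_probabilities(diazinon[0], p, ModelConfig(N=50, M=500))
        assert curve.status == "improper_params"
        assert np.all(np.isnan(curve.S))

    @pytest.mark.parametrize("seed", range(10))
    def test_fast_recursion_equals_naive_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        experiment, params = random_instance(rng)
        cfg = ModelConfig(N=50, M=200)
        tau, dtau = refine_time_grid(experiment.survival.times, cfg.M)
        grid = lognormal_threshold_grid(params.mn, params.sd, cfg.N)
        fast = survival_probabilities(experiment, params, cfg).S
        naive = naive_survival_sum(experiment.exposure, params,
                                   experiment.survival.times, grid, tau, dtau)
        np.testing.assert_allclose(fast, naive, rtol=1e-12)

    def test_background_mortality_factorises_exactly(self, rng):
        experiment, params = random_instance(rng)
        cfg = ModelConfig(N=50, M=300)
        with_hb = survival_probabilities(experiment, params, cfg).S
        p0 = ParameterSet(hb=0.0, ke=params.ke, kk=params.kk, mn=params.mn, sd=params.sd)
        without = survival_probabilities(experiment, p0, cfg).S
        t = experiment.survival.times
        np.testing.assert_allclose(with_hb, without * np.exp(-params.hb * t), rtol=1e-12)

    def test_convergence_in_N_and_M(self, rng):
        experiment, params = random_instance(rng)
        diffs = []
        for N, M in [(50, 200), (100, 400), (200, 800), (400, 1600)]:
            a = survival_probabilities(experiment, params, ModelConfig(N=N, M=M)).S
            b = survival_probabilities(experiment, params, ModelConfig(N=2 * N, M=2 * M)).S
            diffs.append(np.max(np.abs(a - b)))
        assert diffs[-1] < diffs[0]
        assert diffs[-1] < 1e-3

    def test_random_threshold_sampling_agrees_with_importance_grid(self, diazinon):
        cfg = ModelConfig(N=4000, M=2000)
        det = survival_probabilities(diazinon[0], DIAZINON_MAP, cfg).S
        mc = survival_probabilities(diazinon[0], DIAZINON_MAP, cfg,
                                    rng=np.random.default_rng(5)).S
        assert np.max(np.abs(det - mc)) < 0.02


class TestLimits:
    def test_sd_equals_delta_distribution(self, rng):
        experiment, params = random_instance(rng)
        sd_cfg = ModelConfig(dist="delta", N=1, M=500)
        sd_curve = survival_probabilities(
            experiment, [params.hb, params.ke, params.kk, params.mn], sd_cfg).S
        # closed form: exp(-kk * dtau * sum max(D - mn, 0) - hb t)
        from guts.damage_kinetics import cut_indices, damage_on_grid

        tau, dtau = refine_time_grid(experiment.survival.times, 500)
        D = damage_on_grid(experiment.exposure, params.ke, tau)
        cuts = cut_indices(tau, experiment.survival.times)
        expected = [
            np.exp(-params.kk * dtau * np.sum(np.maximum(D[:c] - params.mn, 0.0))
                   - params.hb * t)
            for c, t in zip(cuts, experiment.survival.times)
        ]
        np.testing.assert_allclose(sd_curve, expected, rtol=1e-12)

    def test_proper_with_tiny_sd_approaches_sd_model(self, rng):
        experiment, params = random_instance(rng)
        mn = params.mn
        proper = survival_probabilities(
            experiment, [params.hb, params.ke, params.kk, mn, 1e-6],
            ModelConfig(N=1000, M=1000)).S
        delta = survival_probabilities(
            experiment, [params.hb, params.ke, params.kk, mn],
            ModelConfig(dist="delta", N=1, M=1000)).S
        assert np.max(np.abs(proper - delta)) < 1e-3

    def test_proper_with_huge_kk_approaches_it(self, diazinon):
        hb, ke, mn, sd = 0.05, 0.1, 15.0, 6.0
        cfg = ModelConfig(N=4000, M=10000)
        proper = survival_probabilities(diazinon[0], [hb, ke, 1e6, mn, sd], cfg).S
        it = it_survival(diazinon[0], [hb, ke, mn, sd],
                         ModelConfig(model="it", N=4000, M=10000)).S
        assert np.max(np.abs(proper - it)) < 1e-2

    def test_it_with_monotone_damage_tracks_threshold_cdf(self):
        from scipy import stats

        exp = make_experiment([80, 80], [0, 30], [10, 9, 8, 7], [0, 5, 10, 20])
        hb, ke, mn, sd = 0.0, 0.2, 30.0, 10.0
        S = it_survival(exp, [hb, ke, mn, sd], ModelConfig(model="it", M=5000)).S
        mu, sigma = lognormal_mu_sigma(mn, sd)
        d = 80 * (1 - np.exp(-ke * exp.survival.times))
        expected = 1 - stats.lognorm.cdf(d, s=sigma, scale=np.exp(mu))
        np.testing.assert_allclose(S, expected, atol=1e-6)


@settings(derandomize=True, deadline=None, max_examples=40)
@given(
    seed=st.integers(0, 10_000),
    hb=st.floats(0.0, 0.3),
    ke=st.floats(0.01, 2.0),
    kk=st.floats(0.0, 30.0),
    mn=st.floats(0.5, 60.0),
    sd=st.floats(0.1, 30.0),
    flavour=st.sampled_from(["proper", "sd", "it"]),
)
def test_survival_curve_invariants(seed, hb, ke, kk, mn, sd, flavour):
    """S starts at exactly 1, is non-increasing, and stays within [0, 1]."""
    rng = np.random.default_rng(seed)
    experiment, _ = random_instance(rng)
    if flavour == "proper":
        cfg, vec = ModelConfig(N=64, M=300), [hb, ke, kk, mn, sd]
    elif flavour == "sd":
        cfg, vec = ModelConfig(dist="delta", N=1, M=300), [hb, ke, kk, mn]
    else:
        cfg, vec = ModelConfig(model="it", N=64, M=300), [hb, ke, mn, sd]
    S = survival_probabilities(experiment, vec, cfg).S
    assert S[0] == 1.0
    assert np.all(np.diff(S) <= 1e-12)
    assert np.all((S >= 0) & (S <= 1 + 1e-12))
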