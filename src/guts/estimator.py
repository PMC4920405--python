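"""Scikit-learn-style estimator wrapping calibration and prediction.

``GutsModel`` follows the estimator protocol (``get_params``/``set_params``
from :class:`sklearn.base.BaseEstimator`, a ``fit`` that returns ``self``,
fitted attributes with trailing underscores) so it can be cloned and driven
by generic tooling.  The "X" of this estimator is a list of
:class:`~guts.data_model.SurvivalExperiment` objects rather than a feature
matrix; the functional modules remain the lower-level API.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data_model import ModelConfig, SurvivalExperiment, parameter_names
from .inference import (
    PriorBounds,
    default_bounds,
    default_box_upper,
    default_start,
    find_map,
    log_posterior,
    run_mcmc,
    summarise_posterior,
)
from .likelihood import total_log_likelihood
from .prediction import predict_deaths, validate_predictions
from .survival_engine import survival_probabilities

__all__ = ["GutsModel"]


class GutsModel(BaseEstimator):
    """Bayesian threshold-hazard survival model with MAP + MCMC calibration.

    Parameters mirror the conventional workflow: model flavour and
    discretisation (``dist``, ``model``, ``N``, ``M``), the optimisation
    start and box, and the sampler settings.  ``fit`` runs the pattern
    search followed by the adaptive Metropolis chain; ``predict`` returns
    posterior predictive death-count quantiles for a scenario experiment.
    """

    def __init__(self, dist: str = "lognormal", model: str = "proper",
                 N: int = 1000, M: int = 10000, start=None, box_upper=None,
                 n_iter: int = 50000, n_adapt: int = 20000,
                 target_accept: float = 0.4, burn_in: int = 10000,
                 seed: int | None = 0, run_mcmc: bool = True):
        self.dist = dist
        self.model = model
        self.N = N
        self.M = M
        self.start = start
        self.box_upper = box_upper
        self.n_iter = n_iter
        self.n_adapt = n_adapt
        self.target_accept = target_accept
        self.burn_in = burn_in
        self.seed = seed
        self.run_mcmc = run_mcmc

    # ------------------------------------------------------------------
    def _config(self) -> ModelConfig:
        return ModelConfig(dist=self.dist, model=self.model, N=self.N, M=self.M)

    def _validate_experiments(self, X) -> list[SurvivalExperiment]:
        if isinstance(X, SurvivalExperiment):
            X = [X]
        X = list(X)
        if not X or not all(isinstance(e, SurvivalExperiment) for e in X):
            raise ValueError("X must be a non-empty list of SurvivalExperiment")
        return X

    def fit(self, X, y=None) -> "GutsModel":
        """Calibrate on a list of experiments: MAP search, then MCMC."""
        experiments = self._validate_experiments(X)
        config = self._config()
        bounds = default_bounds(config)
        start = default_start(config) if self.start is None else np.asarray(self.start, float)
        box_upper = (default_box_upper(config) if self.box_upper is None
                     else np.asarray(self.box_upper, float))
        self.config_ = config
        self.bounds_ = bounds
        self.param_names_ = parameter_names(config)
        self.map_params_, self.map_log_posterior_ = find_map(
            start, experiments, bounds, config, box_upper=box_upper)
        if self.run_mcmc:
            self.posterior_ = run_mcmc(
                self.map_params_, experiments, bounds, config,
                n_iter=self.n_iter, n_adapt=self.n_adapt,
                target_accept=self.target_accept, seed=self.seed)
            self.summary_ = summarise_posterior(self.posterior_, burn_in=self.burn_in)
        return self

    def score(self, X, y=None) -> float:
        """Total log-likelihood of experiments at the MAP estimate."""
        experiments = self._validate_experiments(X)
        return total_log_likelihood(experiments, self.map_params_, self.config_).value

    def predict_survival(self, experiment: SurvivalExperiment) -> np.ndarray:
        """Survival probabilities at the experiment's observation times (MAP)."""
        return survival_probabilities(experiment, self.map_params_, self.config_).S

    def predict(self, X, n_draws: int | None = 4000) -> list[pd.DataFrame]:
        """Posterior predictive death-count tables for scenario experiment(s)."""
        if not hasattr(self, "posterior_"):
            raise AttributeError("predict requires a fitted model with run_mcmc=True")
        scenarios = self._validate_experiments(X)
        return [predict_deaths(s, self.posterior_, burn_in=self.burn_in,
                               n_draws=n_draws, seed=self.seed, config=self.config_)
                for s in scenarios]

    def validate(self, scenario: SurvivalExperiment, n_draws: int | None = 4000):
        """Prediction table with measured deaths plus 95%-interval coverage."""
        return validate_predictions(scenario, self.posterior_, burn_in=self.burn_in,
                                    n_draws=n_draws, seed=self.seed, config=self.config_)

    def log_posterior(self, params, X) -> float:
        experiments = self._validate_experiments(X)
        return log_posterior(params, experiments, default_bounds(self._config()),
                             self._config())
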