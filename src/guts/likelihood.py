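"""Multinomial-kernel log-likelihood of survivor time series.

Deaths per observation window (t_{i-1}, t_i] follow a multinomial with
probabilities S_{i-1} - S_i, with a terminal window reaching to infinity
(S at infinity is zero).  Up to a parameter-independent combinatorial
constant the log-likelihood is

    ln f(y|theta) = sum_{i=1}^{n+1} (y_{i-1} - y_i) ln(S_{i-1} - S_i)

with y_{n+1} = 0 and S_{n+1} = 0.  Windows without deaths contribute zero
even when the survival difference vanishes (0*ln 0 := 0); a window with
deaths but non-positive survival mass makes the value -inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ModelConfig, ParameterSet, SurvivalExperiment, check_parameters
from .survival_engine import survival_probabilities

__all__ = ["LogLikelihoodResult", "log_likelihood_from_curve", "log_likelihood", "total_log_likelihood"]

#: survival-mass floor below which a window with deaths is treated as impossible
_MASS_FLOOR = 1e-300


@dataclass(frozen=True)
class LogLikelihoodResult:
    value: float
    status: str = "ok"
    warnings: tuple[str, ...] = ()

    def __float__(self) -> float:
        return self.value


def log_likelihood_from_curve(counts: np.ndarray, S: np.ndarray) -> float:
    """Multinomial kernel given survivor counts and matching survival curve."""
    y = np.asarray(counts, dtype=float)
    S = np.asarray(S, dtype=float)
    deaths = np.append(-np.diff(y), y[-1])          # windows 1..n, then beyond t_n
    mass = np.append(np.maximum(-np.diff(S), 0.0), max(S[-1], 0.0))
    active = deaths > 0
    if np.any(mass[active] <= _MASS_FLOOR):
        return -np.inf
    return float(np.sum(deaths[active] * np.log(mass[active])))


def _check(params, config: ModelConfig):
    if isinstance(params, ParameterSet):
        params = params.to_vector(config)  # raises ParameterArityError on mismatch
    flag = check_parameters(params, config)
    if flag == "wrong_arity":
        from .data_model import ParameterArityError

        raise ParameterArityError(
            f"expected {config.n_params} parameters for {config.dist}/{config.model}"
        )
    return params, flag


def log_likelihood(
    experiment: SurvivalExperiment,
    params,
    config: ModelConfig = ModelConfig(),
) -> LogLikelihoodResult:
    """Log-likelihood of one experiment.

    A wrong parameter count raises; improper values (negative, NaN,
    infinite) return value -inf with ``status="improper_params"`` and a
    warning message, mirroring a warning-not-error policy that keeps
    optimisers and samplers running.
    """
    params, flag = _check(params, config)
    if flag == "improper":
        return LogLikelihoodResult(
            value=-np.inf,
            status="improper_params",
            warnings=("improper parameter values; log-likelihood set to -inf",),
        )
    curve = survival_probabilities(experiment, params, config)
    value = log_likelihood_from_curve(experiment.survival.counts, curve.S)
    return LogLikelihoodResult(value=value)


def total_log_likelihood(
    experiments,
    params,
    config: ModelConfig = ModelConfig(),
) -> LogLikelihoodResult:
    """Sum of per-experiment log-likelihoods; -inf and warnings propagate."""
    experiments = list(experiments)
    if not experiments:
        raise ValueError("need at least one experiment")
    total = 0.0
    status = "ok"
    warnings: tuple[str, ...] = ()
    for exp in experiments:
        res = log_likelihood(exp, params, config)
        total += res.value
        if res.status != "ok":
            status = res.status
            warnings = res.warnings
            break
    return LogLikelihoodResult(value=total, status=status, warnings=warnings)
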