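"""Fast O(N)+O(M) computation of population survival probabilities.

The population survival probability under a threshold-distributed hazard is

    S(t) = Integral exp(-kk * Integral_0^t max(D(tau) - z, 0) dtau - hb*t) f(z) dz

with D the damage trajectory and f the threshold distribution.  Both
integrals are discretised: the time axis on an equidistant grid of M points
(left Riemann sum with weight dtau) and the threshold axis on N ordered
points z_1 < ... < z_N.  Binning each damage value into the threshold
intervals and maintaining suffix sums of the per-bin damage totals (E_j)
and counts (F_j) turns the double sum into a single backward recursion, so
one survival curve costs O(M) binning plus O(N) per observation time.

For the lognormal threshold distribution the default is a deterministic
log-uniform grid covering [mu - 4 sigma, mu + 4 sigma] on the log axis,
with importance weights ln f(z_j)/g(z_j); the resulting survival vector is
normalised by its first element, which makes S(0) = 1 exact.  All partial
sums are accumulated in log space, so large killing rates cannot underflow.

The individual-tolerance (IT) limit kk -> infinity is computed directly:
S(t) = exp(-hb*t) * (1 - F(max_{tau <= t} D(tau))) with F the threshold CDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import (
    ModelConfig,
    ParameterSet,
    SurvivalExperiment,
    ValidationError,
    check_parameters,
)
from .damage_kinetics import cut_indices, damage_at_times, damage_on_grid, refine_time_grid

__all__ = [
    "ThresholdGrid",
    "SurvivalCurve",
    "lognormal_threshold_grid",
    "lognormal_threshold_sample",
    "delta_threshold",
    "lognormal_mu_sigma",
    "survival_probabilities",
    "it_survival",
]


@dataclass(frozen=True)
class ThresholdGrid:
    """Ordered thresholds with per-threshold log importance weights."""

    z: np.ndarray
    logw: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        logw = np.asarray(self.logw, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "logw", logw)
        if z.shape != logw.shape or z.ndim != 1 or z.size < 1:
            raise ValidationError("threshold grid and weights must be 1-d of equal length")
        if z.size > 1 and np.any(np.diff(z) <= 0):
            raise ValidationError("thresholds must be strictly increasing")


@dataclass(frozen=True)
class SurvivalCurve:
    """Survival probabilities at the observation times of one experiment."""

    S: np.ndarray
    times: np.ndarray
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def lognormal_mu_sigma(mn: float, sd: float) -> tuple[float, float]:
    """Log-scale parameters (mu, sigma) of a lognormal with mean mn and sd."""
    sigma2 = np.log1p(sd**2 / mn**2)
    mu = np.log(mn) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def lognormal_threshold_grid(mn: float, sd: float, N: int) -> ThresholdGrid:
    """Deterministic log-uniform grid with lognormal importance weights.

    The grid points are z_j = exp(x_j) with x_j equidistant on
    [mu - 4 sigma, mu + 4 sigma]; the log weight is -(mu - x_j)^2 / (2 sigma^2)
    up to a parameter-independent constant that the normalisation of the
    survival vector removes.
    """
    if not (mn > 0 and sd > 0):
        raise ValidationError("lognormal threshold grid requires mn > 0 and sd > 0")
    if N < 2:
        raise ValidationError("lognormal threshold grid requires N >= 2")
    mu, sigma = lognormal_mu_sigma(mn, sd)
    x = np.linspace(mu - 4.0 * sigma, mu + 4.0 * sigma, N)
    logw = -((mu - x) ** 2) / (2.0 * sigma**2)
    return ThresholdGrid(z=np.exp(x), logw=logw)


def lognormal_threshold_sample(mn: float, sd: float, N: int, rng: np.random.Generator) -> ThresholdGrid:
    """Plain ordered Monte-Carlo sample from the lognormal threshold law."""
    if not (mn > 0 and sd > 0):
        raise ValidationError("lognormal threshold sample requires mn > 0 and sd > 0")
    mu, sigma = lognormal_mu_sigma(mn, sd)
    z = np.sort(rng.lognormal(mean=mu, sigma=sigma, size=N))
    return ThresholdGrid(z=z, logw=np.zeros(N))


def delta_threshold(mn: float) -> ThresholdGrid:
    """Point-mass threshold (stochastic-death flavour): a single z = mn."""
    if not (np.isfinite(mn) and mn >= 0):
        raise ValidationError("delta threshold requires mn >= 0")
    return ThresholdGrid(z=np.asarray([mn]), logw=np.asarray([0.0]))


def _logsumexp(a: np.ndarray) -> float:
    m = a.max()
    if not np.isfinite(m):
        return m
    return m + np.log(np.sum(np.exp(a - m)))


def proper_survival_from_grids(
    D: np.ndarray,
    dtau: float,
    cuts: np.ndarray,
    obs_times: np.ndarray,
    grid: ThresholdGrid,
    kk: float,
    hb: float,
) -> np.ndarray:
    """The backward recursion over threshold bins, in log space.

    ``cuts[i]`` is the number of damage grid values with tau < t_i.  Damage
    values are binned with strict inequalities: a value exactly equal to a
    threshold counts as not exceeding it.
    """
    z, logw = grid.z, grid.logw
    N = z.size
    # bin index = number of thresholds strictly below D_l (0 = below z_1)
    bins = np.searchsorted(z, D, side="left")
    f = np.zeros(N + 1)
    e = np.zeros(N + 1)
    log_s = np.empty(len(obs_times))
    prev = 0
    for i, cut in enumerate(cuts):
        if cut > prev:
            sl = bins[prev:cut]
            f += np.bincount(sl, minlength=N + 1)
            e += np.bincount(sl, weights=D[prev:cut], minlength=N + 1)
            prev = cut
        # suffix sums over bins j = N..1 (bin 0 never contributes)
        F = np.cumsum(f[:0:-1])[::-1]
        E = np.cumsum(e[:0:-1])[::-1]
        a = -kk * dtau * (E - F * z) + logw
        log_s[i] = _logsumexp(a) - hb * obs_times[i]
    log_s -= log_s[0]  # normalisation by the first unnormalised element
    return np.exp(log_s)


def _threshold_grid_for(params: ParameterSet, config: ModelConfig,
                        rng: np.random.Generator | None) -> ThresholdGrid:
    if config.dist == "delta":
        return delta_threshold(params.mn)
    if rng is not None:
        return lognormal_threshold_sample(params.mn, params.sd, config.N, rng)
    return lognormal_threshold_grid(params.mn, params.sd, config.N)


def _as_params(params, config: ModelConfig) -> ParameterSet:
    if isinstance(params, ParameterSet):
        return params
    return ParameterSet.from_vector(params, config)


def survival_probabilities(
    experiment: SurvivalExperiment,
    params,
    config: ModelConfig = ModelConfig(),
    rng: np.random.Generator | None = None,
) -> SurvivalCurve:
    """Population survival probabilities at the experiment's observation times.

    ``params`` may be a :class:`ParameterSet` or a flavour-ordered vector.
    Improper parameter values (negative, NaN, infinite) yield a curve of
    NaNs with ``status="improper_params"`` rather than an exception; a wrong
    parameter count raises.  Passing ``rng`` replaces the deterministic
    importance grid by a plain random threshold sample (lognormal only).
    """
    p = _as_params(params, config)
    obs_times = experiment.survival.times
    if check_parameters(p.to_vector(config), config) != "proper":
        return SurvivalCurve(S=np.full(len(obs_times), np.nan), times=obs_times,
                             status="improper_params")
    if config.model == "it":
        return it_survival(experiment, p, config)
    tau, dtau = refine_time_grid(obs_times, config.M)
    D = damage_on_grid(experiment.exposure, p.ke, tau)
    cuts = cut_indices(tau, obs_times)
    grid = _threshold_grid_for(p, config, rng)
    S = proper_survival_from_grids(D, dtau, cuts, obs_times, grid, p.kk, p.hb)
    return SurvivalCurve(S=S, times=obs_times)


def it_survival(
    experiment: SurvivalExperiment,
    params,
    config: ModelConfig = ModelConfig(dist="lognormal", model="it"),
) -> SurvivalCurve:
    """Individual-tolerance survival: threshold CDF at the running damage maximum.

    The maximum over (0, t_i] combines the running maximum over grid points
    strictly before t_i with the exact damage value at t_i itself.
    """
    p = _as_params(params, config)
    obs_times = experiment.survival.times
    vec = p.to_vector(ModelConfig(dist="lognormal", model="it", N=config.N, M=config.M))
    if check_parameters(vec, ModelConfig(dist="lognormal", model="it")) != "proper":
        return SurvivalCurve(S=np.full(len(obs_times), np.nan), times=obs_times,
                             status="improper_params")
    tau, _ = refine_time_grid(obs_times, config.M)
    D = damage_on_grid(experiment.exposure, p.ke, tau)
    running = np.maximum.accumulate(D)
    cuts = cut_indices(tau, obs_times)
    d_exact = damage_at_times(experiment.exposure, p.ke, obs_times)
    d_max = np.where(cuts > 0, running[np.maximum(cuts - 1, 0)], 0.0)
    d_max = np.maximum(d_max, d_exact)
    if p.sd == 0.0:
        cdf = (d_max > p.mn).astype(float)
    else:
        mu, sigma = lognormal_mu_sigma(p.mn, p.sd)
        cdf = stats.lognorm.cdf(d_max, s=sigma, scale=np.exp(mu))
    S = np.exp(-p.hb * obs_times) * (1.0 - cdf)
    return SurvivalCurve(S=S, times=obs_times)
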