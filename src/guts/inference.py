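"""Posterior inference: bounded-uniform priors, pattern-search MAP, and a
robust adaptive Metropolis sampler.

Priors are uniform with lower bounds 0; upper bounds are infinite except
for the killing rate kk, which is capped (default 30) because its
posterior is heavy-tailed and an unbounded chain can diverge — the cap is
large enough to be practically indistinguishable from the
individual-tolerance limit kk = infinity.

The MAP search is a classic Hooke–Jeeves pattern search (derivative-free,
box-constrained, deterministic).  The sampler is a robust adaptive
Metropolis: a random-walk Metropolis whose proposal Cholesky factor is
updated with a rank-one correction toward a target acceptance rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ModelConfig, parameter_names
from .likelihood import total_log_likelihood

__all__ = [
    "PriorBounds",
    "PosteriorSample",
    "default_bounds",
    "default_start",
    "default_box_upper",
    "log_posterior",
    "hooke_jeeves_max",
    "find_map",
    "ram_sampler",
    "run_mcmc",
    "summarise_posterior",
]

#: default uniform-prior / optimiser-box settings for the full flavour,
#: keyed by parameter name: (start, box upper)
_DEFAULTS = {
    "hb": (0.05, 1.0),
    "ke": (0.1, 1.0),
    "kk": (3.0, 30.0),
    "mn": (20.0, 40.0),
    "sd": (10.0, 20.0),
}

#: prior upper bound on the killing rate (1/(day * concentration unit))
KK_PRIOR_BOUND = 30.0


@dataclass(frozen=True)
class PriorBounds:
    """Box of a bounded-uniform prior (upper bounds may be +inf)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape:
            raise ValueError("bound vectors must have equal length")
        if np.any(lower < 0) or np.any(upper <= lower):
            raise ValueError("bounds require 0 <= lower < upper")

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(
            np.all(np.isfinite(x)) and np.all(x >= self.lower) and np.all(x <= self.upper)
        )


def default_bounds(config: ModelConfig) -> PriorBounds:
    """Zero lower bounds; upper bounds infinite except kk < 30."""
    names = parameter_names(config)
    upper = np.asarray([KK_PRIOR_BOUND if n == "kk" else np.inf for n in names])
    return PriorBounds(lower=np.zeros(len(names)), upper=upper)


def default_start(config: ModelConfig) -> np.ndarray:
    return np.asarray([_DEFAULTS[n][0] for n in parameter_names(config)])


def default_box_upper(config: ModelConfig) -> np.ndarray:
    return np.asarray([_DEFAULTS[n][1] for n in parameter_names(config)])


def log_posterior(params, experiments, bounds: PriorBounds | None = None,
                  config: ModelConfig = ModelConfig()) -> float:
    """Log posterior density up to a constant: log-likelihood on the prior box,
    -inf outside it (the flat prior contributes nothing on the inside)."""
    x = np.atleast_1d(np.asarray(params, dtype=float))
    if bounds is None:
        bounds = default_bounds(config)
    if x.shape != bounds.lower.shape or not bounds.contains(x):
        return -np.inf
    return total_log_likelihood(experiments, x, config).value


def hooke_jeeves_max(f, x0, lower, upper, *, init_step: float = 0.1,
                     tol: float = 1e-7, max_feval: int = 30000) -> tuple[np.ndarray, float, int]:
    """Maximise ``f`` over a finite box with Hooke–Jeeves pattern search.

    Step sizes start at ``init_step`` times the box width per coordinate and
    halve whenever no exploratory move improves; terminates when the largest
    relative step drops below ``tol`` or the evaluation budget is exhausted.
    Returns ``(x_best, f_best, n_feval)`` and is fully deterministic.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if not np.all(np.isfinite(lower)) or not np.all(np.isfinite(upper)):
        raise ValueError("pattern search requires a finite box")
    x = np.clip(np.asarray(x0, dtype=float), lower, upper)
    width = upper - lower
    h = init_step * width
    n_feval = 0

    def ev(pt):
        nonlocal n_feval
        n_feval += 1
        return f(pt)

    fx = ev(x)
    if not np.isfinite(fx):
        raise ValueError("no feasible start: objective is -inf at the initial point")

    def explore(base, fbase):
        xb = base.copy()
        fb = fbase
        for j in range(len(xb)):
            for sign in (1.0, -1.0):
                trial = xb.copy()
                trial[j] = np.clip(trial[j] + sign * h[j], lower[j], upper[j])
                if trial[j] == xb[j]:
                    continue
                ft = ev(trial)
                if ft > fb:
                    xb, fb = trial, ft
                    break
        return xb, fb

    while np.max(h / width) > tol and n_feval < max_feval:
        xn, fn = explore(x, fx)
        if fn <= fx:
            h /= 2.0
            continue
        # pattern moves: keep extrapolating along the successful direction
        while fn > fx and n_feval < max_feval:
            direction = xn - x
            x, fx = xn, fn
            xp = np.clip(x + direction, lower, upper)
            fp = ev(xp)
            xn, fn = explore(xp, fp)
    return x, fx, n_feval


def find_map(start, experiments, bounds: PriorBounds | None = None,
             config: ModelConfig = ModelConfig(), *, box_lower=None, box_upper=None,
             max_feval: int = 30000) -> tuple[np.ndarray, float]:
    """Derivative-free MAP search on the log posterior inside a finite box.

    The optimisation box defaults to lower 0 and the conventional finite
    uppers (1, 1, 30, 40, 20) for (hb, ke, kk, mn, sd); it may be tighter
    than the prior box, which is enforced through the objective itself.
    """
    if bounds is None:
        bounds = default_bounds(config)
    if start is None:
        start = default_start(config)
    box_lower = bounds.lower if box_lower is None else np.asarray(box_lower, dtype=float)
    box_upper = default_box_upper(config) if box_upper is None else np.asarray(box_upper, dtype=float)

    def objective(x):
        return log_posterior(x, experiments, bounds, config)

    x_best, f_best, _ = hooke_jeeves_max(objective, start, box_lower, box_upper,
                                         max_feval=max_feval)
    return x_best, f_best


@dataclass
class PosteriorSample:
    """MCMC output: draws (iterations x parameters) with log-posterior values."""

    draws: np.ndarray
    logp: np.ndarray
    acceptance_rate: float
    param_names: tuple[str, ...]
    seed: int | None = None
    n_adapt: int = 0
    target_accept: float = 0.4

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df["logp"] = self.logp
        return df


def ram_sampler(logp, init, *, n_iter: int, n_adapt: int, target_accept: float = 0.4,
                seed: int | None = None, initial_sd=None,
                gamma: float = 2.0 / 3.0) -> tuple[np.ndarray, np.ndarray, float]:
    """Robust adaptive Metropolis on an arbitrary log density.

    Proposals are x + S u with u standard normal; during the first
    ``n_adapt`` iterations the Cholesky factor S receives the rank-one
    update S S' <- S (I + eta_n (alpha - target) u u' / |u|^2) S' with step
    eta_n = min(1, d n^-gamma), which drives the realised acceptance
    probability toward the target.  Returns (draws, logp values, acceptance
    rate over the post-adaptation phase).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(init, dtype=float).copy()
    d = x.size
    lp = logp(x)
    if not np.isfinite(lp):
        raise ValueError("infeasible init: log density is -inf at the starting point")
    if initial_sd is None:
        initial_sd = 0.1 * np.abs(x)
    S = np.diag(np.sqrt(np.asarray(initial_sd, dtype=float) ** 2 + 1e-12))
    draws = np.empty((n_iter, d))
    lps = np.empty(n_iter)
    accepted_post = 0
    eye = np.eye(d)
    for n in range(n_iter):
        u = rng.standard_normal(d)
        prop = x + S @ u
        lp_prop = logp(prop)
        with np.errstate(over="ignore"):
            alpha = min(1.0, np.exp(lp_prop - lp)) if np.isfinite(lp_prop) else 0.0
        if rng.random() < alpha:
            x, lp = prop, lp_prop
            if n >= n_adapt:
                accepted_post += 1
        draws[n] = x
        lps[n] = lp
        if n < n_adapt:
            eta = min(1.0, d * (n + 1) ** (-gamma))
            un = u / np.linalg.norm(u)
            M = S @ (eye + eta * (alpha - target_accept) * np.outer(un, un)) @ S.T
            try:
                S = np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                S = np.linalg.cholesky(M + 1e-12 * eye)
    denom = max(n_iter - n_adapt, 1)
    return draws, lps, accepted_post / denom


def run_mcmc(init, experiments, bounds: PriorBounds | None = None,
             config: ModelConfig = ModelConfig(), *, n_iter: int = 50000,
             n_adapt: int = 20000, target_accept: float = 0.4,
             seed: int | None = None) -> PosteriorSample:
    """Sample the parameter posterior with the robust adaptive Metropolis.

    The initial proposal covariance is diagonal with standard deviations of
    10% of the initial parameter values (plus a small jitter guarding
    against zero components).
    """
    if bounds is None:
        bounds = default_bounds(config)
    init = np.asarray(init, dtype=float)

    def logp(x):
        return log_posterior(x, experiments, bounds, config)

    draws, lps, acc = ram_sampler(
        logp, init, n_iter=n_iter, n_adapt=n_adapt,
        target_accept=target_accept, seed=seed,
    )
    return PosteriorSample(
        draws=draws, logp=lps, acceptance_rate=acc,
        param_names=parameter_names(config), seed=seed,
        n_adapt=n_adapt, target_accept=target_accept,
    )


def summarise_posterior(sample: PosteriorSample, burn_in: int = 10000,
                        thin: int = 1) -> pd.DataFrame:
    """Per-parameter maxpost and (2.5, 50, 97.5)% quantiles after burn-in.

    ``maxpost`` is the draw with the highest stored log posterior over the
    whole chain; quantiles are empirical (linear interpolation) on the
    post-burn-in draws.  Thinning is available for plotting economy but the
    default uses every retained draw.
    """
    if burn_in >= len(sample.draws):
        raise ValueError("burn_in leaves no draws")
    kept = sample.draws[burn_in::thin]
    best = sample.draws[int(np.argmax(sample.logp))]
    q = np.quantile(kept, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {"maxpost": best, "q0.025": q[0], "q0.5": q[1], "q0.975": q[2]},
        index=list(sample.param_names),
    )
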