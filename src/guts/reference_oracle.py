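"""Slow independent cross-checks and a forward simulator.

These routines exist for verification and synthetic-data studies, not for
speed: a literal double sum over the threshold and time grids, an adaptive
two-dimensional quadrature of the survival integral, and an
individual-based simulator that draws thresholds and death times directly
from the stochastic process the likelihood describes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .data_model import ModelConfig, ParameterSet, SurvivalExperiment, make_experiment
from .damage_kinetics import damage_at_times, damage_on_grid, refine_time_grid
from .survival_engine import ThresholdGrid, lognormal_mu_sigma

__all__ = [
    "SimulatedAssay",
    "brute_force_survival",
    "naive_survival_sum",
    "simulate_survival",
]


@dataclass(frozen=True)
class SimulatedAssay:
    """A synthetic experiment together with the generating truth."""

    experiment: SurvivalExperiment
    truth: ParameterSet
    seed: int


def _scalar_damage_fn(exposure, ke: float):
    """Fast scalar closure D(tau) with precomputed segment-boundary damage."""
    import math

    s = exposure.times.tolist()
    c = exposure.conc.tolist()
    Db = damage_at_times(exposure, ke, exposure.times).tolist()
    slopes = [(c[k + 1] - c[k]) / (s[k + 1] - s[k]) for k in range(len(s) - 1)] + [0.0]
    last = len(s) - 1

    def D(tau: float) -> float:
        if ke == 0.0:
            return 0.0
        k = min(max(int(np.searchsorted(exposure.times, tau, side="right")) - 1, 0), last)
        dt = tau - s[k]
        x = ke * dt
        em = math.expm1(-x)
        phi = (x / 2.0 - x * x / 6.0 + x**3 / 24.0) if abs(x) < 1e-4 else (x + em) / x
        return Db[k] * math.exp(-x) + c[k] * (-em) + slopes[k] * dt * phi

    return D


def _damage_excess_integral(damage_fn, breaks, z: float, t: float) -> float:
    """Integral_0^t max(D(tau) - z, 0) dtau by adaptive quadrature."""
    val, _ = integrate.quad(lambda tau: max(damage_fn(tau) - z, 0.0),
                            0.0, t, points=[b for b in breaks if 0.0 < b < t],
                            limit=200, epsabs=1e-10, epsrel=1e-9)
    return val


def brute_force_survival(exposure, params: ParameterSet, t: float,
                         config: ModelConfig = ModelConfig()) -> float:
    """Direct 2-D quadrature of the survival integral at a single time.

    The damage excess is integrated adaptively over time (using the exact
    closed-form damage), nested inside an adaptive integration over the
    threshold against the lognormal density (or evaluated at the point mass
    for the delta flavour).  Intended accuracy about 1e-6.
    """
    hb, ke, kk = params.hb, params.ke, params.kk
    if t == 0.0:
        return 1.0
    damage_fn = _scalar_damage_fn(exposure, ke)
    breaks = exposure.times.tolist()
    if config.dist == "delta":
        J = _damage_excess_integral(damage_fn, breaks, params.mn, t)
        return float(np.exp(-kk * J - hb * t))
    mu, sigma = lognormal_mu_sigma(params.mn, params.sd)

    def outer(x):  # integrate on the log-threshold axis against N(mu, sigma)
        J = _damage_excess_integral(damage_fn, breaks, float(np.exp(x)), t)
        return np.exp(-kk * J) * stats.norm.pdf(x, loc=mu, scale=sigma)

    val, err = integrate.quad(outer, mu - 10 * sigma, mu + 10 * sigma,
                              limit=200, epsabs=1e-9, epsrel=1e-8)
    if err > 1e-5:
        raise RuntimeError(f"quadrature did not converge (err={err:.2e})")
    return float(np.exp(-hb * t) * val)


def naive_survival_sum(exposure, params: ParameterSet, t_points, grid: ThresholdGrid,
                       tau: np.ndarray, dtau: float) -> np.ndarray:
    """The literal O(N*M) double sum, with the same grids as the fast engine.

    For each observation time the inner sum runs over damage values on
    grid points strictly before it; the outer sum runs over thresholds,
    with importance weights in the exponent, and the resulting vector is
    normalised by its first element.
    """
    hb, kk = params.hb, params.kk
    D = damage_on_grid(exposure, params.ke, tau)
    t_points = np.asarray(t_points, dtype=float)
    out = np.empty(len(t_points))
    for i, t in enumerate(t_points):
        Dl = D[tau < t]
        total = 0.0
        for zj, lw in zip(grid.z, grid.logw):
            excess = Dl[Dl > zj] - zj
            total += np.exp(-kk * dtau * np.sum(excess) - hb * t + lw)
        out[i] = total
    return out / out[0]


def simulate_survival(exposure, obs_times, params: ParameterSet,
                      config: ModelConfig = ModelConfig(), n0: int = 70,
                      seed: int | None = None) -> SurvivalExperiment:
    """Individual-based forward simulation of a survival assay.

    Each individual draws its threshold from the configured distribution,
    accumulates hazard kk * integral of damage excess (left Riemann sum on
    the refined grid) plus background hb*t, and dies when the cumulative
    hazard first exceeds a standard-exponential variate (inverted by linear
    interpolation between grid points).  In the IT flavour death occurs at
    the first threshold crossing or from background mortality, whichever
    comes first.  Deaths are binned into the observation windows.
    """
    rng = np.random.default_rng(seed)
    obs_times = np.asarray(obs_times, dtype=float)
    tau, dtau = refine_time_grid(obs_times, config.M)
    D = damage_on_grid(exposure, params.ke, tau)
    t_n = obs_times[-1]

    if config.dist == "delta":
        z_draws = np.full(n0, params.mn)
    else:
        mu, sigma = lognormal_mu_sigma(params.mn, params.sd)
        z_draws = rng.lognormal(mean=mu, sigma=sigma, size=n0)

    death = np.full(n0, np.inf)
    if config.model == "it":
        running = np.maximum.accumulate(D)
        t_bg = rng.exponential(size=n0) / params.hb if params.hb > 0 else np.full(n0, np.inf)
        for i in range(n0):
            above = running > z_draws[i]
            t_cross = tau[np.argmax(above)] if above.any() else np.inf
            death[i] = min(t_bg[i], t_cross)
    else:
        eps = rng.exponential(size=n0)
        chunk = max(1, int(2_000_000 // max(len(tau), 1)))
        for lo in range(0, n0, chunk):
            hi = min(lo + chunk, n0)
            excess = np.maximum(D[None, :] - z_draws[lo:hi, None], 0.0)
            # cumulative hazard at tau_l uses grid points strictly before tau_l
            cum = np.concatenate(
                [np.zeros((hi - lo, 1)), np.cumsum(excess[:, :-1], axis=1)], axis=1
            )
            H = params.kk * dtau * cum + params.hb * tau[None, :]
            H_end = params.kk * dtau * (cum[:, -1] + excess[:, -1]) + params.hb * t_n
            for r in range(hi - lo):
                i = lo + r
                if H_end[r] < eps[i]:
                    continue
                idx = int(np.searchsorted(H[r], eps[i], side="left"))
                if idx >= len(tau):
                    t0, h0, t1, h1 = tau[-1], H[r, -1], t_n, H_end[r]
                else:
                    t0 = tau[idx - 1] if idx > 0 else 0.0
                    h0 = H[r, idx - 1] if idx > 0 else 0.0
                    t1, h1 = tau[idx], H[r, idx]
                death[i] = t0 if h1 <= h0 else t0 + (eps[i] - h0) * (t1 - t0) / (h1 - h0)

    death_sorted = np.sort(death)
    counts = n0 - np.searchsorted(death_sorted, obs_times, side="right")
    return make_experiment(exposure.conc, exposure.times, counts, obs_times,
                           label="simulated")
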