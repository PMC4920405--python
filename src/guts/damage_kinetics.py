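"""Damage kinetics: exact solution of dD/dt = ke * (C(t) - D(t)).

The exposure C(t) is the linear interpolation of the measured
concentrations; beyond the last measurement it is held constant.  Within a
segment [s_k, s_{k+1}] with C(t) = C_k + b*(t - s_k) the solution is

    D(t) = D(s_k) e^{-ke dt} + C_k (1 - e^{-ke dt}) + b (dt - (1 - e^{-ke dt})/ke)

with dt = t - s_k.  The slope term is evaluated as b*dt*phi(ke*dt) with
phi(x) = (x + expm1(-x))/x, using a Taylor branch for small x so that the
ke -> 0 limit (damage frozen at its initial value) is reached without
catastrophic cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ExposureSeries, ValidationError

__all__ = [
    "DamageTrajectory",
    "refine_time_grid",
    "cut_indices",
    "damage_on_grid",
    "damage_at_times",
    "damage_trajectory",
]


@dataclass(frozen=True)
class DamageTrajectory:
    """Damage evaluated on an equidistant grid of spacing ``dtau``."""

    tau: np.ndarray
    D: np.ndarray
    dtau: float


def refine_time_grid(survival_times, M: int) -> tuple[np.ndarray, float]:
    """Equidistant grid tau_l = l * (t_n / M), l = 0..M-1, spanning [0, t_n).

    Returns ``(tau, dtau)``.  M must be at least the number of observation
    intervals so that each window contains grid points.
    """
    survival_times = np.asarray(survival_times, dtype=float)
    n_intervals = len(survival_times) - 1
    if M < n_intervals:
        raise ValidationError(
            f"time grid size M={M} smaller than number of observation intervals {n_intervals}"
        )
    t_n = float(survival_times[-1])
    dtau = t_n / M
    return np.arange(M) * dtau, dtau


def cut_indices(tau: np.ndarray, obs_times) -> np.ndarray:
    """Number of grid points strictly before each observation time."""
    return np.searchsorted(tau, np.asarray(obs_times, dtype=float), side="left")


def _phi(x: np.ndarray) -> np.ndarray:
    """(x + expm1(-x)) / x, stable near 0 (limit 0, leading term x/2)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = xs / 2.0 - xs**2 / 6.0 + xs**3 / 24.0
    xl = x[~small]
    out[~small] = (xl + np.expm1(-xl)) / xl
    return out


def _boundary_damage(s: np.ndarray, c: np.ndarray, ke: float) -> np.ndarray:
    """Damage at the exposure measurement times, propagated exactly."""
    n = len(s)
    D = np.zeros(n)
    ds = np.diff(s)
    slopes = np.diff(c) / ds
    x = ke * ds
    decay = np.exp(-x)
    growth = -np.expm1(-x)
    ramp = slopes * ds * _phi(x)
    for k in range(n - 1):
        D[k + 1] = D[k] * decay[k] + c[k] * growth[k] + ramp[k]
    return D


def damage_at_times(exposure: ExposureSeries, ke: float, times) -> np.ndarray:
    """Exact damage D(t) (initial condition D(0) = 0) at arbitrary times >= 0."""
    if not np.isfinite(ke) or ke < 0:
        raise ValidationError(f"dominant rate constant ke must be finite and >= 0, got {ke}")
    t = np.asarray(times, dtype=float)
    if ke == 0.0:
        return np.zeros_like(t)
    s = exposure.times
    c = exposure.conc
    Db = _boundary_damage(s, c, ke)
    slopes = np.append(np.diff(c) / np.diff(s), 0.0)  # constant extrapolation
    k = np.clip(np.searchsorted(s, t, side="right") - 1, 0, len(s) - 1)
    dt = t - s[k]
    x = ke * dt
    return Db[k] * np.exp(-x) + c[k] * (-np.expm1(-x)) + slopes[k] * dt * _phi(x)


def damage_on_grid(exposure: ExposureSeries, ke: float, tau: np.ndarray) -> np.ndarray:
    """Damage evaluated on a (typically refined) time grid."""
    return damage_at_times(exposure, ke, tau)


def damage_trajectory(exposure: ExposureSeries, ke: float, survival_times, M: int) -> DamageTrajectory:
    """Refine the observation times to an M-point grid and solve for damage."""
    tau, dtau = refine_time_grid(survival_times, M)
    return DamageTrajectory(tau=tau, D=damage_on_grid(exposure, ke, tau), dtau=dtau)
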