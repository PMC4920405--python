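"""Domain types for threshold-hazard survival modelling.

A survival assay couples a time-varying exposure record (concentration
measurements, linearly interpolated in between) with a series of survivor
counts observed on the same clock.  Model flavours differ in how the
per-individual tolerance threshold is distributed and in whether death
above the threshold is instantaneous:

* ``dist="lognormal", model="proper"`` — full model: lognormal threshold
  distribution and a finite killing rate (parameters hb, ke, kk, mn, sd).
* ``dist="delta", model="proper"`` — stochastic death (SD): every
  individual shares the threshold ``mn`` (no sd).
* ``dist="lognormal", model="it"`` — individual tolerance (IT): an
  individual dies the moment damage first exceeds its personal threshold,
  i.e. the killing rate is infinite (no kk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "ParameterArityError",
    "ExposureSeries",
    "SurvivalSeries",
    "SurvivalExperiment",
    "ModelConfig",
    "ParameterSet",
    "make_experiment",
    "check_parameters",
    "parameter_names",
]


class ValidationError(ValueError):
    """An input violates a construction-time invariant."""


class ParameterArityError(ValueError):
    """The parameter vector length does not match the model flavour."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class ExposureSeries:
    """Measured exposure concentrations at strictly increasing times.

    Concentration between measurement points is linearly interpolated;
    beyond the last measurement it is held constant at the last value.
    """

    conc: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        conc = _as_float_array(self.conc, "conc")
        times = _as_float_array(self.times, "times")
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "times", times)
        if len(conc) != len(times):
            raise ValidationError(
                "exposure concentrations and times must have equal length "
                f"({len(conc)} != {len(times)})"
            )
        if len(times) < 2:
            raise ValidationError("exposure series needs at least 2 points")
        if times[0] != 0.0:
            raise ValidationError("exposure times must start at 0")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("exposure times must be strictly increasing")
        if np.any(conc < 0):
            raise ValidationError("exposure concentrations must be non-negative")
        if not np.all(np.isfinite(conc)) or not np.all(np.isfinite(times)):
            raise ValidationError("exposure series must be finite")


@dataclass(frozen=True)
class SurvivalSeries:
    """Survivor counts at strictly increasing observation times."""

    counts: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        counts_raw = np.asarray(self.counts)
        counts = np.asarray(counts_raw, dtype=float)
        times = _as_float_array(self.times, "times")
        if np.any(counts != np.floor(counts)):
            raise ValidationError("survivor counts must be integers")
        counts = counts.astype(int)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "times", times)
        if len(counts) != len(times):
            raise ValidationError(
                "survivor counts and times must have equal length "
                f"({len(counts)} != {len(times)})"
            )
        if len(times) < 2:
            raise ValidationError("survival series needs at least 2 points")
        if times[0] != 0.0:
            raise ValidationError("observation times must start at 0")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("observation times must be strictly increasing")
        if counts[0] < 1:
            raise ValidationError("initial survivor count must be at least 1")
        if np.any(counts < 0):
            raise ValidationError("survivor counts must be non-negative")
        if np.any(np.diff(counts) > 0):
            raise ValidationError("survivor counts must be non-increasing")

    @property
    def n0(self) -> int:
        return int(self.counts[0])


@dataclass(frozen=True)
class SurvivalExperiment:
    """One assay: an exposure record plus a survivor-count series.

    Both series share the same time origin (t = 0).  Observation times are
    allowed to run past the last exposure measurement; the exposure is then
    extrapolated as constant at its last measured value.
    """

    exposure: ExposureSeries
    survival: SurvivalSeries
    label: str = ""

    @property
    def n_windows(self) -> int:
        """Number of observation windows (t_{i-1}, t_i]."""
        return len(self.survival.times) - 1


#: canonical ordering of the full parameter vector
_FULL_ORDER = ("hb", "ke", "kk", "mn", "sd")


def parameter_names(config: "ModelConfig") -> tuple[str, ...]:
    """Parameter names, in order, for the given model flavour."""
    names = list(_FULL_ORDER)
    if config.model == "it":
        names.remove("kk")
    if config.dist == "delta":
        names.remove("sd")
    return tuple(names)


@dataclass(frozen=True)
class ModelConfig:
    """Model flavour plus discretisation sizes.

    N is the number of points on the threshold axis (sample or grid) and M
    the number of points of the refined time grid.
    """

    dist: str = "lognormal"
    model: str = "proper"
    N: int = 1000
    M: int = 10000

    def __post_init__(self):
        if self.dist not in ("lognormal", "delta"):
            raise ValidationError(f"unknown threshold distribution {self.dist!r}")
        if self.model not in ("proper", "it"):
            raise ValidationError(f"unknown model {self.model!r}")
        if self.dist == "delta" and self.model != "proper":
            raise ValidationError(
                "the delta distribution (stochastic death) requires model='proper'"
            )
        if self.N < 1 or self.M < 1:
            raise ValidationError("N and M must be positive")

    @property
    def n_params(self) -> int:
        return len(parameter_names(self))


@dataclass(frozen=True)
class ParameterSet:
    """Model parameters (units: rates in 1/day, thresholds in damage units).

    ``kk`` is None for the IT flavour (implicitly infinite), ``sd`` is None
    for the delta distribution (point mass at ``mn``).
    """

    hb: float
    ke: float
    mn: float
    kk: float | None = None
    sd: float | None = None

    @classmethod
    def from_vector(cls, values: Sequence[float], config: ModelConfig) -> "ParameterSet":
        names = parameter_names(config)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(names),):
            raise ParameterArityError(
                f"{config.dist}/{config.model} expects {len(names)} parameters "
                f"{names}, got {values.size}"
            )
        d = dict(zip(names, values.tolist()))
        return cls(hb=d["hb"], ke=d["ke"], mn=d["mn"],
                   kk=d.get("kk"), sd=d.get("sd"))

    def to_vector(self, config: ModelConfig) -> np.ndarray:
        vals = []
        for name in parameter_names(config):
            v = getattr(self, name)
            if v is None:
                raise ParameterArityError(f"parameter {name!r} required but missing")
            vals.append(v)
        return np.asarray(vals, dtype=float)

    def is_proper(self) -> bool:
        vals = [v for v in (self.hb, self.ke, self.kk, self.mn, self.sd) if v is not None]
        arr = np.asarray(vals, dtype=float)
        return bool(np.all(np.isfinite(arr)) and np.all(arr >= 0))


def make_experiment(conc, conc_times, counts, count_times, label: str = "") -> SurvivalExperiment:
    """Build a validated :class:`SurvivalExperiment` from raw vectors."""
    exposure = ExposureSeries(conc=conc, times=conc_times)
    survival = SurvivalSeries(counts=counts, times=count_times)
    return SurvivalExperiment(exposure=exposure, survival=survival, label=label)


def check_parameters(params, config: ModelConfig) -> str:
    """Classify a raw parameter vector for a model flavour.

    Returns ``"proper"``, ``"improper"`` (negative, NaN or infinite values)
    or ``"wrong_arity"`` (length mismatch).  Never raises on numeric input.
    """
    if isinstance(params, ParameterSet):
        try:
            params = params.to_vector(config)
        except ParameterArityError:
            return "wrong_arity"
    arr = np.atleast_1d(np.asarray(params, dtype=float))
    if arr.shape != (config.n_params,):
        return "wrong_arity"
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        return "improper"
    return "proper"
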