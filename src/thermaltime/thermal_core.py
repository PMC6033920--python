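"""Thermal-time (growing degree day) computation.

Four methods for converting air temperature into daily thermal time (DTT,
°C·d) are provided, all parameterised by the same triple of cardinal
temperatures (base ``T_b``, optimum ``T_opt``, upper threshold ``T_u``):

``method1``
    Linear response to the daily mean temperature ``T_avg = (T_max+T_min)/2``,
    zero below ``T_b`` and saturating at ``T_u − T_b`` above ``T_u``.
``method2``
    As ``method1``, but ``T_max``/``T_min`` are first clamped into
    ``[T_b, T_u]`` before averaging; the branch (zero / linear / saturated)
    is still selected by the unclamped mean.
``method3``
    Bilinear hourly response: rises linearly from ``T_b`` to a sharp peak of
    ``T_opt − T_b`` at ``T_opt``, falls linearly to zero at ``T_u``.  Daily
    DTT is the mean of the 24 hourly values.
``bfm``
    Beta-distribution-function method: a smooth, asymmetric hourly response

    .. math::

        HTT(T_h) = \\frac{T_h - T_b}{T_{opt} - T_b}
                   \\left(\\frac{T_u - T_h}{T_u - T_{opt}}\\right)
                   ^{\\frac{T_u - T_{opt}}{T_{opt} - T_b}} (T_{opt} - T_b)

    which is zero at ``T_b`` and ``T_u`` and attains its maximum
    ``T_opt − T_b`` only at ``T_opt``.  Daily DTT is again the 24-hour mean.

Hourly temperatures are obtained from daily extremes by a pluggable
disaggregation scheme (default: single cosine wave peaking at 14:00), or can
be supplied directly when true hourly records exist.

All temperature functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "InvalidWeatherError",
    "CardinalTemps",
    "Phase",
    "CropParams",
    "ThermalSeries",
    "CORN",
    "WINTER_WHEAT",
    "SPRING_WHEAT",
    "CROPS",
    "get_crop",
    "METHODS",
    "daily_average",
    "dtt_method1",
    "dtt_method2",
    "htt_method3",
    "dev_rate_beta",
    "htt_bfm",
    "hourly_from_daily",
    "dtt_from_hourly",
    "daily_dtt",
    "dtt_series",
    "gdd_accumulate",
]


class ParameterError(ValueError):
    """Invalid cardinal temperatures or other model parameters."""


class InvalidWeatherError(ValueError):
    """Weather record violating t_min <= t_max or date ordering."""


@dataclass(frozen=True)
class CardinalTemps:
    """Cardinal temperatures (°C) of a developmental response.

    ``t_base < t_opt < t_upper`` is enforced strictly: development stops
    below the base and above the upper threshold and is fastest at the
    optimum.
    """

    t_base: float
    t_opt: float
    t_upper: float

    def __post_init__(self) -> None:
        if not (self.t_base < self.t_opt < self.t_upper):
            raise ParameterError(
                f"cardinal temperatures must satisfy t_base < t_opt < t_upper, "
                f"got ({self.t_base}, {self.t_opt}, {self.t_upper})"
            )

    @property
    def beta_exponent(self) -> float:
        """Exponent (T_u − T_opt)/(T_opt − T_b) of the beta response."""
        return (self.t_upper - self.t_opt) / (self.t_opt - self.t_base)

    def shifted(self, cardinal: str, delta: float) -> "CardinalTemps":
        """Return a copy with one cardinal temperature shifted by ``delta`` °C.

        Raises :class:`ParameterError` if the shift breaks the strict
        ordering — callers doing sensitivity scans catch and report this.
        """
        if cardinal not in ("t_base", "t_opt", "t_upper"):
            raise ParameterError(f"unknown cardinal temperature {cardinal!r}")
        kwargs = {
            "t_base": self.t_base,
            "t_opt": self.t_opt,
            "t_upper": self.t_upper,
        }
        kwargs[cardinal] += delta
        return CardinalTemps(**kwargs)


@dataclass(frozen=True)
class Phase:
    """One developmental phase of a crop.

    ``ends_at`` is the phenological stage at which the next phase takes
    over (``None`` for the final phase).
    """

    name: str
    cardinal: CardinalTemps
    ends_at: str | None = None


@dataclass(frozen=True)
class CropParams:
    """Crop parameter set: ordered phases and the stage vocabulary.

    ``stages`` lists observable stages in developmental order (sowing is
    implicit and not listed).  Phase boundaries must appear in ``stages``.
    """

    name: str
    phases: tuple[Phase, ...]
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ParameterError("a crop needs at least one phase")
        boundaries = [p.ends_at for p in self.phases[:-1]]
        if any(b is None for b in boundaries):
            raise ParameterError("only the final phase may lack a boundary stage")
        if self.phases[-1].ends_at is not None:
            raise ParameterError("the final phase must not name a boundary stage")
        idx = []
        for b in boundaries:
            if b not in self.stages:
                raise ParameterError(f"phase boundary {b!r} not in stage list")
            idx.append(self.stages.index(b))
        if idx != sorted(set(idx)):
            raise ParameterError("phase boundaries must be distinct and ordered")

    @property
    def multiphase(self) -> bool:
        return len(self.phases) > 1

    def stage_index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise ParameterError(
                f"unknown stage {stage!r} for crop {self.name!r}"
            ) from None

    def perturbed(self, cardinal: str, delta: float) -> "CropParams":
        """Shift one cardinal temperature by ``delta`` in every phase."""
        return CropParams(
            name=self.name,
            phases=tuple(
                Phase(p.name, p.cardinal.shifted(cardinal, delta), p.ends_at)
                for p in self.phases
            ),
            stages=self.stages,
        )


# Shipped crop parameter sets.  Corn: 8/33/40 °C.  Winter wheat switches
# cardinal sets at heading: vegetative 0/24/45 °C, reproductive 8/29/40 °C.
# Spring wheat: 0/24/42 °C for the whole cycle.
CORN = CropParams(
    name="corn",
    phases=(Phase("whole", CardinalTemps(8.0, 33.0, 40.0)),),
    stages=(
        "emergence",
        "3rd leaf",
        "7th leaf",
        "jointing",
        "tasseling",
        "milk",
        "maturity",
    ),
)

WINTER_WHEAT = CropParams(
    name="winter wheat",
    phases=(
        Phase("vegetative", CardinalTemps(0.0, 24.0, 45.0), ends_at="heading"),
        Phase("reproductive", CardinalTemps(8.0, 29.0, 40.0)),
    ),
    stages=("emergence", "jointing", "heading", "milk", "maturity"),
)

SPRING_WHEAT = CropParams(
    name="spring wheat",
    phases=(Phase("whole", CardinalTemps(0.0, 24.0, 42.0)),),
    stages=("emergence", "jointing", "heading", "milk", "maturity"),
)

CROPS: dict[str, CropParams] = {
    "corn": CORN,
    "winter-wheat": WINTER_WHEAT,
    "spring-wheat": SPRING_WHEAT,
}

METHODS: tuple[str, ...] = ("method1", "method2", "method3", "bfm")


def get_crop(name: str) -> CropParams:
    """Look up a shipped crop parameter set by registry key."""
    try:
        return CROPS[name]
    except KeyError:
        raise ParameterError(
            f"unknown crop {name!r}; available: {sorted(CROPS)}"
        ) from None


# ---------------------------------------------------------------------------
# scalar/array plumbing

def _prep(t) -> tuple[np.ndarray, bool]:
    arr = np.asarray(t, dtype=float)
    return arr, arr.ndim == 0


def _ret(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def _check_weather(t_max, t_min) -> None:
    if np.any(np.asarray(t_min, float) > np.asarray(t_max, float)):
        raise InvalidWeatherError("t_min exceeds t_max")


# ---------------------------------------------------------------------------
# daily methods (1 and 2)

def daily_average(t_max, t_min):
    """Daily mean temperature (T_max + T_min)/2 in °C."""
    _check_weather(t_max, t_min)
    tmax, s1 = _prep(t_max)
    tmin, s2 = _prep(t_min)
    return _ret((tmax + tmin) / 2.0, s1 and s2)


def dtt_method1(t_max, t_min, ct: CardinalTemps):
    """Daily thermal time, linear in the daily mean temperature.

    Zero below ``t_base``, ``T_avg − t_base`` between the thresholds,
    saturating at ``t_upper − t_base``.
    """
    _check_weather(t_max, t_min)
    tmax, s1 = _prep(t_max)
    tmin, s2 = _prep(t_min)
    tavg = (tmax + tmin) / 2.0
    out = np.select(
        [tavg < ct.t_base, tavg > ct.t_upper],
        [0.0, ct.t_upper - ct.t_base],
        default=tavg - ct.t_base,
    )
    return _ret(out, s1 and s2)


def dtt_method2(t_max, t_min, ct: CardinalTemps):
    """Daily thermal time with extremes clamped into [t_base, t_upper].

    ``T_m = min(T_max, t_upper)`` and ``T_n = max(T_min, t_base)`` are
    averaged in the middle branch; which branch applies is decided by the
    unclamped daily mean, so methods 1 and 2 agree whenever the whole day
    lies inside the thresholds.
    """
    _check_weather(t_max, t_min)
    tmax, s1 = _prep(t_max)
    tmin, s2 = _prep(t_min)
    tavg = (tmax + tmin) / 2.0
    t_m = np.minimum(tmax, ct.t_upper)
    t_n = np.maximum(tmin, ct.t_base)
    clamped_avg = (t_m + t_n) / 2.0
    out = np.select(
        [tavg < ct.t_base, tavg > ct.t_upper],
        [0.0, ct.t_upper - ct.t_base],
        default=clamped_avg - ct.t_base,
    )
    return _ret(out, s1 and s2)


# ---------------------------------------------------------------------------
# hourly responses (method 3 and BFM)

def htt_method3(t_h, ct: CardinalTemps):
    """Hourly thermal time with a bilinear (triangular) response.

    Rises as ``t_h − t_base`` up to ``t_opt``, then falls along
    ``(t_opt−t_base)/(t_upper−t_opt) · (t_upper − t_h)``; zero outside
    ``[t_base, t_upper]``.
    """
    th, scalar = _prep(t_h)
    slope = (ct.t_opt - ct.t_base) / (ct.t_upper - ct.t_opt)
    out = np.select(
        [
            th < ct.t_base,
            th <= ct.t_opt,
            th <= ct.t_upper,
        ],
        [
            0.0,
            th - ct.t_base,
            slope * (ct.t_upper - th),
        ],
        default=0.0,
    )
    return _ret(out, scalar)


def _beta_shape(t_h, ct: CardinalTemps):
    """Beta response shape: 1 at t_opt, 0 at and outside the thresholds."""
    th, scalar = _prep(t_h)
    inside = (th >= ct.t_base) & (th <= ct.t_upper)
    # evaluate at t_opt where outside to avoid fractional powers of negatives
    safe = np.where(inside, th, ct.t_opt)
    rise = (safe - ct.t_base) / (ct.t_opt - ct.t_base)
    fall = (ct.t_upper - safe) / (ct.t_upper - ct.t_opt)
    out = np.where(inside, rise * fall**ct.beta_exponent, 0.0)
    return _ret(out, scalar)


def dev_rate_beta(t_h, ct: CardinalTemps, r_max: float):
    """Developmental rate r(T) = R_max · beta shape term.

    ``r_max`` is the maximal developmental rate (1/time), attained at
    ``t_opt``; the rate is zero outside ``[t_base, t_upper]``.
    """
    if r_max <= 0:
        raise ParameterError(f"r_max must be positive, got {r_max}")
    shape = _beta_shape(t_h, ct)
    return r_max * shape


def htt_bfm(t_h, ct: CardinalTemps):
    """Hourly thermal time under the beta-distribution-function method.

    The beta shape term scaled by ``t_opt − t_base``, so the thermal-time
    contribution is zero at both thresholds and maximal (``t_opt − t_base``)
    exactly at the optimum.
    """
    return _beta_shape(t_h, ct) * (ct.t_opt - ct.t_base)


# ---------------------------------------------------------------------------
# daily <-> hourly

def _cosine_profile(t_max, t_min, peak_hour: float = 14.0) -> np.ndarray:
    tmax = np.asarray(t_max, float)
    tmin = np.asarray(t_min, float)
    hours = np.arange(24.0)
    tavg = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0
    return (
        tavg[..., None]
        + amp[..., None] * np.cos(2.0 * np.pi * (hours - peak_hour) / 24.0)
    )


_SCHEMES: dict[str, Callable[..., np.ndarray]] = {"cosine": _cosine_profile}


class ConfigError(ValueError):
    """Unknown scheme / option name in configuration."""


def hourly_from_daily(t_max, t_min, scheme: str = "cosine", **kwargs) -> np.ndarray:
    """Disaggregate daily extremes into a 24-value hourly profile.

    The default ``cosine`` scheme is a single diurnal wave
    ``T_avg + (T_max−T_min)/2 · cos(2π(h − peak)/24)`` with the maximum at
    ``peak_hour`` (default 14:00) and the minimum 12 h earlier (02:00).
    Arrays of daily extremes produce a ``(n_days, 24)`` array.
    """
    _check_weather(t_max, t_min)
    try:
        fn = _SCHEMES[scheme]
    except KeyError:
        raise ConfigError(
            f"unknown disaggregation scheme {scheme!r}; available: {sorted(_SCHEMES)}"
        ) from None
    return fn(t_max, t_min, **kwargs)


_HOURLY_FNS: dict[str, Callable] = {"method3": htt_method3, "bfm": htt_bfm}


def dtt_from_hourly(profile, ct: CardinalTemps, hourly_fn: Callable | str = htt_bfm):
    """Daily thermal time as the mean of 24 hourly contributions.

    ``hourly_fn`` is :func:`htt_method3`, :func:`htt_bfm` or their method
    names.  ``profile`` must have 24 values along its last axis.
    """
    if isinstance(hourly_fn, str):
        try:
            hourly_fn = _HOURLY_FNS[hourly_fn]
        except KeyError:
            raise ConfigError(f"unknown hourly method {hourly_fn!r}") from None
    prof = np.asarray(profile, dtype=float)
    if prof.shape[-1] != 24:
        raise ValueError(
            f"hourly profile must have 24 values, got shape {prof.shape}"
        )
    htt = hourly_fn(prof, ct)
    return np.asarray(htt).mean(axis=-1)


def daily_dtt(
    t_max,
    t_min,
    ct: CardinalTemps,
    method: str,
    scheme: str = "cosine",
    **scheme_kwargs,
):
    """Daily thermal time under any of the four methods.

    Methods 3 and BFM disaggregate the daily extremes into an hourly
    profile first; methods 1 and 2 work on the daily mean directly.
    """
    if method == "method1":
        return dtt_method1(t_max, t_min, ct)
    if method == "method2":
        return dtt_method2(t_max, t_min, ct)
    if method in ("method3", "bfm"):
        profile = hourly_from_daily(t_max, t_min, scheme=scheme, **scheme_kwargs)
        return dtt_from_hourly(profile, ct, method)
    raise ConfigError(f"unknown method {method!r}; available: {METHODS}")


def dtt_series(weather: pd.DataFrame, ct: CardinalTemps, method: str, **kw) -> np.ndarray:
    """Per-day DTT for a weather frame with ``tmax``/``tmin`` columns."""
    return np.atleast_1d(
        daily_dtt(weather["tmax"].to_numpy(), weather["tmin"].to_numpy(), ct, method, **kw)
    )


# ---------------------------------------------------------------------------
# accumulation

@dataclass
class ThermalSeries:
    """Per-day thermal time and its running total under one method."""

    method: str
    dtt: np.ndarray
    gdd: np.ndarray = field(default=None)  # type: ignore[assignment]
    dates: pd.DatetimeIndex | None = None

    def __post_init__(self) -> None:
        self.dtt = np.asarray(self.dtt, dtype=float)
        if self.gdd is None:
            self.gdd = np.cumsum(self.dtt)

    @property
    def total(self) -> float:
        return float(self.gdd[-1]) if len(self.gdd) else 0.0

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"dtt": self.dtt, "gdd": self.gdd})
        frame.insert(0, "method", self.method)
        if self.dates is not None:
            frame.insert(0, "date", self.dates)
        return frame


def gdd_accumulate(
    dtts: Sequence[float] | np.ndarray,
    method: str = "unspecified",
    dates: pd.DatetimeIndex | None = None,
) -> ThermalSeries:
    """Accumulate daily thermal time into cumulative GDD.

    Thermal time is non-negative by construction in all four methods; a
    negative input indicates an upstream bug and is rejected.
    """
    arr = np.asarray(dtts, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError(f"negative daily thermal time: min {arr.min()}")
    return ThermalSeries(method=method, dtt=arr, dates=dates)
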