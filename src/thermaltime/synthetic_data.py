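"""Synthetic weather, phenology and dry-matter fixtures with known truth.

Every downstream module is testable without any external archive: daily
Tmax/Tmin series come from an annual sinusoid plus AR(1) noise, stage dates
are generated by inverting a chosen thermal-time method against known GDD
thresholds, and dry-matter observations follow a logistic curve with known
coefficients.  Each generated study carries a :class:`GroundTruth` sidecar
so recovery tests read the truth from the fixture, never from constants
baked into the tests.

Two climate presets are shipped:

``arid-hot``
    A continental-desert growing season (large annual cycle, wide diurnal
    range): summer hours frequently exceed the wheat optimum of 24 °C, the
    regime in which linear GDD methods become inconsistent from year to
    year.
``temperate-mild``
    A mild temperate climate in which daily maxima rarely exceed the corn
    optimum of 33 °C, the regime in which all four methods behave almost
    identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phenology_eval as pe
from .dry_matter import logistic
from .thermal_core import CropParams, get_crop

__all__ = [
    "ClimatePreset",
    "PRESETS",
    "GroundTruth",
    "DEFAULT_STAGE_DAYS",
    "DEFAULT_SOWING",
    "generate_weather",
    "thresholds_from_days",
    "make_truth",
    "generate_phenology",
    "generate_dry_matter",
]


@dataclass(frozen=True)
class ClimatePreset:
    """Parameters of the stochastic daily-weather generator.

    Daily mean temperature is ``annual_mean + annual_amplitude ·
    sin(2π(doy − phase)/365)`` plus stationary AR(1) noise with marginal
    standard deviation ``noise_sd`` and lag-1 autocorrelation ``noise_ar``;
    the phase puts the annual minimum in mid-January.  Tmax/Tmin are the
    daily mean ± half a jittered diurnal range (floored at 0.5 °C).
    """

    name: str
    annual_mean: float
    annual_amplitude: float
    diurnal_range_mean: float
    noise_sd: float
    noise_ar: float = 0.6
    phase_doy: float = 106.25  # minimum near January 15

    def __post_init__(self) -> None:
        if self.diurnal_range_mean <= 0:
            raise ValueError("diurnal range mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not (0 <= self.noise_ar < 1):
            raise ValueError("noise autocorrelation must be in [0, 1)")


PRESETS: dict[str, ClimatePreset] = {
    "arid-hot": ClimatePreset(
        name="arid-hot",
        annual_mean=15.0,
        annual_amplitude=16.0,
        diurnal_range_mean=14.0,
        noise_sd=2.5,
    ),
    "temperate-mild": ClimatePreset(
        name="temperate-mild",
        annual_mean=13.5,
        annual_amplitude=9.0,
        diurnal_range_mean=8.0,
        noise_sd=1.5,
    ),
}

# Canonical mean days-after-sowing per stage used to place realistic GDD
# thresholds on whatever method scale a study generates under.
DEFAULT_STAGE_DAYS: dict[str, dict[str, int]] = {
    "corn": {
        "emergence": 8,
        "3rd leaf": 14,
        "7th leaf": 27,
        "jointing": 36,
        "tasseling": 56,
        "milk": 77,
        "maturity": 103,
    },
    "spring-wheat": {
        "emergence": 24,
        "jointing": 55,
        "heading": 75,
        "milk": 95,
        "maturity": 109,
    },
    "winter-wheat": {
        "emergence": 10,
        "jointing": 122,
        "heading": 157,
        "milk": 186,
        "maturity": 209,
    },
}

DEFAULT_SOWING: dict[str, tuple[int, int]] = {
    "corn": (5, 1),
    "spring-wheat": (3, 25),
    "winter-wheat": (10, 10),
}


@dataclass
class GroundTruth:
    """Everything a recovery test needs to invert a generated fixture."""

    crop: str
    method: str
    thresholds: dict[str, float]
    sowing: tuple[int, int]
    logistic_a: float = 5.0
    logistic_b: float = -0.005
    seed: int = 0

    def __post_init__(self) -> None:
        crop = get_crop(self.crop)
        order = [s for s in crop.stages if s in self.thresholds]
        vals = [self.thresholds[s] for s in order]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("stage thresholds must be strictly increasing")

    def to_json(self, path) -> None:
        data = asdict(self)
        data["sowing"] = list(self.sowing)
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        data["sowing"] = tuple(data["sowing"])
        return cls(**data)


def generate_weather(
    preset: ClimatePreset | str,
    years: int,
    seed: int,
    start_year: int = 2000,
) -> pd.DataFrame:
    """Daily weather (date, tmax, tmin) for ``years`` calendar years.

    Reproducible from ``seed``; with ``noise_sd = 0`` the series is exactly
    periodic and identical across seeds.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + years - 1}-12-31", freq="D"
    )
    doy = dates.dayofyear.to_numpy(dtype=float)
    clim = preset.annual_mean + preset.annual_amplitude * np.sin(
        2.0 * np.pi * (doy - preset.phase_doy) / 365.0
    )
    n = len(dates)
    noise = np.zeros(n)
    if preset.noise_sd > 0:
        z = rng.standard_normal(n)
        innov_sd = preset.noise_sd * np.sqrt(1.0 - preset.noise_ar**2)
        noise[0] = preset.noise_sd * z[0]
        for i in range(1, n):
            noise[i] = preset.noise_ar * noise[i - 1] + innov_sd * z[i]
    tavg = clim + noise
    # range jitter is part of the stochastic component: noise_sd = 0 is the
    # fully deterministic limit (exactly periodic, seed-independent)
    if preset.noise_sd > 0:
        jitter = 0.15 * preset.diurnal_range_mean * rng.standard_normal(n)
    else:
        jitter = 0.0
    diurnal = np.maximum(0.5, preset.diurnal_range_mean + jitter)
    return pd.DataFrame(
        {"date": dates, "tmax": tavg + diurnal / 2.0, "tmin": tavg - diurnal / 2.0}
    )


def thresholds_from_days(
    weather: pd.DataFrame,
    sowing_date,
    crop: CropParams,
    method: str,
    stage_days: dict[str, int],
) -> dict[str, float]:
    """GDD thresholds that place the stages at given days in one season.

    Evaluates the cumulative GDD of the season starting at ``sowing_date``
    under ``method`` and reads it off at each stage's day-after-sowing.
    This puts ground-truth thresholds on the natural scale of whichever
    method a study generates under.
    """
    horizon = max(stage_days.values())
    window = pe._season_weather(weather, sowing_date, horizon)
    switch = {
        p.ends_at: stage_days[p.ends_at]
        for p in crop.phases[:-1]
        if p.ends_at in stage_days
    }
    cum = np.cumsum(pe._phase_dtt(window, crop, method, switch))
    return {s: float(cum[d - 1]) for s, d in stage_days.items()}


def make_truth(
    weather: pd.DataFrame,
    crop_key: str,
    method: str,
    seed: int = 0,
    stage_days: dict[str, int] | None = None,
    logistic_a: float = 5.0,
    logistic_b: float = -0.005,
    reference_year: int | None = None,
) -> GroundTruth:
    """Build a :class:`GroundTruth` with thresholds anchored in real days.

    The thresholds are taken from the first full season of ``weather`` (or
    ``reference_year``) so that the canonical stage days land mid-season
    regardless of the generating method's scale.
    """
    crop = get_crop(crop_key)
    stage_days = stage_days or DEFAULT_STAGE_DAYS[crop_key]
    month, day = DEFAULT_SOWING[crop_key]
    year = reference_year or int(pd.Timestamp(weather["date"].iloc[0]).year)
    sowing = pd.Timestamp(year=year, month=month, day=day)
    thresholds = thresholds_from_days(weather, sowing, crop, method, stage_days)
    return GroundTruth(
        crop=crop_key,
        method=method,
        thresholds=thresholds,
        sowing=(month, day),
        logistic_a=logistic_a,
        logistic_b=logistic_b,
        seed=seed,
    )


def generate_phenology(
    weather: pd.DataFrame,
    truth: GroundTruth,
    station: str = "synthetic",
    jitter_days: int = 0,
    seed: int | None = None,
    horizon: int = 400,
) -> tuple[pd.DataFrame, list[dict]]:
    """Observed-style phenology records by inverting the truth thresholds.

    For every season whose window fits inside ``weather``, each stage date
    is the first day the cumulative GDD (under the truth's generating
    method) reaches that stage's threshold.  Optional uniform ±``jitter_days``
    observation noise is applied per stage, with developmental order
    restored by a running maximum.  Seasons in which any threshold is never
    reached are skipped and reported in the second return value.
    """
    crop = get_crop(truth.crop)
    month, day = truth.sowing
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    years = sorted({ts.year for ts in pd.DatetimeIndex(weather["date"])})
    rows: list[dict] = []
    skipped: list[dict] = []
    order = [s for s in crop.stages if s in truth.thresholds]
    for year in years:
        sowing = pd.Timestamp(year=year, month=month, day=day)
        if sowing < weather["date"].min():
            continue
        try:
            days = {
                stage: pe.predict_stage_date(
                    weather,
                    sowing,
                    truth.thresholds[stage],
                    truth.method,
                    crop,
                    boundary_requirements=truth.thresholds,
                    horizon=horizon,
                )
                for stage in order
            }
        except pe.GapError as exc:
            skipped.append({"season_year": year, "reason": str(exc)})
            continue
        if any(d is None for d in days.values()):
            missing = [s for s, d in days.items() if d is None]
            skipped.append(
                {"season_year": year, "reason": f"threshold not reached: {missing}"}
            )
            continue
        stage_days = np.array([days[s] for s in order], dtype=int)
        if jitter_days:
            stage_days = stage_days + rng.integers(
                -jitter_days, jitter_days + 1, size=len(order)
            )
            stage_days = np.maximum.accumulate(np.maximum(stage_days, 1))
        rows.append(
            {
                "station": station,
                "crop": truth.crop,
                "season_year": year,
                "stage": "sowing",
                "date": sowing,
            }
        )
        for stage, d in zip(order, stage_days):
            rows.append(
                {
                    "station": station,
                    "crop": truth.crop,
                    "season_year": year,
                    "stage": stage,
                    "date": sowing + pd.Timedelta(days=int(d)),
                }
            )
    return pd.DataFrame(rows), skipped


def generate_dry_matter(
    gdd_grid,
    a: float,
    b: float,
    noise_sd: float,
    seed: int,
    y_max: float = 1.0,
) -> pd.DataFrame:
    """Dry-matter observations from a logistic curve plus Gaussian noise.

    The normalized curve is clamped to [0, 1] after noising, then scaled by
    ``y_max`` (kg/hm²).  A non-negative ``b`` is allowed but warned about:
    it describes biomass that never increases with thermal time.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if b >= 0:
        warnings.warn("b >= 0 gives a non-increasing biomass curve", stacklevel=2)
    g = np.asarray(gdd_grid, dtype=float)
    rng = np.random.default_rng(seed)
    y = logistic(g, a, b)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=g.shape)
    y = np.clip(y, 0.0, 1.0)
    return pd.DataFrame({"gdd": g, "mass": y * y_max})
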