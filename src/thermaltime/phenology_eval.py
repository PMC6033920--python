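"""Calibration and evaluation of GDD-based phenology prediction.

Given multi-year observed stage dates and daily weather, each thermal-time
method is used as a developmental clock: the GDD accumulated from sowing to
each observed stage is computed per season, the across-year mean becomes the
stage's GDD requirement, and stage dates are predicted as the first day the
running GDD total reaches that requirement.

Method quality is scored the way agronomic model comparisons usually are:

* CV in days — the across-year standard deviation of the stage GDD
  requirement divided by the mean daily GDD since sowing.  It converts the
  spread of thermal-time requirements into a spread of calendar days; a
  method whose clock ticks consistently from year to year has a low CV.
* Willmott's refined index of agreement ``d_r`` in [−1, 1] between observed
  and predicted days after sowing (1 = perfect).
* A sensitivity scan that perturbs one cardinal temperature at a time by
  {−4, −2, −1, +1, +2, +4} °C and recomputes the CVs.

Conventions: sowing day is day 0; a stage observed ``n`` days after sowing
accrues the thermal time of days ``0 .. n−1`` (through the day before the
stage date).  For multi-phase crops (winter wheat) the cardinal set switches
at the observed boundary stage during calibration and at the *predicted*
boundary crossing during prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .thermal_core import (
    METHODS,
    CropParams,
    ParameterError,
    dtt_series,
)

__all__ = [
    "GapError",
    "RecordError",
    "InsufficientDataError",
    "StageRequirement",
    "season_gdd_to_stage",
    "calibrate_requirements",
    "cv_days",
    "cv_percent",
    "requirements_table",
    "predict_stage_date",
    "predicted_dtt_series",
    "evaluate_predictions",
    "dr_by_season",
    "refined_index_dr",
    "sensitivity_table",
    "SENSITIVITY_DELTAS",
]

SENSITIVITY_DELTAS: tuple[float, ...] = (-4.0, -2.0, -1.0, 1.0, 2.0, 4.0)


class GapError(ValueError):
    """Weather series does not cover the requested window contiguously."""


class RecordError(ValueError):
    """Malformed phenology records (missing sowing, stage before sowing...)."""


class InsufficientDataError(ValueError):
    """Fewer seasons than the operation requires."""


# ---------------------------------------------------------------------------
# weather windows and phase-aware DTT

def _season_weather(weather: pd.DataFrame, sowing_date: pd.Timestamp, n_days: int) -> pd.DataFrame:
    """Contiguous daily weather for days 0 .. n_days−1 after sowing."""
    sowing_date = pd.Timestamp(sowing_date)
    end = sowing_date + pd.Timedelta(days=n_days - 1)
    window = weather[(weather["date"] >= sowing_date) & (weather["date"] <= end)]
    if len(window) != n_days:
        raise GapError(
            f"weather covers {len(window)} of {n_days} days from {sowing_date.date()}"
        )
    dates = window["date"].to_numpy()
    if n_days > 1 and not (np.diff(dates) == np.timedelta64(1, "D")).all():
        raise GapError(f"weather has gaps in the window starting {sowing_date.date()}")
    return window


def _phase_dtt(
    weather_window: pd.DataFrame,
    crop: CropParams,
    method: str,
    switch_days: dict[str, int] | None,
) -> np.ndarray:
    """Daily DTT from sowing with cardinal sets switching at known day indices.

    ``switch_days`` maps each phase-boundary stage to its day-after-sowing
    index; days before the index use the earlier phase, the boundary day
    itself starts the later phase.
    """
    n = len(weather_window)
    if not crop.multiphase:
        return dtt_series(weather_window, crop.phases[0].cardinal, method)
    switch_days = switch_days or {}
    dtt = np.empty(n)
    start = 0
    for phase in crop.phases:
        if phase.ends_at is None:
            stop = n
        else:
            if phase.ends_at not in switch_days:
                raise RecordError(
                    f"no boundary day for phase switch at {phase.ends_at!r}"
                )
            stop = min(max(switch_days[phase.ends_at], start), n)
        if stop > start:
            seg = weather_window.iloc[start:stop]
            dtt[start:stop] = dtt_series(seg, phase.cardinal, method)
        start = stop
    return dtt


# ---------------------------------------------------------------------------
# calibration

def _split_season(records: pd.DataFrame) -> tuple[pd.Timestamp, pd.DataFrame]:
    sowing = records[records["stage"] == "sowing"]
    if len(sowing) != 1:
        raise RecordError(
            f"expected exactly one sowing record per season, got {len(sowing)}"
        )
    sowing_date = pd.Timestamp(sowing["date"].iloc[0])
    stages = records[records["stage"] != "sowing"]
    if (pd.to_datetime(stages["date"]) <= sowing_date).any():
        raise RecordError("stage observed on or before the sowing date")
    return sowing_date, stages


def season_gdd_to_stage(
    records: pd.DataFrame,
    weather: pd.DataFrame,
    method: str,
    crop: CropParams,
) -> dict[str, float]:
    """GDD from sowing to each observed stage for a single season.

    ``records`` holds one season's rows (``stage``, ``date``) including the
    sowing row.  Multi-phase crops switch cardinal sets at the observed
    boundary stage; observing a post-boundary stage without the boundary
    itself is a record error.
    """
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}")
    sowing_date, stages = _split_season(records)
    days = {
        str(row.stage): int((pd.Timestamp(row.date) - sowing_date).days)
        for row in stages.itertuples()
    }
    order = {s: i for i, s in enumerate(crop.stages)}
    known = sorted(days, key=lambda s: order.get(s, len(order)))
    if any(s not in order for s in known):
        unknown = [s for s in known if s not in order]
        raise RecordError(f"stages {unknown} not in {crop.name!r} stage list")

    switch_days: dict[str, int] = {}
    for phase in crop.phases[:-1]:
        boundary = phase.ends_at
        later = [s for s in known if order[s] > order[boundary]]
        if boundary in days:
            switch_days[boundary] = days[boundary]
        elif later:
            raise RecordError(
                f"stage(s) {later} observed but phase boundary {boundary!r} missing"
            )

    horizon = max(days.values())
    window = _season_weather(weather, sowing_date, horizon)
    cum = np.cumsum(_phase_dtt(window, crop, method, switch_days))
    return {s: float(cum[days[s] - 1]) for s in known}


@dataclass
class StageRequirement:
    """Across-year GDD requirement of one stage under one method.

    ``mean_daily_gdd`` is the across-year mean of (stage GDD ÷ days after
    sowing) — the mean daily thermal-time accrual since sowing, used to
    convert GDD spread into days.
    """

    stage: str
    gdd_by_year: dict[int, float]
    days_by_year: dict[int, int]

    @property
    def per_year_gdd(self) -> np.ndarray:
        return np.array([self.gdd_by_year[y] for y in sorted(self.gdd_by_year)])

    @property
    def mean_gdd(self) -> float:
        return float(self.per_year_gdd.mean())

    @property
    def sd_gdd(self) -> float:
        return float(self.per_year_gdd.std(ddof=1))

    @property
    def mean_daily_gdd(self) -> float:
        vals = [
            self.gdd_by_year[y] / self.days_by_year[y]
            for y in sorted(self.gdd_by_year)
        ]
        return float(np.mean(vals))

    @property
    def mean_days(self) -> float:
        return float(np.mean([self.days_by_year[y] for y in sorted(self.days_by_year)]))

    @property
    def n_years(self) -> int:
        return len(self.gdd_by_year)


def _season_groups(records: pd.DataFrame):
    required = {"season_year", "stage", "date"}
    missing = required - set(records.columns)
    if missing:
        raise RecordError(f"phenology records missing columns {sorted(missing)}")
    return records.groupby("season_year", sort=True)


def calibrate_requirements(
    records: pd.DataFrame,
    weather: pd.DataFrame,
    method: str,
    crop: CropParams,
) -> dict[str, StageRequirement]:
    """Per-stage GDD requirements calibrated across seasons.

    Requires at least two seasons overall and keeps only stages observed in
    at least two of them (a sample SD needs n ≥ 2).
    """
    groups = _season_groups(records)
    if groups.ngroups < 2:
        raise InsufficientDataError(
            f"calibration needs >= 2 seasons, got {groups.ngroups}"
        )
    gdd_by_stage: dict[str, dict[int, float]] = {}
    days_by_stage: dict[str, dict[int, int]] = {}
    for year, season in groups:
        year = int(year)
        sowing_date, stages = _split_season(season)
        gdds = season_gdd_to_stage(season, weather, method, crop)
        for row in stages.itertuples():
            stage = str(row.stage)
            gdd_by_stage.setdefault(stage, {})[year] = gdds[stage]
            days_by_stage.setdefault(stage, {})[year] = int(
                (pd.Timestamp(row.date) - sowing_date).days
            )
    out: dict[str, StageRequirement] = {}
    for stage in crop.stages:
        if stage in gdd_by_stage and len(gdd_by_stage[stage]) >= 2:
            out[stage] = StageRequirement(
                stage=stage,
                gdd_by_year=gdd_by_stage[stage],
                days_by_year=days_by_stage[stage],
            )
    return out


def cv_days(req: StageRequirement) -> float:
    """Across-year variability of a stage requirement, in days.

    SD of the annual stage GDD divided by the mean daily GDD since sowing
    (°Cd ÷ °Cd/day = days).  Low values mean the method's thermal clock
    places the stage consistently across years.
    """
    denom = req.mean_daily_gdd
    if denom <= 0:
        raise ZeroDivisionError("mean daily GDD must be positive")
    return req.sd_gdd / denom


def cv_percent(cv: float, mean_days_after_sowing: float) -> float:
    """CV in days expressed as a percentage of the mean days after sowing."""
    if mean_days_after_sowing <= 0:
        raise ZeroDivisionError("mean days after sowing must be positive")
    return 100.0 * cv / mean_days_after_sowing


def requirements_table(requirements: dict[str, StageRequirement]) -> pd.DataFrame:
    """Tidy summary of calibrated requirements and their CVs."""
    rows = []
    for stage, req in requirements.items():
        cv = cv_days(req)
        rows.append(
            {
                "stage": stage,
                "n_years": req.n_years,
                "mean_gdd": req.mean_gdd,
                "sd_gdd": req.sd_gdd,
                "mean_daily_gdd": req.mean_daily_gdd,
                "mean_days": req.mean_days,
                "cv_days": cv,
                "cv_percent": cv_percent(cv, req.mean_days),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# prediction

def predicted_dtt_series(
    weather: pd.DataFrame,
    sowing_date,
    crop: CropParams,
    method: str,
    boundary_requirements: dict[str, float] | None = None,
    horizon: int = 400,
) -> np.ndarray:
    """Daily DTT from sowing with phase switches at *predicted* boundaries.

    For multi-phase crops each phase boundary is placed at the first day the
    running total reaches that boundary stage's GDD requirement (prediction
    cannot see observed dates).  A boundary requirement that is never reached
    leaves the earlier phase's cardinal set in force to the horizon.
    """
    sowing_date = pd.Timestamp(sowing_date)
    last = weather["date"].max()
    avail = int((last - sowing_date).days) + 1
    n = min(horizon, avail)
    if n < 1:
        raise GapError(f"no weather on or after sowing date {sowing_date.date()}")
    window = _season_weather(weather, sowing_date, n)
    if not crop.multiphase:
        return dtt_series(window, crop.phases[0].cardinal, method)
    boundary_requirements = boundary_requirements or {}
    switch_days: dict[str, int] = {}
    start = 0
    cum = 0.0
    dtt = np.empty(n)
    for phase in crop.phases:
        stop = n
        seg = dtt_series(window.iloc[start:n], phase.cardinal, method)
        if phase.ends_at is not None:
            req = boundary_requirements.get(phase.ends_at)
            if req is None:
                raise RecordError(
                    f"no GDD requirement for phase boundary {phase.ends_at!r}"
                )
            running = cum + np.cumsum(seg)
            crossed = np.nonzero(running >= req)[0]
            if crossed.size:
                stop = start + int(crossed[0]) + 1
        dtt[start:stop] = seg[: stop - start]
        cum += float(seg[: stop - start].sum())
        if phase.ends_at is not None:
            switch_days[phase.ends_at] = stop
        start = stop
        if start >= n:
            break
    return dtt


def predict_stage_date(
    weather: pd.DataFrame,
    sowing_date,
    requirement: float,
    method: str,
    crop: CropParams,
    boundary_requirements: dict[str, float] | None = None,
    horizon: int = 400,
) -> int | None:
    """First day after sowing on which cumulative GDD reaches ``requirement``.

    Returns the predicted days-after-sowing (the stage date as a day count;
    thermal time accrues through the day before it), or ``None`` when the
    threshold is not reached within the weather window/horizon.
    """
    if requirement <= 0:
        raise ParameterError(f"GDD requirement must be positive, got {requirement}")
    dtt = predicted_dtt_series(
        weather, sowing_date, crop, method, boundary_requirements, horizon
    )
    cum = np.cumsum(dtt)
    crossed = np.nonzero(cum >= requirement)[0]
    if not crossed.size:
        return None
    return int(crossed[0]) + 1


def evaluate_predictions(
    records: pd.DataFrame,
    weather: pd.DataFrame,
    method: str,
    crop: CropParams,
    mode: str = "in-sample",
    horizon: int = 400,
) -> pd.DataFrame:
    """Observed vs predicted days after sowing for every season and stage.

    ``mode='in-sample'`` calibrates requirements on all seasons (the usual
    CV formulation); ``mode='leave-one-year-out'`` recalibrates without the
    season being predicted for an out-of-sample assessment.
    """
    if mode not in ("in-sample", "leave-one-year-out"):
        raise ParameterError(f"unknown evaluation mode {mode!r}")
    groups = _season_groups(records)
    all_reqs = calibrate_requirements(records, weather, method, crop)
    rows = []
    for year, season in groups:
        year = int(year)
        if mode == "leave-one-year-out":
            rest = records[records["season_year"] != year]
            try:
                reqs = calibrate_requirements(rest, weather, method, crop)
            except InsufficientDataError:
                continue
        else:
            reqs = all_reqs
        sowing_date, stages = _split_season(season)
        boundary = {s: r.mean_gdd for s, r in reqs.items()}
        for row in stages.itertuples():
            stage = str(row.stage)
            if stage not in reqs:
                continue
            predicted = predict_stage_date(
                weather,
                sowing_date,
                reqs[stage].mean_gdd,
                method,
                crop,
                boundary_requirements=boundary,
                horizon=horizon,
            )
            rows.append(
                {
                    "season_year": year,
                    "stage": stage,
                    "observed_days": int((pd.Timestamp(row.date) - sowing_date).days),
                    "predicted_days": np.nan if predicted is None else predicted,
                    "crossed": predicted is not None,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# agreement

def refined_index_dr(observed, predicted, c: float = 2.0) -> float:
    """Willmott's refined index of agreement d_r in [−1, 1].

    ``1 − Σ|P−O| / (c·Σ|O−Ō|)`` while the absolute-error sum stays within
    ``c`` times the observed deviation sum, smoothly switching to
    ``c·Σ|O−Ō| / Σ|P−O| − 1`` beyond it.  1 means perfect agreement; values
    fall toward −1 as predictions degrade.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"shape mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 2:
        raise ValueError("d_r needs at least two observations")
    abs_err = float(np.abs(pred - obs).sum())
    obs_dev = float(np.abs(obs - obs.mean()).sum())
    if obs_dev == 0.0:
        raise ZeroDivisionError("observed values are all identical; d_r undefined")
    if abs_err <= c * obs_dev:
        return 1.0 - abs_err / (c * obs_dev)
    return c * obs_dev / abs_err - 1.0


def dr_by_season(predictions: pd.DataFrame, c: float = 2.0) -> pd.DataFrame:
    """d_r computed per season over that season's stages."""
    rows = []
    for year, grp in predictions.dropna(subset=["predicted_days"]).groupby("season_year"):
        if len(grp) < 2 or grp["observed_days"].nunique() < 2:
            continue
        rows.append(
            {
                "season_year": int(year),
                "n_stages": len(grp),
                "dr": refined_index_dr(
                    grp["observed_days"].to_numpy(),
                    grp["predicted_days"].to_numpy(),
                    c=c,
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensitivity analysis

def sensitivity_table(
    records: pd.DataFrame,
    weather: pd.DataFrame,
    methods,
    crop: CropParams,
    stages,
    deltas: tuple[float, ...] = SENSITIVITY_DELTAS,
) -> pd.DataFrame:
    """CV response to perturbing one cardinal temperature at a time.

    Every (cardinal, delta, method, stage) combination is recalibrated with
    the shifted cardinal set (shift applied in every phase).  T_opt rows are
    emitted only for method3/BFM — methods 1 and 2 do not use the optimum.
    A delta-0 control row per combination carries the unperturbed CV.
    Perturbations that break the cardinal ordering are kept as rows with
    status ``skipped`` and an explanatory note.
    """
    if isinstance(methods, str):
        methods = [methods]
    stages = list(stages)
    rows = []
    for method in methods:
        uses_topt = method in ("method3", "bfm")
        cardinals = ["t_base", "t_opt", "t_upper"] if uses_topt else ["t_base", "t_upper"]
        for cardinal in cardinals:
            for delta in (0.0, *deltas):
                try:
                    pcrop = crop.perturbed(cardinal, delta) if delta else crop
                    reqs = calibrate_requirements(records, weather, method, pcrop)
                except ParameterError as exc:
                    for stage in stages:
                        rows.append(
                            {
                                "cardinal": cardinal,
                                "delta": delta,
                                "method": method,
                                "stage": stage,
                                "cv_days": np.nan,
                                "cv_percent": np.nan,
                                "status": "skipped",
                                "note": str(exc),
                            }
                        )
                    continue
                for stage in stages:
                    if stage not in reqs:
                        rows.append(
                            {
                                "cardinal": cardinal,
                                "delta": delta,
                                "method": method,
                                "stage": stage,
                                "cv_days": np.nan,
                                "cv_percent": np.nan,
                                "status": "skipped",
                                "note": "stage not calibrated",
                            }
                        )
                        continue
                    cv = cv_days(reqs[stage])
                    rows.append(
                        {
                            "cardinal": cardinal,
                            "delta": delta,
                            "method": method,
                            "stage": stage,
                            "cv_days": cv,
                            "cv_percent": cv_percent(cv, reqs[stage].mean_days),
                            "status": "ok",
                            "note": "",
                        }
                    )
    return pd.DataFrame(rows)
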