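import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

import thermaltime.synthetic_data as sd
from thermaltime import CORN, CardinalTemps

CORN_CT = CORN.phases[0].cardinal


@pytest.fixture
def corn_ct() -> CardinalTemps:
    return CORN_CT


def make_constant_weather(n_days: int, t_max: float, t_min: float,
                          start: str = "2005-04-01") -> pd.DataFrame:
    """Degenerate weather with identical extremes every day."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame(
        {"date": dates, "tmax": float(t_max), "tmin": float(t_min)}
    )


def make_records(sowing: str, stage_days: dict[str, int], season_year: int,
                 station: str = "test", crop: str = "corn") -> pd.DataFrame:
    """Phenology records for one season from days-after-sowing."""
    sow = pd.Timestamp(sowing)
    rows = [
        {"station": station, "crop": crop, "season_year": season_year,
         "stage": "sowing", "date": sow}
    ]
    for stage, d in stage_days.items():
        rows.append(
            {"station": station, "crop": crop, "season_year": season_year,
             "stage": stage, "date": sow + pd.Timedelta(days=d)}
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def mild_corn_study():
    """Corn seasons in the mild preset, stage dates generated by method 1."""
    weather = sd.generate_weather("temperate-mild", 8, seed=42)
    truth = sd.make_truth(weather, "corn", "method1", seed=42)
    records, skipped = sd.generate_phenology(weather, truth)
    assert not skipped
    return weather, truth, records


@pytest.fixture(scope="session")
def hot_wheat_study():
    """Spring-wheat seasons in the hot preset, stage dates generated by BFM."""
    weather = sd.generate_weather("arid-hot", 10, seed=7)
    truth = sd.make_truth(weather, "spring-wheat", "bfm", seed=7)
    records, skipped = sd.generate_phenology(weather, truth)
    assert not skipped
    return weather, truth, records


def random_cardinals(rng: np.random.Generator) -> CardinalTemps:
    t_base = rng.uniform(-5.0, 15.0)
    t_opt = t_base + rng.uniform(3.0, 25.0)
    t_upper = t_opt + rng.uniform(2.0, 20.0)
    return CardinalTemps(t_base, t_opt, t_upper)
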