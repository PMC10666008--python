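import numpy as np
import pandas as pd
import pytest

from heatwear.synthetic_data import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_sim() -> SimConfig:
    """A small synthetic world for fast pipeline tests."""
    return SimConfig(
        n_participants=6,
        study_days=20,
        missing_steps=0.2,
        missing_sleep=0.2,
        missing_hr_night=0.4,
    )


def random_weather(rng, n_days=5, station="S01", start="2022-02-01",
                   gap_frac=0.0):
    """A random 15-min observation table, optionally with dropped intervals."""
    grid = pd.date_range(start, periods=n_days * 96, freq="15min")
    n = len(grid)
    df = pd.DataFrame(
        {
            "station_id": station,
            "timestamp": grid,
            "air_temp_c": rng.uniform(15.0, 42.0, n).round(2),
            "rel_humidity_pct": rng.uniform(5.0, 100.0, n).round(1),
            "precip_mm": np.where(rng.random(n) < 0.05,
                                  rng.gamma(1.0, 4.0, n), 0.0).round(2),
            "wind_speed_ms": rng.uniform(0.0, 6.0, n).round(2),
            "global_radiation_wm2": rng.uniform(0.0, 900.0, n).round(1),
        }
    )
    if gap_frac:
        keep = rng.random(n) >= gap_frac
        df = df[keep].reset_index(drop=True)
    return df
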