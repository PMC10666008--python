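"""Join cleaned wearable outcomes to exposures and covariates.

Produces the model-ready panel: one row per participant-day (steps with
daytime WBGT_max and daily rainfall) or participant-night (sleep duration
or nighttime heart rate with nighttime HI_min and the night-date's daily
rainfall), plus the demographic and calendar covariates the models adjust
for (month, weekend, age group, sex, BMI group).
"""
from __future__ import annotations

import pandas as pd

from .exposure import GeoPoint, assign_nearest_station, season_of

__all__ = [
    "AGE_GROUPS",
    "BMI_GROUPS",
    "age_group_of",
    "bmi_group_of",
    "derive_covariates",
    "assign_stations",
    "build_panel",
]

AGE_GROUPS = ("young", "middle", "older")
BMI_GROUPS = ("underweight", "healthy", "overweight")


def age_group_of(age: float) -> str:
    """young < 25 <= middle < 65 <= older (half-open intervals)."""
    if age < 25:
        return "young"
    if age < 65:
        return "middle"
    return "older"


def bmi_group_of(bmi: float) -> str:
    """underweight < 18.5 <= healthy < 25 <= overweight."""
    if bmi < 18.5:
        return "underweight"
    if bmi < 25:
        return "healthy"
    return "overweight"


def derive_covariates(roster: pd.DataFrame, study_start) -> pd.DataFrame:
    """Compute age at study start, BMI and group memberships per participant.

    Roster columns: participant_id, sex, birth_date, height_cm, weight_kg,
    village_id.  Age is measured at the study start date; BMI is
    weight [kg] / height [m] squared; both groupings use half-open
    intervals [lo, hi).
    """
    study_start = pd.Timestamp(study_start)
    out = roster.copy()
    if (out["height_cm"] <= 0).any() or (out["weight_kg"] <= 0).any():
        raise ValueError("height and weight must be positive")
    birth = pd.to_datetime(out["birth_date"])
    out["age"] = (study_start - birth).dt.days / 365.25
    out["age_group"] = out["age"].map(age_group_of)
    h_m = out["height_cm"] / 100.0
    out["bmi"] = out["weight_kg"] / (h_m * h_m)
    out["bmi_group"] = out["bmi"].map(bmi_group_of)
    return out


def assign_stations(
    participants: pd.DataFrame,
    villages: pd.DataFrame,
    stations: pd.DataFrame,
) -> pd.DataFrame:
    """Attach each participant's nearest weather station via their village.

    ``villages`` and ``stations`` carry columns (id, lat, lon).  Each
    participant keeps one station for the whole study (home-village
    assignment; mobility is out of scope).
    """
    station_points = [
        (str(r.id), GeoPoint(float(r.lat), float(r.lon)))
        for r in stations.itertuples()
    ]
    village_to_station = {
        str(r.id): assign_nearest_station(
            GeoPoint(float(r.lat), float(r.lon)), station_points
        )
        for r in villages.itertuples()
    }
    out = participants.copy()
    unknown = set(out["village_id"].astype(str)) - set(village_to_station)
    if unknown:
        raise ValueError(f"villages without coordinates: {sorted(unknown)}")
    out["station_id"] = out["village_id"].astype(str).map(village_to_station)
    return out


_COVARIATE_COLS = ["sex", "age", "age_group", "bmi", "bmi_group", "station_id"]


def build_panel(
    outcomes: pd.DataFrame,
    daily_weather: pd.DataFrame,
    participants: pd.DataFrame,
    kind: str,
) -> pd.DataFrame:
    """Left-join outcome rows to station exposures and covariates.

    ``kind`` is ``"day"`` (outcome table has a ``date`` column; joined to
    the same calendar date's daytime exposures) or ``"night"`` (outcome
    table has ``night_date``; joined to that night's exposures — the night
    labelled *d* spans *d* 22:00 to *d*+1 06:00).  Rows lacking exposure
    are retained with missing exposure and dropped listwise at fit time.
    The join never duplicates: output rows == outcome rows.
    """
    if kind not in ("day", "night"):
        raise ValueError("kind must be 'day' or 'night'")
    date_col = "date" if kind == "day" else "night_date"
    if date_col not in outcomes.columns:
        raise ValueError(f"outcome table lacks column {date_col!r}")

    part = participants.set_index("participant_id")
    missing = set(outcomes["participant_id"]) - set(part.index)
    if missing:
        raise ValueError(f"outcomes reference unknown participants: {sorted(missing)}")

    panel = outcomes.merge(
        part[_COVARIATE_COLS],
        left_on="participant_id",
        right_index=True,
        how="left",
        validate="many_to_one",
    )

    exposure_cols = {
        "day": ["wbgt_max_day", "tmax_day", "rain_total", "is_heat_stress_day",
                "is_heavy_rain_day"],
        "night": ["hi_min_night", "tmin_night", "rain_total",
                  "is_heat_stress_night", "is_heavy_rain_day"],
    }[kind]
    weather = daily_weather[["station_id", "date"] + exposure_cols].rename(
        columns={"date": date_col}
    )
    panel[date_col] = pd.to_datetime(panel[date_col])
    weather = weather.assign(**{date_col: pd.to_datetime(weather[date_col])})
    panel = panel.merge(
        weather,
        on=["station_id", date_col],
        how="left",
        validate="many_to_one",
    )

    dt = panel[date_col]
    panel["month"] = dt.dt.month
    panel["weekend"] = dt.dt.dayofweek >= 5  # Saturday, Sunday
    panel["season"] = panel["month"].map(season_of)
    return panel
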