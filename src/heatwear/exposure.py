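"""Weather-station series to daily heat and rainfall exposures.

This module turns raw 15-minute weather observations (air temperature,
relative humidity, precipitation, wind speed, global radiation) into the
exposure variables used downstream:

* per-interval heat metrics — the US National Weather Service heat index
  (HI) and an outdoor wet-bulb globe temperature (WBGT) estimate,
* per station-date summaries over a day window [06:00, 22:00) and a night
  window [22:00, 06:00 next day), where the night labelled with date *d*
  spans *d* 22:00 to *d*+1 06:00,
* extreme-weather index counts (heavy-precipitation days, tropical nights,
  hot days, heat-stress days, heat-stress nights),
* nearest-station assignment for villages on the WGS 84 ellipsoid.

All thresholds come from :class:`~heatwear.thresholds.Thresholds`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .thresholds import DEFAULT_THRESHOLDS, Thresholds

__all__ = [
    "GeoPoint",
    "geodesic_distance",
    "assign_nearest_station",
    "heat_index",
    "stull_wet_bulb",
    "natural_wet_bulb_default",
    "globe_temperature_default",
    "wbgt_estimate",
    "season_of",
    "add_heat_metrics",
    "daily_weather_summary",
    "summarize_daily",
    "extreme_indexes",
]

SEASONS = ("rainy", "cool_dry", "hot_dry")

#: month -> season: rainy Jun-Sep, cool dry Oct-Jan, hot dry Feb-May
_SEASON_BY_MONTH = {
    1: "cool_dry", 2: "hot_dry", 3: "hot_dry", 4: "hot_dry", 5: "hot_dry",
    6: "rainy", 7: "rainy", 8: "rainy", 9: "rainy",
    10: "cool_dry", 11: "cool_dry", 12: "cool_dry",
}


def season_of(month: int) -> str:
    """Map a calendar month (1..12) to the local season.

    Rainy season runs June-September, the cool dry season
    October-January and the hot dry season February-May.
    """
    try:
        return _SEASON_BY_MONTH[int(month)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"month must be an integer in 1..12, got {month!r}")


# ---------------------------------------------------------------------------
# WGS 84 geodesics
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0                  # semi-major axis [m]
_WGS84_F = 1.0 / 298.257223563        # flattening
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)


@dataclass(frozen=True)
class GeoPoint:
    """A point on the WGS 84 ellipsoid in decimal degrees."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude out of range: {self.longitude}")


def geodesic_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Shortest distance between two points on the WGS 84 ellipsoid, in km.

    Vincenty's inverse method; agrees with ellipsoidal reference solutions
    to well below a metre for non-antipodal points, which covers any
    station-to-village assignment within a study region.
    """
    if not isinstance(a, GeoPoint):
        a = GeoPoint(*a)
    if not isinstance(b, GeoPoint):
        b = GeoPoint(*b)
    if a == b:
        return 0.0

    phi1, phi2 = math.radians(a.latitude), math.radians(b.latitude)
    L = math.radians(b.longitude - a.longitude)
    U1 = math.atan((1.0 - _WGS84_F) * math.tan(phi1))
    U2 = math.atan((1.0 - _WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0  # coincident after normalisation
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos_sq_alpha = 1.0 - sin_alpha * sin_alpha
        if cos_sq_alpha == 0.0:
            cos2sigma_m = 0.0  # equatorial line
        else:
            cos2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos_sq_alpha
        C = _WGS84_F / 16.0 * cos_sq_alpha * (
            4.0 + _WGS84_F * (4.0 - 3.0 * cos_sq_alpha)
        )
        lam_prev = lam
        lam = L + (1.0 - C) * _WGS84_F * sin_alpha * (
            sigma
            + C * sin_sigma * (
                cos2sigma_m
                + C * cos_sigma * (-1.0 + 2.0 * cos2sigma_m * cos2sigma_m)
            )
        )
        if abs(lam - lam_prev) < 1e-13:
            break
    else:
        raise RuntimeError(
            "geodesic did not converge (near-antipodal points)"
        )

    u_sq = cos_sq_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1.0 + u_sq / 16384.0 * (
        4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq))
    )
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = B * sin_sigma * (
        cos2sigma_m
        + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos2sigma_m**2)
            - B / 6.0 * cos2sigma_m
            * (-3.0 + 4.0 * sin_sigma**2)
            * (-3.0 + 4.0 * cos2sigma_m**2)
        )
    )
    return _WGS84_B * A * (sigma - delta_sigma) / 1000.0


def assign_nearest_station(
    village: GeoPoint,
    stations: Sequence[tuple[str, GeoPoint]],
) -> str:
    """Return the id of the station nearest to ``village``.

    Ties are broken by lexicographic station id so the assignment is
    deterministic.
    """
    if not stations:
        raise ValueError("at least one station is required")
    best = min(
        stations,
        key=lambda s: (geodesic_distance(village, s[1]), str(s[0])),
    )
    return best[0]


# ---------------------------------------------------------------------------
# Heat index (NWS)
# ---------------------------------------------------------------------------

def _hi_fahrenheit(t_f: float, rh: float) -> float:
    """NWS heat index in degF from temperature [degF] and RH [%].

    Simple-formula branch below 79 degF apparent temperature, otherwise the
    Rothfusz regression with the published low-RH and high-RH adjustments.
    """
    if t_f <= 40.0:
        return t_f
    simple = 0.5 * (t_f + 61.0 + (t_f - 68.0) * 1.2 + rh * 0.094)
    if simple < 79.0:
        return simple
    hi = (
        -42.379
        + 2.04901523 * t_f
        + 10.14333127 * rh
        - 0.22475541 * t_f * rh
        - 6.83783e-3 * t_f * t_f
        - 5.481717e-2 * rh * rh
        + 1.22874e-3 * t_f * t_f * rh
        + 8.5282e-4 * t_f * rh * rh
        - 1.99e-6 * t_f * t_f * rh * rh
    )
    if rh < 13.0 and 80.0 <= t_f <= 112.0:
        hi -= ((13.0 - rh) / 4.0) * math.sqrt(
            (17.0 - abs(t_f - 95.0)) / 17.0
        )
    elif rh > 85.0 and 80.0 <= t_f <= 87.0:
        hi += ((rh - 85.0) / 10.0) * ((87.0 - t_f) / 5.0)
    return hi


def heat_index(air_temp_c, rel_humidity):
    """US National Weather Service heat index, in degC.

    The regression is degF-native: inputs are converted to degF, the NWS
    algorithm (simple branch plus Rothfusz regression with its humidity
    adjustments) is evaluated at full precision, and the result converted
    back to degC.  NaN in either input propagates to NaN.  Scalar in,
    scalar out; array-likes are mapped elementwise.
    """
    t = np.asarray(air_temp_c, dtype=float)
    rh = np.asarray(rel_humidity, dtype=float)
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("relative humidity must lie in [0, 100]")
    t_f = t * 9.0 / 5.0 + 32.0
    out = np.full(np.broadcast(t_f, rh).shape, np.nan)
    t_b, rh_b = np.broadcast_arrays(t_f, rh)
    it = np.nditer(out, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        tv, rv = float(t_b[idx]), float(rh_b[idx])
        if not (math.isnan(tv) or math.isnan(rv)):
            out[idx] = (_hi_fahrenheit(tv, rv) - 32.0) * 5.0 / 9.0
    if out.shape == ():
        return float(out)
    return out


# ---------------------------------------------------------------------------
# WBGT estimate
# ---------------------------------------------------------------------------

def stull_wet_bulb(air_temp_c, rel_humidity):
    """Psychrometric wet-bulb temperature [degC] from T and RH (Stull 2011)."""
    t = np.asarray(air_temp_c, dtype=float)
    rh = np.asarray(rel_humidity, dtype=float)
    tw = (
        t * np.arctan(0.151977 * np.sqrt(rh + 8.313659))
        + np.arctan(t + rh)
        - np.arctan(rh - 1.676331)
        + 0.00391838 * rh**1.5 * np.arctan(0.023101 * rh)
        - 4.686035
    )
    if tw.shape == ():
        return float(tw)
    return tw


def natural_wet_bulb_default(air_temp_c, rel_humidity, global_radiation, wind_speed):
    """Default natural wet-bulb estimator [degC].

    The psychrometric wet bulb (Stull) is raised by solar loading and the
    excess is ventilated away by wind:  Tnwb = Tw + 0.0021*S / (1 + 0.15*u)
    with S in W/m2 and u in m/s.  At night (S = 0) it reduces to the
    psychrometric wet bulb.  Monotone non-decreasing in radiation.
    """
    tw = stull_wet_bulb(air_temp_c, rel_humidity)
    s = np.asarray(global_radiation, dtype=float)
    u = np.asarray(wind_speed, dtype=float)
    out = tw + 0.0021 * s / (1.0 + 0.15 * u)
    if np.asarray(out).shape == ():
        return float(out)
    return out


def globe_temperature_default(air_temp_c, rel_humidity, global_radiation, wind_speed):
    """Default black-globe temperature estimator [degC].

    Radiative excess over air temperature proportional to global radiation
    and ventilated by wind: Tg = Ta + 0.0130*S / (1 + 0.30*u).  Monotone
    non-decreasing in radiation; equals air temperature in darkness.
    """
    t = np.asarray(air_temp_c, dtype=float)
    s = np.asarray(global_radiation, dtype=float)
    u = np.asarray(wind_speed, dtype=float)
    out = t + 0.0130 * s / (1.0 + 0.30 * u)
    if np.asarray(out).shape == ():
        return float(out)
    return out


def wbgt_estimate(
    air_temp_c,
    rel_humidity,
    global_radiation,
    wind_speed,
    natural_wet_bulb: Callable = natural_wet_bulb_default,
    globe_temperature: Callable = globe_temperature_default,
):
    """Outdoor wet-bulb globe temperature estimate [degC].

    WBGT = 0.7*Tnwb + 0.2*Tg + 0.1*Ta.  The natural wet-bulb and globe
    sub-estimators are pluggable; each is called with
    (air_temp_c, rel_humidity, global_radiation, wind_speed).  Missing
    input in any channel yields NaN for that interval.
    """
    t = np.asarray(air_temp_c, dtype=float)
    tnwb = np.asarray(
        natural_wet_bulb(air_temp_c, rel_humidity, global_radiation, wind_speed),
        dtype=float,
    )
    tg = np.asarray(
        globe_temperature(air_temp_c, rel_humidity, global_radiation, wind_speed),
        dtype=float,
    )
    out = 0.7 * tnwb + 0.2 * tg + 0.1 * t
    if out.shape == ():
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Daily summaries
# ---------------------------------------------------------------------------

WEATHER_COLUMNS = [
    "station_id",
    "timestamp",
    "air_temp_c",
    "rel_humidity_pct",
    "precip_mm",
    "wind_speed_ms",
    "global_radiation_wm2",
]


def add_heat_metrics(obs: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the observation table with per-interval ``hi_c``
    and ``wbgt_c`` columns."""
    out = obs.copy()
    out["hi_c"] = heat_index(
        out["air_temp_c"].to_numpy(), out["rel_humidity_pct"].to_numpy()
    )
    out["wbgt_c"] = wbgt_estimate(
        out["air_temp_c"].to_numpy(),
        out["rel_humidity_pct"].to_numpy(),
        out["global_radiation_wm2"].to_numpy(),
        out["wind_speed_ms"].to_numpy(),
    )
    return out


DAILY_FIELDS = [
    "station_id",
    "date",
    "season",
    "tmax_day",
    "tmin_night",
    "wbgt_max_day",
    "hi_min_night",
    "rain_total",
    "is_heat_stress_day",
    "is_heat_stress_night",
    "is_heavy_rain_day",
    "is_tropical_night",
    "is_hot_day",
]


def _flag(value: float, threshold: float, strict: bool = False):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return pd.NA
    return bool(value > threshold) if strict else bool(value >= threshold)


def daily_weather_summary(
    obs: pd.DataFrame,
    date,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> dict:
    """Summarise one station's observations for one calendar date.

    Day window: [06:00, 22:00) of ``date``; night window: [22:00 of
    ``date``, 06:00 of ``date``+1); rain totalled over the calendar day.
    A window with zero observations yields missing summary fields and
    missing (not false) flags.  Invariant to the ordering of ``obs``.
    """
    date = pd.Timestamp(date).normalize()
    if "hi_c" not in obs.columns or "wbgt_c" not in obs.columns:
        obs = add_heat_metrics(obs)
    ts = pd.to_datetime(obs["timestamp"])

    day0 = date + pd.Timedelta(hours=thresholds.day_start_hour)
    day1 = date + pd.Timedelta(hours=thresholds.night_start_hour)
    night1 = date + pd.Timedelta(days=1, hours=thresholds.day_start_hour)

    day = obs[(ts >= day0) & (ts < day1)]
    night = obs[(ts >= day1) & (ts < night1)]
    cal = obs[(ts >= date) & (ts < date + pd.Timedelta(days=1))]

    tmax_day = float(day["air_temp_c"].max()) if len(day) else math.nan
    wbgt_max = float(day["wbgt_c"].max()) if len(day) else math.nan
    tmin_night = float(night["air_temp_c"].min()) if len(night) else math.nan
    hi_min = float(night["hi_c"].min()) if len(night) else math.nan
    rain = float(cal["precip_mm"].sum()) if len(cal) else math.nan

    station = obs["station_id"].iloc[0] if len(obs) else pd.NA
    return {
        "station_id": station,
        "date": date,
        "season": season_of(date.month),
        "tmax_day": tmax_day,
        "tmin_night": tmin_night,
        "wbgt_max_day": wbgt_max,
        "hi_min_night": hi_min,
        "rain_total": rain,
        "is_heat_stress_day": _flag(wbgt_max, thresholds.heat_stress_wbgt_c),
        "is_heat_stress_night": _flag(hi_min, thresholds.heat_stress_hi_c),
        "is_heavy_rain_day": _flag(rain, thresholds.heavy_rain_mm),
        "is_tropical_night": _flag(tmin_night, thresholds.tropical_night_c, strict=True),
        "is_hot_day": _flag(tmax_day, thresholds.hot_day_c),
    }


def summarize_daily(
    obs: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Daily summaries for every station-date present in ``obs``.

    Vectorised equivalent of calling :func:`daily_weather_summary` for
    each station and calendar date spanned by its observations.
    """
    if obs.empty:
        return pd.DataFrame(columns=DAILY_FIELDS)
    obs = add_heat_metrics(obs)
    obs = obs.assign(timestamp=pd.to_datetime(obs["timestamp"]))
    ts = obs["timestamp"]
    hours = ts.dt.hour
    cal_date = ts.dt.normalize()

    day_mask = (hours >= thresholds.day_start_hour) & (
        hours < thresholds.night_start_hour
    )
    # night of date d = [d 22:00, d+1 06:00): pre-midnight hours belong to d,
    # post-midnight hours to d-1
    night_mask = (hours >= thresholds.night_start_hour) | (
        hours < thresholds.day_start_hour
    )
    night_date = cal_date.where(
        hours >= thresholds.night_start_hour, cal_date - pd.Timedelta(days=1)
    )

    day_agg = (
        obs[day_mask]
        .groupby(["station_id", cal_date[day_mask].rename("date")])
        .agg(tmax_day=("air_temp_c", "max"), wbgt_max_day=("wbgt_c", "max"))
    )
    night_agg = (
        obs[night_mask]
        .groupby(["station_id", night_date[night_mask].rename("date")])
        .agg(tmin_night=("air_temp_c", "min"), hi_min_night=("hi_c", "min"))
    )
    rain_agg = (
        obs.groupby(["station_id", cal_date.rename("date")])
        .agg(rain_total=("precip_mm", "sum"))
    )
    daily = day_agg.join(night_agg, how="outer").join(rain_agg, how="outer")
    daily = daily.reset_index().sort_values(["station_id", "date"])
    daily["season"] = daily["date"].dt.month.map(season_of)

    daily["is_heat_stress_day"] = [
        _flag(v, thresholds.heat_stress_wbgt_c) for v in daily["wbgt_max_day"]
    ]
    daily["is_heat_stress_night"] = [
        _flag(v, thresholds.heat_stress_hi_c) for v in daily["hi_min_night"]
    ]
    daily["is_heavy_rain_day"] = [
        _flag(v, thresholds.heavy_rain_mm) for v in daily["rain_total"]
    ]
    daily["is_tropical_night"] = [
        _flag(v, thresholds.tropical_night_c, strict=True)
        for v in daily["tmin_night"]
    ]
    daily["is_hot_day"] = [
        _flag(v, thresholds.hot_day_c) for v in daily["tmax_day"]
    ]
    return daily[DAILY_FIELDS].reset_index(drop=True)


EXTREME_INDEX_NAMES = [
    "heavy_rain_days",
    "tropical_nights",
    "hot_days",
    "heat_stress_days",
    "heat_stress_nights",
]


def extreme_indexes(daily: pd.DataFrame) -> dict[str, int]:
    """Count extreme-weather days/nights in a daily summary table.

    Heavy-rain, hot-day and heat-stress counts use ``>=`` thresholds;
    tropical nights require minimum temperature strictly above 20 degC.
    Rows whose flag is missing (empty window) do not contribute.  An empty
    table gives all-zero counts.
    """
    def count(col: str) -> int:
        if daily.empty or col not in daily.columns:
            return 0
        flags = pd.array(daily[col], dtype="boolean")
        return int(flags.fillna(False).sum())

    return {
        "heavy_rain_days": count("is_heavy_rain_day"),
        "tropical_nights": count("is_tropical_night"),
        "hot_days": count("is_hot_day"),
        "heat_stress_days": count("is_heat_stress_day"),
        "heat_stress_nights": count("is_heat_stress_night"),
    }
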