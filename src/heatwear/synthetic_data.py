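"""Synthetic study-world generator with known ground truth.

Generates everything the pipeline consumes — weather-station series,
participant roster, and raw wearable streams — from a single
:class:`SimConfig` and seed, so every stage can be tested against known
truth without any external data:

* weather — 15-minute series per station with a seasonal mean, diurnal
  sinusoid and noise for temperature, humidity anti-correlated with
  temperature, per-day Bernoulli-gamma rainfall concentrated in the rainy
  season, diurnal radiation with cloud attenuation on rain days;
* cohort — roster with sex, birth date, height, weight and village, plus
  per-participant true random intercepts;
* outcomes — per-day steps, per-night sleep duration and nighttime heart
  rate built on the linked scale from the configured fixed effects
  (heat, heat squared, rain, weekend, month) and then decomposed into
  plausible raw streams (step epochs with diurnal peaks, sleep records
  optionally split in two to exercise merging, HR samples around the
  nightly mean), with configurable missingness;
* QC violations — duplicates, zero-step epochs, out-of-window naps,
  short sleep spans, overlapping sleep records and heart-rate spikes
  above the age-predicted ceiling, injected at configured rates and
  recorded in a ground-truth ledger that QC exclusion counts must match
  exactly.

Everything is reproducible from ``(config, seed)``: each sub-generator
draws from its own stream derived from the master seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import exposure
from .thresholds import DEFAULT_THRESHOLDS, Thresholds

__all__ = [
    "SeasonWeather",
    "EffectConfig",
    "SimConfig",
    "simulate_sites",
    "simulate_weather",
    "simulate_cohort",
    "simulate_true_panel",
    "simulate_outcomes",
]


@dataclass(frozen=True)
class SeasonWeather:
    """Per-season weather generator parameters."""

    temp_mean: float          # season mean air temperature [degC]
    temp_diurnal_amp: float   # half-range of the diurnal cycle [degC]
    temp_day_sd: float        # day-to-day offset SD [degC]
    rh_base: float            # humidity at the season-mean temperature [%]
    rain_prob: float          # probability a day has rain
    rain_gamma_shape: float   # daily rain amount ~ Gamma(shape, scale) [mm]
    rain_gamma_scale: float
    radiation_peak: float     # clear-sky solar noon radiation [W/m2]
    wind_mean: float          # mean wind speed [m/s]


#: seasonal defaults emulating the Sahelian study region: one rainy season
#: (Jun-Sep, humid, mean ~27.6 C), a cool dry (Oct-Jan, ~26.8 C) and a hot
#: dry season (Feb-May, ~31.1 C) with large diurnal swings when dry
DEFAULT_SEASONS: dict[str, SeasonWeather] = {
    "rainy": SeasonWeather(27.6, 4.0, 1.2, 72.0, 0.35, 1.2, 12.0, 750.0, 2.0),
    "cool_dry": SeasonWeather(26.8, 7.5, 1.5, 32.0, 0.01, 1.0, 5.0, 820.0, 2.5),
    "hot_dry": SeasonWeather(31.1, 7.5, 1.5, 28.0, 0.02, 1.0, 5.0, 880.0, 2.5),
}


@dataclass(frozen=True)
class EffectConfig:
    """True fixed effects and noise scales for one outcome."""

    intercept: float
    heat: float = 0.0
    heat_quadratic: float = 0.0
    rain: float = 0.0
    weekend: float = 0.0
    month: tuple[tuple[int, float], ...] = ()   # (month, shift) pairs
    sex_female: float = 0.0
    resid_sd: float = 1.0
    intercept_sd: float = 0.5

    def month_shift(self, month: int) -> float:
        return dict(self.month).get(int(month), 0.0)


@dataclass(frozen=True)
class SimConfig:
    """All true parameters of the synthetic study world.

    Defaults describe the study conditions the pipeline is exercised
    under: 60 participants followed for 120 days starting at the height
    of the rainy season, seasonal Sahelian weather at 2 stations serving
    5 villages, outcome effects near the headline exposure-response
    estimates (sleep −0.04 h per degC of nighttime heat index, +0.01 h
    per mm rain; an inverted-U activity response peaking near 27 degC
    WBGT with −39 steps per mm rain), and wearable missingness at the
    observed stream-completeness levels (about half of days for steps and
    sleep, most nights absent for heart rate).
    """

    n_participants: int = 60
    study_days: int = 120
    start_date: str = "2021-08-01"
    n_stations: int = 2
    n_villages: int = 5
    center_lat: float = 12.73
    center_lon: float = -3.86
    seasons: Mapping[str, SeasonWeather] = field(
        default_factory=lambda: dict(DEFAULT_SEASONS)
    )
    # cohort margins: ~50% female, age 43 (SD 13), BMI 22.3 (SD 2.7)
    female_fraction: float = 0.5
    age_mean: float = 43.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (16.0, 79.0)
    height_mean_cm: float = 168.0
    height_sd_cm: float = 8.0
    bmi_mean: float = 22.3
    bmi_sd: float = 2.7
    bmi_range: tuple[float, float] = (15.0, 33.0)
    # true outcome models (linked scale)
    sleep: EffectConfig = field(default_factory=lambda: EffectConfig(
        intercept=7.9, heat=-0.04, rain=0.01, weekend=0.10,
        resid_sd=0.9, intercept_sd=0.6,
    ))
    steps: EffectConfig = field(default_factory=lambda: EffectConfig(
        intercept=900.0, heat=648.0, heat_quadratic=-12.0, rain=-39.0,
        weekend=-500.0, month=((8, 1000.0),),
        resid_sd=2500.0, intercept_sd=2000.0,
    ))
    hr: EffectConfig = field(default_factory=lambda: EffectConfig(
        intercept=69.0, heat=0.0, rain=-0.04,
        resid_sd=6.0, intercept_sd=8.0,
    ))
    # sleep shift on heat-stress nights for the binary-exposure generator
    sleep_extreme_shift: float = -0.24
    # missingness per stream (fraction of participant-days/nights absent)
    missing_steps: float = 0.5
    missing_sleep: float = 0.5
    missing_hr_night: float = 0.8
    # raw-stream texture
    sleep_split_prob: float = 0.15      # split a long night into 2 records
    sleep_waso_mean_min: float = 36.0
    sleep_waso_sd_min: float = 10.0
    hr_sample_minutes: int = 10
    hr_sample_sd: float = 2.0
    # QC-violation injection rates
    dup_step_rate: float = 0.0          # per clean epoch
    zero_step_rate: float = 0.0         # per day with data
    nap_rate: float = 0.0               # out-of-window sleep record per night
    short_sleep_rate: float = 0.0       # <3 h in-window record per night
    overlap_sleep_rate: float = 0.0     # overlapping record per (unsplit) night
    hr_spike_rate: float = 0.0          # per night with HR data

    def asdict(self) -> dict[str, Any]:
        d = asdict(self)
        d["seasons"] = {k: asdict(v) if not isinstance(v, dict) else v
                        for k, v in dict(self.seasons).items()}
        return d

    def season(self, month: int) -> SeasonWeather:
        s = self.seasons[exposure.season_of(month)]
        return s if isinstance(s, SeasonWeather) else SeasonWeather(**s)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.study_days, freq="D")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

def simulate_sites(config: SimConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Station and village coordinate tables (id, lat, lon)."""
    rng = _rng(seed, 0)
    stations = pd.DataFrame(
        {
            "id": [f"S{i+1:02d}" for i in range(config.n_stations)],
            "lat": config.center_lat + rng.uniform(-0.15, 0.15, config.n_stations),
            "lon": config.center_lon + rng.uniform(-0.15, 0.15, config.n_stations),
        }
    )
    villages = pd.DataFrame(
        {
            "id": [f"V{i+1:02d}" for i in range(config.n_villages)],
            "lat": config.center_lat + rng.uniform(-0.18, 0.18, config.n_villages),
            "lon": config.center_lon + rng.uniform(-0.18, 0.18, config.n_villages),
        }
    )
    return stations, villages


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

def simulate_weather(
    config: SimConfig,
    seed: int,
    noise: bool = True,
) -> pd.DataFrame:
    """15-minute weather observations for every station.

    Covers the study period plus one extra morning so the final night
    window [22:00, 06:00) is complete.  Temperature follows the seasonal
    mean plus a diurnal sinusoid (warmest mid-afternoon) with day-level
    and interval-level noise; relative humidity is anti-correlated with
    the temperature anomaly; rain falls on Bernoulli days with
    gamma-distributed daily totals spread over a few afternoon intervals;
    radiation follows a solar arc attenuated on rain days.  Setting
    ``noise=False`` zeroes every stochastic term (and rain), leaving an
    exactly periodic series.  Deterministic given (config, seed).
    """
    stations, _ = simulate_sites(config, seed)
    n_days = config.study_days + 1
    start = pd.Timestamp(config.start_date)
    grid = pd.date_range(start, periods=n_days * 96, freq="15min")
    frames = []
    for si, station in enumerate(stations["id"]):
        rng = _rng(seed, 100 + si)
        hours = grid.hour + grid.minute / 60.0
        months = grid.month
        seas = [config.season(m) for m in months]
        t_mean = np.array([s.temp_mean for s in seas])
        t_amp = np.array([s.temp_diurnal_amp for s in seas])
        rh_base = np.array([s.rh_base for s in seas])
        rad_peak = np.array([s.radiation_peak for s in seas])
        wind_mean = np.array([s.wind_mean for s in seas])

        diurnal = np.cos(2.0 * np.pi * (hours - 15.0) / 24.0)
        day_idx = ((grid - start).days).to_numpy()
        if noise:
            day_sd = np.array([config.season(m).temp_day_sd
                               for m in pd.DatetimeIndex(
                                   start + pd.to_timedelta(np.arange(n_days), "D")
                               ).month])
            day_offset = rng.normal(0.0, 1.0, n_days) * day_sd
            iv_noise = rng.normal(0.0, 0.3, len(grid))
        else:
            day_offset = np.zeros(n_days)
            iv_noise = np.zeros(len(grid))
        temp = t_mean + t_amp * diurnal + day_offset[day_idx] + iv_noise

        # rain: per-day Bernoulli, gamma total, spread over 1-6 afternoon slots
        precip = np.zeros(len(grid))
        rain_day = np.zeros(n_days, dtype=bool)
        if noise:
            for d in range(n_days):
                month = (start + pd.Timedelta(days=d)).month
                s = config.season(month)
                if rng.random() < s.rain_prob:
                    rain_day[d] = True
                    total = rng.gamma(s.rain_gamma_shape, s.rain_gamma_scale)
                    k = int(rng.integers(1, 7))
                    slots = rng.choice(np.arange(48, 84), size=k, replace=False)
                    parts = rng.dirichlet(np.ones(k)) * total
                    precip[d * 96 + slots] += parts

        rh = rh_base - 1.8 * (temp - t_mean)
        if noise:
            rh = rh + rng.normal(0.0, 3.0, len(grid))
        rh = rh + 12.0 * rain_day[day_idx]
        rh = np.clip(rh, 3.0, 100.0)

        solar = np.clip(np.sin(np.pi * (hours - 6.0) / 12.0), 0.0, None)
        atten = np.where(rain_day[day_idx], 0.35, 1.0)
        rad = rad_peak * solar * atten
        if noise:
            rad = np.clip(rad + rng.normal(0.0, 15.0, len(grid)) * (solar > 0), 0.0, None)

        wind = np.abs(wind_mean + (rng.normal(0.0, 0.8, len(grid)) if noise else 0.0))

        frames.append(pd.DataFrame(
            {
                "station_id": station,
                "timestamp": grid,
                "air_temp_c": np.round(temp, 2),
                "rel_humidity_pct": np.round(rh, 1),
                "precip_mm": np.round(precip, 2),
                "wind_speed_ms": np.round(wind, 2),
                "global_radiation_wm2": np.round(rad, 1),
            }
        ))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roster table plus ground-truth per-participant random intercepts.

    Returns ``(roster, truth)``: the roster is CSV-compatible
    (participant_id, sex, birth_date, height_cm, weight_kg, village_id);
    the truth table carries age, BMI and the true random intercept per
    outcome, retained for parameter-recovery tests.
    """
    rng = _rng(seed, 200)
    n = config.n_participants
    pid = [f"P{i+1:03d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), *config.age_range)
    height = rng.normal(config.height_mean_cm, config.height_sd_cm, n)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), *config.bmi_range)
    weight = bmi * (height / 100.0) ** 2
    start = pd.Timestamp(config.start_date)
    birth = start - pd.to_timedelta(np.round(age * 365.25), "D")
    villages = [f"V{(i % config.n_villages) + 1:02d}" for i in range(n)]

    roster = pd.DataFrame(
        {
            "participant_id": pid,
            "sex": sex,
            "birth_date": birth.strftime("%Y-%m-%d"),
            "height_cm": np.round(height, 1),
            "weight_kg": np.round(weight, 1),
            "village_id": villages,
        }
    )
    truth = pd.DataFrame(
        {
            "participant_id": pid,
            "age": age,
            "bmi": bmi,
            "intercept_sleep": rng.normal(0.0, config.sleep.intercept_sd, n),
            "intercept_steps": rng.normal(0.0, config.steps.intercept_sd, n),
            "intercept_hr": rng.normal(0.0, config.hr.intercept_sd, n),
        }
    )
    return roster, truth


# ---------------------------------------------------------------------------
# Linked-scale outcomes
# ---------------------------------------------------------------------------

def _station_of_participants(config: SimConfig, seed: int, roster: pd.DataFrame) -> pd.Series:
    from .linkage import assign_stations

    stations, villages = simulate_sites(config, seed)
    assigned = assign_stations(roster, villages, stations)
    return assigned.set_index("participant_id")["station_id"]


def simulate_true_panel(
    config: SimConfig,
    seed: int,
    weather: pd.DataFrame | None = None,
    roster: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
    binary_sleep: bool = False,
) -> dict[str, pd.DataFrame]:
    """Linked-scale ground-truth outcome panels.

    For every participant-date (steps) and participant-night (sleep, HR)
    the true outcome is the configured linear model evaluated at the
    simulated exposures plus the participant's true intercept and
    Gaussian noise; missingness is applied per stream.  With
    ``binary_sleep`` the sleep outcome uses the heat-stress-night shift
    instead of the continuous heat slope.  Returns dict with keys
    ``steps``, ``sleep``, ``hr`` — these are the tables the raw streams
    are decomposed from, so ground truth survives QC when no violations
    are injected.
    """
    if weather is None:
        weather = simulate_weather(config, seed)
    if roster is None or truth is None:
        roster, truth = simulate_cohort(config, seed)
    daily = exposure.summarize_daily(weather)
    station_of = _station_of_participants(config, seed, roster)

    rng = _rng(seed, 300)
    dates = config.dates()
    n_pid, n_dates = len(roster), len(dates)

    base = pd.DataFrame(
        {
            "participant_id": np.repeat(roster["participant_id"].to_numpy(), n_dates),
            "date": np.tile(dates.to_numpy(), n_pid),
        }
    )
    base["station_id"] = base["participant_id"].map(station_of)
    base = base.merge(
        daily[
            ["station_id", "date", "wbgt_max_day", "tmax_day", "hi_min_night",
             "tmin_night", "rain_total", "is_heat_stress_night"]
        ],
        on=["station_id", "date"],
        how="left",
        validate="many_to_one",
    )
    t = truth.set_index("participant_id")
    sexes = roster.set_index("participant_id")["sex"]
    base["female"] = base["participant_id"].map(sexes).eq("female")
    month = pd.to_datetime(base["date"]).dt.month.to_numpy()
    weekend = (pd.to_datetime(base["date"]).dt.dayofweek >= 5).to_numpy()
    n = len(base)

    keep = {
        "steps": rng.random(n) >= config.missing_steps,
        "sleep": rng.random(n) >= config.missing_sleep,
        "hr": rng.random(n) >= config.missing_hr_night,
    }
    noise = {k: rng.normal(0.0, 1.0, n) for k in ("steps", "sleep", "hr")}

    def structural(eff: EffectConfig, heat_val: np.ndarray) -> np.ndarray:
        shift = np.array([eff.month_shift(m) for m in month])
        return (
            eff.intercept
            + eff.heat * heat_val
            + eff.heat_quadratic * heat_val**2
            + eff.rain * base["rain_total"].to_numpy()
            + eff.weekend * weekend
            + shift
            + eff.sex_female * base["female"].to_numpy()
        )

    out: dict[str, pd.DataFrame] = {}

    # steps (daytime heat metric)
    wbgt = base["wbgt_max_day"].to_numpy(dtype=float)
    y = (
        structural(config.steps, wbgt)
        + base["participant_id"].map(t["intercept_steps"]).to_numpy()
        + noise["steps"] * config.steps.resid_sd
    )
    mask = keep["steps"] & ~np.isnan(wbgt)
    out["steps"] = pd.DataFrame(
        {
            "participant_id": base.loc[mask, "participant_id"].to_numpy(),
            "date": base.loc[mask, "date"].to_numpy(),
            "steps": np.maximum(96.0, np.round(y[mask])),
            "wbgt_max_day": wbgt[mask],
            "tmax_day": base.loc[mask, "tmax_day"].to_numpy(),
            "rain_total": base.loc[mask, "rain_total"].to_numpy(),
        }
    )

    # sleep (nighttime heat metric; optionally the binary-extreme world)
    hi = base["hi_min_night"].to_numpy(dtype=float)
    eff = config.sleep
    if binary_sleep:
        stress = base["is_heat_stress_night"].fillna(False).to_numpy(dtype=bool)
        null_eff = EffectConfig(
            intercept=eff.intercept, rain=eff.rain, weekend=eff.weekend,
            month=eff.month, resid_sd=eff.resid_sd,
            intercept_sd=eff.intercept_sd,
        )
        y = (
            structural(null_eff, np.zeros_like(hi))
            + config.sleep_extreme_shift * stress
            + base["participant_id"].map(t["intercept_sleep"]).to_numpy()
            + noise["sleep"] * eff.resid_sd
        )
    else:
        y = (
            structural(eff, hi)
            + base["participant_id"].map(t["intercept_sleep"]).to_numpy()
            + noise["sleep"] * eff.resid_sd
        )
    y = np.clip(y, 3.2, 12.0)
    mask = keep["sleep"] & ~np.isnan(hi)
    out["sleep"] = pd.DataFrame(
        {
            "participant_id": base.loc[mask, "participant_id"].to_numpy(),
            "night_date": base.loc[mask, "date"].to_numpy(),
            "duration_h": y[mask],
            "hi_min_night": hi[mask],
            "tmin_night": base.loc[mask, "tmin_night"].to_numpy(),
            "rain_total": base.loc[mask, "rain_total"].to_numpy(),
            "is_heat_stress_night": base.loc[mask, "is_heat_stress_night"]
            .fillna(False)
            .to_numpy(dtype=bool),
        }
    )

    # nighttime heart rate
    y = (
        structural(config.hr, hi)
        + base["participant_id"].map(t["intercept_hr"]).to_numpy()
        + noise["hr"] * config.hr.resid_sd
    )
    mask = keep["hr"] & ~np.isnan(hi)
    out["hr"] = pd.DataFrame(
        {
            "participant_id": base.loc[mask, "participant_id"].to_numpy(),
            "night_date": base.loc[mask, "date"].to_numpy(),
            "hr_night_mean": np.maximum(35.0, y[mask]),
            "hi_min_night": hi[mask],
            "rain_total": base.loc[mask, "rain_total"].to_numpy(),
        }
    )
    return out


# ---------------------------------------------------------------------------
# Raw streams + violation injection
# ---------------------------------------------------------------------------

def _diurnal_step_weights() -> np.ndarray:
    """Weights over the 64 day epochs [06:00, 22:00): morning and late
    afternoon activity peaks."""
    hours = 6.0 + np.arange(64) * 0.25
    w = (
        1.0
        + 2.5 * np.exp(-0.5 * ((hours - 9.0) / 1.5) ** 2)
        + 1.8 * np.exp(-0.5 * ((hours - 17.0) / 1.5) ** 2)
    )
    return w / w.sum()


def simulate_outcomes(
    config: SimConfig,
    seed: int,
    weather: pd.DataFrame | None = None,
    roster: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
) -> dict[str, Any]:
    """Decompose linked-scale outcomes into raw wearable streams.

    Returns a dict with raw ``steps``/``sleep``/``hr`` DataFrames in the
    input-CSV schemas, the ground-truth linked ``panels``, and a
    ``ledger`` counting injected QC violations per reason code
    (duplicate, zero_steps, window, short_span, overlap, hr_ceiling).
    Cleaning the raw streams recovers the linked panels exactly for
    sleep/steps (and to rounding for HR) apart from nights lost to
    injected overlaps.
    """
    if weather is None:
        weather = simulate_weather(config, seed)
    if roster is None or truth is None:
        roster, truth = simulate_cohort(config, seed)
    panels = simulate_true_panel(config, seed, weather, roster, truth)
    rng = _rng(seed, 400)
    ages = (
        pd.Timestamp(config.start_date)
        - pd.to_datetime(roster.set_index("participant_id")["birth_date"])
    ).dt.days / 365.25

    ledger = {k: 0 for k in
              ("duplicate", "zero_steps", "window", "short_span", "overlap",
               "hr_ceiling", "hr_duplicate")}
    weights = _diurnal_step_weights()

    # --- steps ---
    step_rows = []
    day_start = DEFAULT_THRESHOLDS.day_start_hour
    for row in panels["steps"].itertuples():
        total = int(row.steps)
        counts = 1 + rng.multinomial(total - 64, weights)
        base = row.date + pd.Timedelta(hours=day_start)
        times = base + pd.to_timedelta(np.arange(64) * 15, "min")
        for ts, c in zip(times, counts):
            step_rows.append((row.participant_id, ts, int(c)))
        # injected violations
        n_dup = int(rng.binomial(64, config.dup_step_rate))
        if n_dup:
            idx = rng.choice(64, size=n_dup, replace=False)
            for i in idx:
                step_rows.append((row.participant_id, times[i], int(counts[i])))
            ledger["duplicate"] += n_dup
        if rng.random() < config.zero_step_rate:
            # a zero epoch in the pre-dawn hours, outside the day grid
            ts = row.date + pd.Timedelta(hours=4, minutes=int(rng.integers(0, 4)) * 15)
            step_rows.append((row.participant_id, ts, 0))
            ledger["zero_steps"] += 1
    steps_raw = pd.DataFrame(
        step_rows, columns=["participant_id", "timestamp", "steps"]
    )

    # --- sleep ---
    sleep_rows = []
    for row in panels["sleep"].itertuples():
        dur_h = float(row.duration_h)
        waso_min = float(
            np.clip(
                rng.normal(config.sleep_waso_mean_min, config.sleep_waso_sd_min),
                5.0,
                90.0,
            )
        )
        onset = (
            row.night_date
            + pd.Timedelta(hours=21)
            + pd.Timedelta(minutes=int(rng.integers(0, 91)))
        )
        split = dur_h >= 7.2 and rng.random() < config.sleep_split_prob
        if split:
            frac = rng.uniform(0.45, 0.55)
            d1, d2 = dur_h * frac, dur_h * (1.0 - frac)
            w1 = waso_min * 0.5
            w2 = waso_min - w1
            gap_min = float(rng.integers(15, 76))
            off1 = onset + pd.Timedelta(hours=d1) + pd.Timedelta(minutes=w1)
            on2 = off1 + pd.Timedelta(minutes=gap_min)
            off2 = on2 + pd.Timedelta(hours=d2) + pd.Timedelta(minutes=w2)
            sleep_rows.append(
                (row.participant_id, onset, off1, round(d1 * 3600), round(w1 * 60))
            )
            sleep_rows.append(
                (row.participant_id, on2, off2, round(d2 * 3600), round(w2 * 60))
            )
            last_offset = off2
        else:
            offset = (
                onset
                + pd.Timedelta(hours=dur_h)
                + pd.Timedelta(minutes=waso_min)
            )
            sleep_rows.append(
                (row.participant_id, onset, offset, round(dur_h * 3600),
                 round(waso_min * 60))
            )
            last_offset = offset
            if rng.random() < config.overlap_sleep_rate:
                # shifted copy overlapping the real record: QC drops both
                sleep_rows.append(
                    (
                        row.participant_id,
                        onset + pd.Timedelta(hours=1),
                        offset + pd.Timedelta(hours=1),
                        round(dur_h * 3600),
                        round(waso_min * 60),
                    )
                )
                ledger["overlap"] += 2
        if rng.random() < config.nap_rate:
            # afternoon nap: onset before 17:00 -> window violation
            nap_on = row.night_date + pd.Timedelta(hours=13, minutes=30)
            nap_off = nap_on + pd.Timedelta(hours=3)
            sleep_rows.append(
                (row.participant_id, nap_on, nap_off, 3 * 3600, 0)
            )
            ledger["window"] += 1
        if rng.random() < config.short_sleep_rate:
            # early-evening fragment shorter than 3 h, inside the window
            s_on = row.night_date + pd.Timedelta(hours=17, minutes=30)
            s_off = s_on + pd.Timedelta(hours=1, minutes=30)
            sleep_rows.append(
                (row.participant_id, s_on, s_off, int(1.4 * 3600), 360)
            )
            ledger["short_span"] += 1
    sleep_raw = pd.DataFrame(
        sleep_rows,
        columns=["participant_id", "onset", "offset", "duration_s", "waso_s"],
    )

    # --- heart rate ---
    hr_rows = []
    night_start = DEFAULT_THRESHOLDS.night_start_hour
    n_samples = int(8 * 60 / config.hr_sample_minutes)
    for row in panels["hr"].itertuples():
        base = row.night_date + pd.Timedelta(hours=night_start)
        times = base + pd.to_timedelta(
            np.arange(n_samples) * config.hr_sample_minutes, "min"
        )
        bpm = np.round(
            row.hr_night_mean + rng.normal(0.0, config.hr_sample_sd, n_samples)
        ).astype(int)
        for ts, b in zip(times, bpm):
            hr_rows.append((row.participant_id, ts, int(b)))
        if rng.random() < config.hr_spike_rate:
            ceiling = 208.0 - 0.7 * ages[row.participant_id]
            spike_ts = base - pd.Timedelta(minutes=int(rng.integers(1, 60)))
            hr_rows.append(
                (row.participant_id, spike_ts, int(math.ceil(ceiling) + 20))
            )
            ledger["hr_ceiling"] += 1
    hr_raw = pd.DataFrame(hr_rows, columns=["participant_id", "timestamp", "bpm"])

    return {
        "steps": steps_raw,
        "sleep": sleep_raw,
        "hr": hr_raw,
        "panels": panels,
        "ledger": ledger,
        "roster": roster,
        "truth": truth,
        "weather": weather,
    }
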