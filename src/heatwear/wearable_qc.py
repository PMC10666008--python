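"""Wearable stream cleaning: steps, sleep, heart rate.

Raw consumer-wearable exports are noisy: duplicated uploads, zero-step
epochs indistinguishable from non-wear, sleep records split or overlapping,
and optically implausible heart-rate spikes.  This module applies the QC
rules that turn those streams into analysis-ready per-day and per-night
outcomes:

* steps — dedupe, drop zero-step epochs, compute wear time (non-wear = a
  gap of more than 1 h between epochs), keep days with >= 10 h wear;
* sleep — keep records inside the 17:00 -> 13:00 night window, drop spans
  shorter than 3 h, drop mutually overlapping records, merge the rest of a
  night into one observation (durations summed, inter-record gaps added to
  wake-after-sleep-onset);
* heart rate — dedupe, drop samples above the age-predicted maximum
  (Tanaka: 208 - 0.7*age), round to integer bpm, aggregate to 15-min bins,
  keep days with >= 2 h and nights with >= 1 h of populated bins.

Every dropped record carries a machine-readable reason code
(:data:`REASON_CODES`) so exclusion counts can be audited against a
ground-truth ledger.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thresholds import DEFAULT_THRESHOLDS, Thresholds

__all__ = [
    "REASON_CODES",
    "QCAudit",
    "max_hr",
    "clean_steps",
    "wear_time",
    "daily_steps",
    "daily_steps_table",
    "bin_15min_steps",
    "bin_15min_hr",
    "clean_sleep",
    "flag_insufficient_sleep",
    "clean_hr",
    "completeness_filter",
]

#: exclusion reason codes used in QC audits
REASON_CODES = (
    "duplicate",
    "zero_steps",
    "window",
    "short_span",
    "overlap",
    "hr_ceiling",
    "hr_duplicate",
)


@dataclass
class QCAudit:
    """Counts of records dropped per exclusion reason."""

    counts: dict[str, int] = field(
        default_factory=lambda: {code: 0 for code in REASON_CODES}
    )

    def add(self, reason: str, n: int = 1) -> None:
        if reason not in self.counts:
            raise KeyError(f"unknown reason code {reason!r}")
        self.counts[reason] += int(n)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reason": list(self.counts), "n_dropped": list(self.counts.values())}
        )


def max_hr(age: float) -> float:
    """Age-predicted maximal heart rate (Tanaka): 208 - 0.7 * age [bpm]."""
    if age is None or not age > 0:
        raise ValueError(f"age must be positive, got {age!r}")
    return 208.0 - 0.7 * float(age)


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------

def clean_steps(
    epochs: pd.DataFrame, audit: QCAudit | None = None
) -> pd.DataFrame:
    """Dedupe and drop zero-step epochs; output sorted by participant, time.

    Zero-step epochs are removed because the device cannot distinguish
    them from non-wear.  Idempotent.
    """
    out = epochs.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    n0 = len(out)
    out = out.drop_duplicates(subset=["participant_id", "timestamp"])
    n_dup = n0 - len(out)
    zero = out["steps"] == 0
    n_zero = int(zero.sum())
    out = out[~zero]
    if audit is not None:
        audit.add("duplicate", n_dup)
        audit.add("zero_steps", n_zero)
    return out.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)


def wear_time(
    epochs: pd.DataFrame,
    date,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> float:
    """Hours of device wear on ``date`` for one participant's epochs.

    Wear time is the sum of gaps between consecutive epochs that are at
    most 1 h (longer gaps are non-wear) plus one epoch width (15 min) for
    the final epoch, so a contiguous 15-min grid covering [08:00, 18:00)
    counts as 10 h.  A day with no epochs has 0 h wear.
    """
    date = pd.Timestamp(date).normalize()
    ts = pd.to_datetime(epochs["timestamp"])
    day = ts[(ts >= date) & (ts < date + pd.Timedelta(days=1))].sort_values()
    if day.empty:
        return 0.0
    gaps = day.diff().dropna().dt.total_seconds() / 3600.0
    worn = float(gaps[gaps <= thresholds.nonwear_gap_hours].sum())
    return worn + thresholds.epoch_minutes / 60.0


def daily_steps(
    epochs: pd.DataFrame,
    date,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> float:
    """Total steps on ``date`` if wear time >= 10 h, else NaN (excluded)."""
    if wear_time(epochs, date, thresholds) < thresholds.min_wear_hours:
        return math.nan
    date = pd.Timestamp(date).normalize()
    ts = pd.to_datetime(epochs["timestamp"])
    mask = (ts >= date) & (ts < date + pd.Timedelta(days=1))
    return float(epochs.loc[mask, "steps"].sum())


def daily_steps_table(
    cleaned: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per participant-date step totals with the wear-time filter applied.

    Returns rows only for days meeting the wear criterion; excluded days
    are absent (missing), never zero.
    """
    rows = []
    cleaned = cleaned.assign(timestamp=pd.to_datetime(cleaned["timestamp"]))
    cleaned = cleaned.assign(date=cleaned["timestamp"].dt.normalize())
    for (pid, date), grp in cleaned.groupby(["participant_id", "date"]):
        ts = grp["timestamp"].sort_values()
        gaps = ts.diff().dropna().dt.total_seconds() / 3600.0
        worn = float(gaps[gaps <= thresholds.nonwear_gap_hours].sum())
        worn += thresholds.epoch_minutes / 60.0
        if worn >= thresholds.min_wear_hours:
            rows.append(
                {
                    "participant_id": pid,
                    "date": date,
                    "steps": float(grp["steps"].sum()),
                    "wear_hours": worn,
                }
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "date", "steps", "wear_hours"]
    )


def bin_15min_steps(cleaned: pd.DataFrame) -> pd.DataFrame:
    """Sum steps into left-closed 15-min bins on :00/:15/:30/:45."""
    out = cleaned.assign(
        bin_start=pd.to_datetime(cleaned["timestamp"]).dt.floor("15min")
    )
    return (
        out.groupby(["participant_id", "bin_start"], as_index=False)["steps"]
        .sum()
        .sort_values(["participant_id", "bin_start"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Sleep
# ---------------------------------------------------------------------------

def _night_date(onset: pd.Timestamp) -> pd.Timestamp:
    """Night label: onsets after noon belong to that date, earlier onsets
    (post-midnight) to the previous date."""
    return onset.normalize() if onset.hour >= 12 else onset.normalize() - pd.Timedelta(days=1)


def clean_sleep(
    records: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    audit: QCAudit | None = None,
    dropped: list | None = None,
) -> pd.DataFrame:
    """Clean and merge raw sleep records into one observation per night.

    Rules, applied in order per participant:

    1. window — keep records with onset >= 17:00 of the night's date and
       offset <= 13:00 of the following day;
    2. short_span — drop records spanning < 3 h onset-to-offset (the
       device flags these as invalid);
    3. overlap — within one night, records that overlap any other record
       of that night are dropped (error measurements);
    4. merge — remaining records of a night are combined: duration is the
       sum of durations, WASO the sum of WASOs plus inter-record gaps,
       onset the earliest onset, offset the latest offset.

    Input columns: participant_id, onset, offset, duration_s, waso_s.
    Output columns: participant_id, night_date, onset, offset,
    duration_h, waso_min, n_records.
    """
    recs = records.copy()
    recs["onset"] = pd.to_datetime(recs["onset"])
    recs["offset"] = pd.to_datetime(recs["offset"])
    nights: list[dict] = []

    def drop(row, reason):
        if audit is not None:
            audit.add(reason)
        if dropped is not None:
            dropped.append(
                {
                    "participant_id": row.participant_id,
                    "onset": row.onset,
                    "offset": row.offset,
                    "reason": reason,
                }
            )

    for pid, grp in recs.groupby("participant_id"):
        by_night: dict[pd.Timestamp, list] = {}
        for row in grp.sort_values("onset").itertuples():
            nd = _night_date(row.onset)
            earliest = nd + pd.Timedelta(hours=thresholds.sleep_onset_earliest_hour)
            latest = nd + pd.Timedelta(
                days=1, hours=thresholds.sleep_offset_latest_hour
            )
            if row.onset < earliest or row.offset > latest:
                drop(row, "window")
                continue
            span_h = (row.offset - row.onset).total_seconds() / 3600.0
            if span_h < thresholds.sleep_min_span_hours:
                drop(row, "short_span")
                continue
            by_night.setdefault(nd, []).append(row)

        for nd, rows in sorted(by_night.items()):
            rows = sorted(rows, key=lambda r: r.onset)
            overlapping = set()
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    if rows[j].onset < rows[i].offset and rows[i].onset < rows[j].offset:
                        overlapping.update((i, j))
            keep = [r for i, r in enumerate(rows) if i not in overlapping]
            for i in sorted(overlapping):
                drop(rows[i], "overlap")
            if not keep:
                continue
            duration_s = sum(float(r.duration_s) for r in keep)
            waso_s = sum(float(r.waso_s) for r in keep)
            for prev, nxt in zip(keep, keep[1:]):
                waso_s += (nxt.onset - prev.offset).total_seconds()
            nights.append(
                {
                    "participant_id": pid,
                    "night_date": nd,
                    "onset": keep[0].onset,
                    "offset": keep[-1].offset,
                    "duration_h": duration_s / 3600.0,
                    "waso_min": waso_s / 60.0,
                    "n_records": len(keep),
                }
            )
    return pd.DataFrame(
        nights,
        columns=[
            "participant_id",
            "night_date",
            "onset",
            "offset",
            "duration_h",
            "waso_min",
            "n_records",
        ],
    )


def flag_insufficient_sleep(
    duration_h: float,
    age: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """True iff the night's sleep is below the age-specific threshold.

    Under 18 years: < 8 h is insufficient; 18 and over: < 7 h.  Age
    exactly 18 is treated as adult.
    """
    limit = (
        thresholds.insufficient_sleep_minor_h
        if age < 18
        else thresholds.insufficient_sleep_adult_h
    )
    return bool(duration_h < limit)


# ---------------------------------------------------------------------------
# Heart rate
# ---------------------------------------------------------------------------

def bin_15min_hr(samples: pd.DataFrame) -> pd.DataFrame:
    """Aggregate HR samples (rounded to integer bpm first) into 15-min bins
    with mean/min/max and sample count."""
    out = samples.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    out["bpm"] = out["bpm"].round().astype(int)
    out["bin_start"] = out["timestamp"].dt.floor("15min")
    agg = (
        out.groupby(["participant_id", "bin_start"])["bpm"]
        .agg(mean_bpm="mean", min_bpm="min", max_bpm="max", n_samples="size")
        .reset_index()
    )
    return agg.sort_values(["participant_id", "bin_start"]).reset_index(drop=True)


def clean_hr(
    samples: pd.DataFrame,
    ages: dict | pd.Series,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    audit: QCAudit | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Clean HR samples and split into qualifying day and night intervals.

    Dedupe (participant, timestamp); drop samples above the Tanaka
    ceiling for the participant's age; round to integer bpm and bin to
    15 min.  Night bins fall in [22:00, 06:00) and are labelled with the
    night's starting date.  A participant-day qualifies with >= 8
    populated day bins (2 h); a participant-night with >= 4 populated
    bins (1 h at one sample per 15 min).

    Returns ``(day_intervals, night_intervals, nightly_mean)`` where
    ``nightly_mean`` has one row per qualifying participant-night with
    the mean of its bin means (the nighttime-HR outcome).  Disqualified
    days/nights are simply absent.
    """
    s = samples.copy()
    s["timestamp"] = pd.to_datetime(s["timestamp"])
    n0 = len(s)
    s = s.drop_duplicates(subset=["participant_id", "timestamp"])
    if audit is not None:
        audit.add("hr_duplicate", n0 - len(s))
    ceiling = s["participant_id"].map(lambda p: max_hr(ages[p]))
    over = s["bpm"] > ceiling
    if audit is not None:
        audit.add("hr_ceiling", int(over.sum()))
    s = s[~over]
    if s.empty:
        empty = bin_15min_hr(s.assign(bpm=s.get("bpm", pd.Series(dtype=float))))
        return empty, empty.copy(), pd.DataFrame(
            columns=["participant_id", "night_date", "hr_night_mean", "n_bins"]
        )

    bins = bin_15min_hr(s)
    hours = bins["bin_start"].dt.hour
    is_night = (hours >= thresholds.night_start_hour) | (
        hours < thresholds.day_start_hour
    )
    night = bins[is_night].copy()
    day = bins[~is_night].copy()

    day["date"] = day["bin_start"].dt.normalize()
    day_counts = day.groupby(["participant_id", "date"])["bin_start"].transform("size")
    day = day[day_counts >= thresholds.hr_day_min_bins].drop(columns=[]).reset_index(drop=True)

    night["night_date"] = night["bin_start"].dt.normalize().where(
        night["bin_start"].dt.hour >= thresholds.night_start_hour,
        night["bin_start"].dt.normalize() - pd.Timedelta(days=1),
    )
    night_counts = night.groupby(["participant_id", "night_date"])[
        "bin_start"
    ].transform("size")
    night = night[night_counts >= thresholds.hr_night_min_bins].reset_index(drop=True)

    nightly = (
        night.groupby(["participant_id", "night_date"])
        .agg(hr_night_mean=("mean_bpm", "mean"), n_bins=("bin_start", "size"))
        .reset_index()
    )
    return day, night, nightly


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------

def completeness_filter(
    coverage: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLDS.completeness_fraction,
) -> set:
    """Participants whose valid-day fraction meets the completeness bar.

    ``coverage`` needs columns participant_id, valid_days, study_days.
    Keeps participants with valid_days / study_days >= threshold;
    participants with zero study days are excluded.
    """
    kept = set()
    for row in coverage.itertuples():
        if row.study_days <= 0:
            continue
        if row.valid_days / row.study_days >= threshold:
            kept.add(row.participant_id)
    return kept
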