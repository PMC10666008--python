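"""CSV schemas, readers and input validation.

Every intermediate of the pipeline is a plain CSV readable without this
package.  Timestamps are local time, ISO-8601 without offsets (the study
area spans a single time zone).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "ValidationReport", "validate_inputs", "read_csv"]

#: required columns per input kind
SCHEMAS: dict[str, list[str]] = {
    "weather": [
        "station_id", "timestamp", "air_temp_c", "rel_humidity_pct",
        "precip_mm", "wind_speed_ms", "global_radiation_wm2",
    ],
    "steps": ["participant_id", "timestamp", "steps"],
    "sleep": ["participant_id", "onset", "offset", "duration_s", "waso_s"],
    "hr": ["participant_id", "timestamp", "bpm"],
    "roster": [
        "participant_id", "sex", "birth_date", "height_cm", "weight_kg",
        "village_id",
    ],
    "sites": ["id", "lat", "lon"],
}


@dataclass
class ValidationReport:
    """Row-level diagnostics collected while checking input files."""

    issues: list[dict] = field(default_factory=list)

    def add(self, file: str, message: str, row: int | None = None,
            column: str | None = None) -> None:
        self.issues.append(
            {"file": file, "row": row, "column": column, "message": message}
        )

    @property
    def ok(self) -> bool:
        return not self.issues

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.issues, columns=["file", "row", "column", "message"])


def _check_timestamps(report: ValidationReport, name: str, df: pd.DataFrame,
                      col: str) -> pd.Series | None:
    try:
        ts = pd.to_datetime(df[col], format="ISO8601")
    except (ValueError, TypeError):
        ts = pd.to_datetime(df[col], errors="coerce")
        for i in ts[ts.isna()].index:
            report.add(name, f"unparseable timestamp {df.loc[i, col]!r}",
                       row=int(i), column=col)
        return None
    return ts


def validate_inputs(paths: dict[str, str | Path]) -> ValidationReport:
    """Schema-check the input CSVs; row-level diagnostics, fail fast.

    ``paths`` maps a schema kind (weather, steps, sleep, hr, roster,
    sites) to a file path.  Checks: file exists, required columns
    present, timestamps parseable, humidity within [0, 100], non-negative
    physical quantities, strictly increasing timestamps per weather
    station, duplicate keys.  Row numbers are 0-based data rows.
    """
    report = ValidationReport()
    for kind, path in paths.items():
        if kind not in SCHEMAS:
            report.add(str(path), f"unknown input kind {kind!r}")
            continue
        path = Path(path)
        if not path.exists():
            report.add(str(path), "file does not exist")
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001
            report.add(str(path), f"malformed CSV: {exc}")
            continue
        name = str(path)
        missing = [c for c in SCHEMAS[kind] if c not in df.columns]
        if missing:
            report.add(name, f"missing required columns: {missing}")
            continue

        if kind == "weather":
            ts = _check_timestamps(report, name, df, "timestamp")
            rh = pd.to_numeric(df["rel_humidity_pct"], errors="coerce")
            for i in df.index[(rh < 0) | (rh > 100)]:
                report.add(name, f"relative humidity out of [0,100]: {rh[i]}",
                           row=int(i), column="rel_humidity_pct")
            for col in ("precip_mm", "wind_speed_ms", "global_radiation_wm2"):
                vals = pd.to_numeric(df[col], errors="coerce")
                for i in df.index[vals < 0]:
                    report.add(name, f"negative value {vals[i]}", row=int(i),
                               column=col)
            if ts is not None:
                for station, grp in df.assign(_ts=ts).groupby("station_id"):
                    if not grp["_ts"].is_monotonic_increasing or grp["_ts"].duplicated().any():
                        report.add(
                            name,
                            f"timestamps not strictly increasing for station {station}",
                            column="timestamp",
                        )
        elif kind in ("steps", "hr"):
            _check_timestamps(report, name, df, "timestamp")
            value_col = "steps" if kind == "steps" else "bpm"
            vals = pd.to_numeric(df[value_col], errors="coerce")
            lo = 0 if kind == "steps" else 1
            for i in df.index[vals < lo]:
                report.add(name, f"value below {lo}: {vals[i]}", row=int(i),
                           column=value_col)
        elif kind == "sleep":
            on = _check_timestamps(report, name, df, "onset")
            off = _check_timestamps(report, name, df, "offset")
            if on is not None and off is not None:
                for i in df.index[off <= on]:
                    report.add(name, "offset not after onset", row=int(i))
        elif kind == "roster":
            for col in ("height_cm", "weight_kg"):
                vals = pd.to_numeric(df[col], errors="coerce")
                for i in df.index[~(vals > 0)]:
                    report.add(name, f"non-positive {col}", row=int(i), column=col)
            dup = df["participant_id"].duplicated()
            for i in df.index[dup]:
                report.add(name, "duplicate participant_id", row=int(i),
                           column="participant_id")
        elif kind == "sites":
            lat = pd.to_numeric(df["lat"], errors="coerce")
            lon = pd.to_numeric(df["lon"], errors="coerce")
            for i in df.index[(lat < -90) | (lat > 90) | (lon < -180) | (lon > 180)]:
                report.add(name, "coordinate out of bounds", row=int(i))
    return report


def read_csv(kind: str, path: str | Path) -> pd.DataFrame:
    """Read one input CSV, parsing its timestamp-like columns."""
    df = pd.read_csv(Path(path))
    date_cols = {
        "weather": ["timestamp"],
        "steps": ["timestamp"],
        "hr": ["timestamp"],
        "sleep": ["onset", "offset"],
        "roster": ["birth_date"],
        "sites": [],
    }[kind]
    for c in date_cols:
        df[c] = pd.to_datetime(df[c])
    return df
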