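"""Every analysis cut-off in one place.

All thresholds used by the exposure and QC stages live in this frozen
dataclass so that boundary semantics (``>=`` vs strict ``>``) are encoded
exactly once and every override is visible in the run manifest.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Any, Mapping


@dataclass(frozen=True)
class Thresholds:
    """Exposure and wearable-QC cut-offs.

    Boundary semantics: heavy rain, hot days, heat-stress days/nights use
    ``>=``; tropical nights use strict ``>``.
    """

    # -- extreme-weather indexes (degC / mm) --
    heavy_rain_mm: float = 20.0          # daily rainfall >= 20 mm
    hot_day_c: float = 35.0              # daily max air temperature >= 35 C
    tropical_night_c: float = 20.0       # night min air temperature  > 20 C
    heat_stress_wbgt_c: float = 30.0     # daily max WBGT >= 30 C
    heat_stress_hi_c: float = 25.0       # night min heat index >= 25 C

    # -- day/night windows (local clock hours) --
    day_start_hour: int = 6              # day   = [06:00, 22:00)
    night_start_hour: int = 22           # night = [22:00, 06:00 next day)

    # -- wearable QC --
    min_wear_hours: float = 10.0         # steps: include day if wear >= 10 h
    nonwear_gap_hours: float = 1.0       # gap > 1 h between epochs = non-wear
    epoch_minutes: int = 15              # step/HR aggregation interval
    sleep_onset_earliest_hour: int = 17  # sleep onset >= 17:00
    sleep_offset_latest_hour: int = 13   # sleep offset <= 13:00 next day
    sleep_min_span_hours: float = 3.0    # onset-to-offset < 3 h is invalid
    hr_day_min_bins: int = 8             # >= 2 h of populated 15-min bins
    hr_night_min_bins: int = 4           # >= 1 h of populated 15-min bins
    completeness_fraction: float = 0.25  # complete case: >= 25% of study days

    # -- insufficient-sleep definition (hours) --
    insufficient_sleep_minor_h: float = 8.0   # aged < 18
    insufficient_sleep_adult_h: float = 7.0   # aged >= 18

    def asdict(self) -> dict[str, Any]:
        return asdict(self)

    def override(self, **kwargs: Any) -> "Thresholds":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any] | None) -> "Thresholds":
        if not mapping:
            return cls()
        unknown = set(mapping) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown threshold fields: {sorted(unknown)}")
        return cls(**mapping)


DEFAULT_THRESHOLDS = Thresholds()
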