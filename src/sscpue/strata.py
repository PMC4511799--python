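"""Spatial and temporal stratification of the fishing season.

Areas are latitude bands (no longitudinal structure), ordered north to
south.  Time strata are calendar months and weeks; weeks follow the ISO
convention (Monday start) unless a custom anchor date is configured.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field

from .errors import ConfigError

MONTH_NAMES = list(calendar.month_name)  # MONTH_NAMES[5] == "May"


@dataclass(frozen=True)
class Area:
    """One latitude band, ``lat_min`` (south edge) to ``lat_max`` (north)."""

    code: str
    lat_min: float
    lat_max: float

    def __post_init__(self):
        if not self.lat_min < self.lat_max:
            raise ConfigError(
                f"area {self.code!r}: lat_min {self.lat_min} must be < "
                f"lat_max {self.lat_max}"
            )


@dataclass
class StrataConfig:
    """Latitude-band areas plus the season calendar.

    Bands must be non-overlapping; they need not be contiguous (the study
    design may leave unsampled gaps between bands).  Band membership uses
    the half-open convention [lat_min, lat_max), except the northernmost
    band which is closed at its top edge, so a point exactly on a shared
    boundary belongs to the band whose *lat_max* equals that latitude.
    """

    areas: list[Area]
    season_start: dt.date
    season_end: dt.date
    week_rule: str = "iso_monday"
    week_anchor: dt.date | None = None
    month_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.areas:
            raise ConfigError("at least one area required")
        codes = [a.code for a in self.areas]
        if len(set(codes)) != len(codes):
            raise ConfigError(f"duplicate area codes in {codes}")
        # sort north -> south, then check pairwise overlap
        self.areas = sorted(self.areas, key=lambda a: -a.lat_max)
        for hi, lo in zip(self.areas, self.areas[1:]):
            if lo.lat_max > hi.lat_min:
                raise ConfigError(
                    f"areas {hi.code!r} and {lo.code!r} overlap: "
                    f"[{lo.lat_min}, {lo.lat_max}) vs [{hi.lat_min}, {hi.lat_max})"
                )
        if self.season_end < self.season_start:
            raise ConfigError("season_end precedes season_start")
        if self.week_rule not in ("iso_monday", "custom_anchor"):
            raise ConfigError(f"unknown week_rule {self.week_rule!r}")
        if self.week_rule == "custom_anchor" and self.week_anchor is None:
            raise ConfigError("week_rule 'custom_anchor' requires week_anchor")
        if not self.month_labels:
            months = []
            d = self.season_start.replace(day=1)
            while d <= self.season_end:
                months.append(MONTH_NAMES[d.month])
                d = (d + dt.timedelta(days=32)).replace(day=1)
            self.month_labels = months

    @property
    def area_codes(self) -> list[str]:
        return [a.code for a in self.areas]

    def area_of(self, lat: float) -> str | None:
        """Area code containing ``lat``, or None if in no band."""
        for i, a in enumerate(self.areas):
            top_closed = i == 0
            if a.lat_min <= lat < a.lat_max or (top_closed and lat == a.lat_max):
                return a.code
        return None

    def week_of(self, d: dt.date) -> int:
        if self.week_rule == "iso_monday":
            return d.isocalendar()[1]
        return (d - self.week_anchor).days // 7

    def month_of(self, d: dt.date) -> str:
        return MONTH_NAMES[d.month]

    def in_season(self, d: dt.date) -> bool:
        return self.season_start <= d <= self.season_end

    def season_dates(self) -> list[dt.date]:
        n = (self.season_end - self.season_start).days + 1
        return [self.season_start + dt.timedelta(days=i) for i in range(n)]
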