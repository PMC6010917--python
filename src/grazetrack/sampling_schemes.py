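"""Reduced logging patterns and battery-life projection.

Constant logging records a fix every 20 s. The two reduced patterns are
emulated by subsampling constant-logging data:

* **regular** — one fix per clock-aligned window (5- or 10-min): the first
  fix of each window is retained;
* **burst** — the full 20-s stream during the first 5 or 10 minutes of
  each hour, then silence (a power-timer duty cycle).

Duty cycling extends battery life multiplicatively; the projection helper
turns a base runtime and an extension factor into hours and whole days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "LoggingScheme",
    "STANDARD_SCHEMES",
    "assign_window",
    "subsample_regular",
    "subsample_burst",
    "BatteryProjection",
    "battery_life_projection",
]


@dataclass(frozen=True)
class LoggingScheme:
    """A logging pattern. ``interval_min`` is the window width for
    ``regular``, the burst duration for ``burst``, and ignored for
    ``constant``."""

    pattern: str                  # "constant" | "regular" | "burst"
    interval_min: int | None = None
    base_interval_s: int = 20

    def __post_init__(self):
        if self.pattern not in ("constant", "regular", "burst"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern != "constant" and (
                self.interval_min is None or self.interval_min <= 0):
            raise ValueError("regular/burst schemes need a positive interval")

    @property
    def name(self) -> str:
        if self.pattern == "constant":
            return "constant"
        return f"{self.pattern}_{self.interval_min}"

    def apply(self, fixes: pd.DataFrame, time_col: str = "time_local",
              ) -> pd.DataFrame:
        if self.pattern == "constant":
            return fixes.reset_index(drop=True)
        if self.pattern == "regular":
            return subsample_regular(fixes, self.interval_min, time_col)
        return subsample_burst(fixes, self.interval_min, time_col)


#: The four reduced schemes studied, plus the constant baseline.
STANDARD_SCHEMES: tuple[LoggingScheme, ...] = (
    LoggingScheme("constant"),
    LoggingScheme("regular", 5),
    LoggingScheme("regular", 10),
    LoggingScheme("burst", 5),
    LoggingScheme("burst", 10),
)


def assign_window(timestamp, width_min: int):
    """Clock-aligned window start for a timestamp (e.g. 08:04:59 at width
    5 -> 08:00). ``width_min`` must divide 60 so windows align with hours."""
    if 60 % width_min != 0:
        raise ValueError(f"window width {width_min} min must divide 60")
    return pd.Timestamp(timestamp).floor(f"{width_min}min")


def _windows(t: pd.Series, width_min: int) -> pd.Series:
    if 60 % width_min != 0:
        raise ValueError(f"window width {width_min} min must divide 60")
    return pd.to_datetime(t).dt.floor(f"{width_min}min")


def subsample_regular(fixes: pd.DataFrame, width_min: int,
                      time_col: str = "time_local") -> pd.DataFrame:
    """First fix of each non-empty clock-aligned window, in time order.
    Ties inside a window are broken by input (file) order."""
    if fixes.empty:
        return fixes.reset_index(drop=True)
    win = _windows(fixes[time_col], width_min)
    keep = ~win.duplicated(keep="first")
    return fixes.loc[keep].reset_index(drop=True)


def subsample_burst(fixes: pd.DataFrame, duration_min: int,
                    time_col: str = "time_local",
                    phase_min: int = 0) -> pd.DataFrame:
    """All fixes within the burst window of each hour (by default the
    first ``duration_min`` minutes; ``phase_min`` shifts the window)."""
    if fixes.empty:
        return fixes.reset_index(drop=True)
    t = pd.to_datetime(fixes[time_col])
    sec_of_hour = t.dt.minute * 60 + t.dt.second + t.dt.microsecond / 1e6
    lo = phase_min * 60.0
    hi = lo + duration_min * 60.0
    keep = (sec_of_hour >= lo) & (sec_of_hour < hi)
    return fixes.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class BatteryProjection:
    hours: float
    days_exact: float   # hours / 24, reported to one decimal
    days_whole: int     # floor of days_exact


def battery_life_projection(base_hours: float, extension_factor: float,
                            ) -> BatteryProjection:
    """Project duty-cycled battery life: ``hours = base × factor``,
    converted to days (one decimal, and floored whole days).

    >>> battery_life_projection(171, 7.5).hours
    1282.5
    >>> battery_life_projection(1306, 1).days_whole
    54
    """
    if base_hours <= 0 or extension_factor <= 0:
        raise ValueError("base_hours and extension_factor must be positive")
    hours = base_hours * extension_factor
    days = hours / 24.0
    return BatteryProjection(hours=hours,
                             days_exact=round(days, 1),
                             days_whole=math.floor(days))
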