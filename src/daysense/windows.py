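"""Clock-time windows and the accelerometer stationary band.

All windows are half-open intervals ``[start, end)`` in minutes since
local midnight, so the four canonical windows partition the 24-hour day
exactly and a poll at a boundary belongs to exactly one window (12:00 is
"day", 06:00 is "am").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class TimeWindow:
    """Half-open clock-time window ``[start_min, end_min)``."""

    name: str
    start_min: int
    end_min: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_min < self.end_min <= MINUTES_PER_DAY):
            raise ValueError(f"invalid window bounds [{self.start_min}, {self.end_min})")

    @property
    def n_minutes(self) -> int:
        return self.end_min - self.start_min

    def contains(self, minute_of_day):
        """Vectorized membership test for minutes since local midnight."""
        m = np.asarray(minute_of_day)
        return (m >= self.start_min) & (m < self.end_min)


#: Canonical windows: night = midnight-6am, am = 6am-noon, day = noon-4pm,
#: eve = 4pm-midnight (the complement, so the four partition 24 h).
CANONICAL_WINDOWS: dict[str, TimeWindow] = {
    "night": TimeWindow("night", 0, 360),
    "am": TimeWindow("am", 360, 720),
    "day": TimeWindow("day", 720, 960),
    "eve": TimeWindow("eve", 960, 1440),
}

#: Peak calling hours (business hours, configurable): 9am-6pm.
PEAK_HOURS = TimeWindow("peak", 540, 1080)


@dataclass(frozen=True)
class StationaryBand:
    """Relative-gravity interval inside which the device counts as at rest.

    Relative gravity is acceleration expressed as a multiple of earth's
    gravity, ~1.0 for a stationary device.  A poll is *active* when its
    value falls outside ``[low, high]`` in either direction.
    """

    low: float = 0.8
    high: float = 1.2

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("stationary band requires low < high")

    def is_active(self, relative_gravity):
        rg = np.asarray(relative_gravity, dtype=float)
        return (rg < self.low) | (rg > self.high)


def minute_of_day(timestamps) -> np.ndarray:
    """Minutes since local midnight for a datetime64 array/Series."""
    import pandas as pd

    ts = pd.DatetimeIndex(np.asarray(timestamps, dtype="datetime64[ns]"))
    return (ts.hour * 60 + ts.minute).to_numpy()
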