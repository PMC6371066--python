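"""Day-wise feature extraction from raw poll and call streams.

Every operation works on one participant-day of records and follows a
strict missing-data policy: a stream that is absent for a day yields
missing values for the features derived from it, never fabricated
zeros.  Aggregation over windows is half-open, so window sub-counts sum
exactly to the day total.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from daysense.registry import DEFAULT_REGISTRY
from daysense.windows import (
    CANONICAL_WINDOWS,
    PEAK_HOURS,
    StationaryBand,
    TimeWindow,
    minute_of_day,
)

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: Grid resolution for distinct-location counting: 3 decimal degrees,
#: about 110 m at the equator.
LOCATION_GRID_DECIMALS = 3

#: Consecutive-poll hops shorter than this are GPS jitter and contribute
#: zero distance.
JITTER_FLOOR_M = 20.0


# ---------------------------------------------------------------------------
# poll-based features


def compute_activity_rate(
    polls: pd.DataFrame,
    window: TimeWindow | None = None,
    band: StationaryBand = StationaryBand(),
) -> float:
    """Number of polls whose relative gravity falls outside the stationary band.

    Parameters
    ----------
    polls : one participant-day of sensor polls with columns
        ``timestamp`` and ``relative_gravity``.
    window : restrict to a clock window; ``None`` means the whole day.
    band : the stationary relative-gravity band (default [0.8, 1.2]).

    Returns NaN when the day has no polls at all (missing, not zero).
    """
    if len(polls) == 0:
        return np.nan
    active = band.is_active(polls["relative_gravity"].to_numpy())
    if window is not None:
        active = active & window.contains(minute_of_day(polls["timestamp"]))
    return float(np.count_nonzero(active))


def compute_screen_on_count(polls: pd.DataFrame, window: TimeWindow | None = None) -> float:
    """Number of polls in the window during which the screen was on.

    NaN when the day has no polls.
    """
    if len(polls) == 0:
        return np.nan
    on = polls["screen_on"].to_numpy().astype(bool)
    if window is not None:
        on = on & window.contains(minute_of_day(polls["timestamp"]))
    return float(np.count_nonzero(on))


def compute_sleep_features(
    polls: pd.DataFrame,
    band: StationaryBand = StationaryBand(),
    night: TimeWindow = CANONICAL_WINDOWS["night"],
    poll_interval_min: float = 2.0,
) -> dict[str, float]:
    """Sleep-related features from the night window (midnight-6am).

    Sleep is estimated as the longest contiguous run of night polls that
    are simultaneously stationary (inside the band) and screen-off; its
    length times the poll interval gives ``sleep_minutes``.  A wake
    episode is a maximal run of night polls violating that condition.

    Returns a dict with keys ``sleep_minutes``, ``night_screen_ons``,
    ``night_stationary_fraction``, ``sleep_efficiency`` and
    ``wake_episodes``; all NaN when the day has no night polls.
    """
    keys = (
        "sleep_minutes",
        "night_screen_ons",
        "night_stationary_fraction",
        "sleep_efficiency",
        "wake_episodes",
    )
    if len(polls) > 0:
        in_night = night.contains(minute_of_day(polls["timestamp"]))
    else:
        in_night = np.zeros(0, dtype=bool)
    if not in_night.any():
        return {k: np.nan for k in keys}
    sub = polls.loc[in_night].sort_values("timestamp")
    rg = sub["relative_gravity"].to_numpy()
    on = sub["screen_on"].to_numpy().astype(bool)
    stationary = ~band.is_active(rg)
    asleep = stationary & ~on
    longest = _longest_run(asleep)
    wake_runs = _count_runs(~asleep)
    return {
        "sleep_minutes": float(longest * poll_interval_min),
        "night_screen_ons": float(np.count_nonzero(on)),
        "night_stationary_fraction": float(np.mean(stationary)),
        "sleep_efficiency": float(longest * poll_interval_min / night.n_minutes),
        "wake_episodes": float(wake_runs),
    }


def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def _count_runs(mask: np.ndarray) -> int:
    """Number of maximal runs of True values."""
    if len(mask) == 0:
        return 0
    m = mask.astype(np.int8)
    starts = np.diff(np.concatenate([[0], m])) == 1
    return int(np.count_nonzero(starts))


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters (earth radius 6,371,000 m)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def compute_mobility_features(
    polls: pd.DataFrame,
    window: TimeWindow | None = None,
    grid_decimals: int = LOCATION_GRID_DECIMALS,
    jitter_floor_m: float = JITTER_FLOOR_M,
) -> tuple[float, float]:
    """(distinct_locations, distance_m) from located polls.

    Locations are counted as distinct cells after snapping coordinates
    to a ``grid_decimals``-decimal-degree grid.  Distance sums haversine
    hops between consecutive located polls of the day, each hop assigned
    to the window of its departure poll; hops below ``jitter_floor_m``
    count as GPS jitter and contribute zero.

    Missing-value rules: no located polls -> both NaN; a single located
    poll -> distance NaN.  With a window restriction, counts are NaN
    only when the *day* lacks the needed located polls.
    """
    located = polls.dropna(subset=["lat", "lon"]) if len(polls) else polls
    if len(located) == 0:
        return (np.nan, np.nan)
    located = located.sort_values("timestamp")
    lat = located["lat"].to_numpy(dtype=float)
    lon = located["lon"].to_numpy(dtype=float)
    minutes = minute_of_day(located["timestamp"])
    in_w = np.ones(len(located), dtype=bool) if window is None else window.contains(minutes)

    cells = set(zip(np.round(lat[in_w], grid_decimals), np.round(lon[in_w], grid_decimals)))
    n_loc = float(len(cells)) if in_w.any() else (np.nan if window is not None else 0.0)

    if len(located) < 2:
        return (n_loc if in_w.any() else np.nan, np.nan)
    hops = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    hops = np.where(hops < jitter_floor_m, 0.0, hops)
    hop_in_w = in_w[:-1]  # hop belongs to the window of the departure poll
    return (n_loc, float(hops[hop_in_w].sum()))


# ---------------------------------------------------------------------------
# call-based features


def _call_subset_features(calls: pd.DataFrame) -> dict[str, float]:
    direction = calls["direction"].to_numpy() if len(calls) else np.array([], dtype=object)
    made = direction == "made"
    received = direction == "received"
    missed = direction == "missed"
    connected = made | received
    dur = calls["duration_min"].to_numpy(dtype=float) if len(calls) else np.array([])
    n_total = int(np.count_nonzero(connected))
    duration_total = float(dur[connected].sum()) if n_total else 0.0
    people = calls.loc[connected, "contact_id"].nunique() if n_total else 0
    return {
        "calls_total": float(n_total),
        "calls_made": float(np.count_nonzero(made)),
        "calls_received": float(np.count_nonzero(received)),
        "calls_missed": float(np.count_nonzero(missed)),
        "call_duration_total": duration_total,
        "call_duration_mean": duration_total / n_total if n_total else np.nan,
        "people_called": float(people),
    }


def compute_call_features(
    calls: pd.DataFrame,
    peak: TimeWindow = PEAK_HOURS,
    covered: bool = False,
) -> dict[str, float]:
    """Communication features for one participant-day of call events.

    ``calls_total`` counts made+received calls; missed calls are kept as
    a separate feature.  ``people_called`` is the number of distinct
    contacts over made+received calls.  Peak/off-peak splits partition
    events at the ``peak`` clock window.

    A day with no call records is treated as *absent from the logs* and
    every feature is missing — unless ``covered=True`` asserts that the
    log explicitly covers the day with zero events, in which case counts
    are 0 (mean durations stay missing: division guard).
    """
    names = [k for k in DEFAULT_REGISTRY if k.startswith(("calls_", "call_duration", "people_called"))]
    if len(calls) == 0 and not covered:
        return {k: np.nan for k in names}
    out: dict[str, float] = dict(_call_subset_features(calls))
    if len(calls):
        in_peak = peak.contains(minute_of_day(calls["timestamp"]))
        peak_calls, offpeak_calls = calls.loc[in_peak], calls.loc[~in_peak]
        made = calls["direction"].to_numpy() == "made"
        received = calls["direction"].to_numpy() == "received"
        dur = calls["duration_min"].to_numpy(dtype=float)
        out["call_duration_made"] = float(dur[made].sum())
        out["call_duration_received"] = float(dur[received].sum())
    else:
        peak_calls = offpeak_calls = calls
        out["call_duration_made"] = 0.0
        out["call_duration_received"] = 0.0
    for suffix, sub in (("peak", peak_calls), ("offpeak", offpeak_calls)):
        for key, value in _call_subset_features(sub).items():
            out[f"{key}_{suffix}"] = value
    return out


# ---------------------------------------------------------------------------
# per-day assembly and bulk extraction


def extract_daily_features(
    polls: pd.DataFrame,
    calls: pd.DataFrame,
    participant_id: str,
    date,
    registry: Iterable[str] = DEFAULT_REGISTRY,
    band: StationaryBand = StationaryBand(),
    windows: Mapping[str, TimeWindow] = CANONICAL_WINDOWS,
    peak: TimeWindow = PEAK_HOURS,
    poll_interval_min: float = 2.0,
    call_covered: bool = False,
) -> dict[str, float]:
    """One participant-day's feature vector over the registered variables.

    Streams are independent: polls absent -> poll-derived features
    missing while call features are still computed, and vice versa.
    """
    values: dict[str, float] = {}
    have_polls = len(polls) > 0
    minutes = minute_of_day(polls["timestamp"]) if have_polls else np.zeros(0, dtype=int)
    active = band.is_active(polls["relative_gravity"].to_numpy()) if have_polls else None
    screen = polls["screen_on"].to_numpy().astype(bool) if have_polls else None

    def _win_counts(flags: np.ndarray) -> dict[str, float]:
        per = {"total": float(np.count_nonzero(flags))}
        for wname, w in windows.items():
            per[wname] = float(np.count_nonzero(flags & w.contains(minutes)))
        return per

    if have_polls:
        act = _win_counts(active)
        scr = _win_counts(screen)
        for wname in ("total", *windows):
            values[f"activity_{wname}"] = act[wname]
            values[f"screen_on_{wname}"] = scr[wname]
            n_in = float(len(minutes)) if wname == "total" else float(
                np.count_nonzero(windows[wname].contains(minutes))
            )
            values[f"activity_frac_{wname}"] = act[wname] / n_in if n_in else np.nan
        values.update(compute_sleep_features(polls, band, windows["night"], poll_interval_min))
        for wname in ("total", *windows):
            w = None if wname == "total" else windows[wname]
            n_loc, dist = compute_mobility_features(polls, window=w)
            values[f"locations_{wname}"] = n_loc
            values[f"distance_{wname}"] = dist
    else:
        for wname in ("total", *windows):
            for prefix in ("activity", "activity_frac", "screen_on", "locations", "distance"):
                values[f"{prefix}_{wname}"] = np.nan
        values.update({k: np.nan for k in (
            "sleep_minutes", "night_screen_ons", "night_stationary_fraction",
            "sleep_efficiency", "wake_episodes",
        )})

    values.update(compute_call_features(calls, peak=peak, covered=call_covered))

    row = {"participant_id": participant_id, "date": date}
    for name in registry:
        if name not in values:
            raise KeyError(f"unknown feature in registry: {name!r}")
        row[name] = values[name]
    return row


def extract_features(
    polls: pd.DataFrame,
    calls: pd.DataFrame,
    registry: Iterable[str] = DEFAULT_REGISTRY,
    band: StationaryBand = StationaryBand(),
    windows: Mapping[str, TimeWindow] = CANONICAL_WINDOWS,
    peak: TimeWindow = PEAK_HOURS,
    poll_interval_min: float = 2.0,
    covered_call_days: set[tuple[str, object]] | None = None,
) -> pd.DataFrame:
    """Extract feature vectors for every participant-day in the streams.

    The participant-day universe is the union of days appearing in
    either stream.  ``covered_call_days`` optionally lists (participant,
    date) pairs whose call log is known to cover the day even when it
    holds zero events.
    """
    registry = list(registry)
    polls = polls.copy()
    calls = calls.copy()
    for df in (polls, calls):
        if len(df):
            df["timestamp"] = pd.to_datetime(df["timestamp"])
            df["_date"] = df["timestamp"].dt.date
    poll_groups = dict(tuple(polls.groupby(["participant_id", "_date"], sort=True))) if len(polls) else {}
    call_groups = dict(tuple(calls.groupby(["participant_id", "_date"], sort=True))) if len(calls) else {}
    days = sorted(set(poll_groups) | set(call_groups))
    empty_polls = polls.iloc[0:0]
    empty_calls = calls.iloc[0:0]
    covered = covered_call_days or set()
    rows = []
    for key in days:
        pid, date = key
        rows.append(
            extract_daily_features(
                poll_groups.get(key, empty_polls),
                call_groups.get(key, empty_calls),
                participant_id=pid,
                date=date,
                registry=registry,
                band=band,
                windows=windows,
                peak=peak,
                poll_interval_min=poll_interval_min,
                call_covered=key in covered,
            )
        )
    out = pd.DataFrame(rows, columns=["participant_id", "date", *registry])
    logger.info("extracted %d participant-day feature vectors", len(out))
    return out
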