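"""Feature extraction: worked examples, brute-force oracles and invariants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from daysense.features import (
    compute_activity_rate,
    compute_call_features,
    compute_mobility_features,
    compute_screen_on_count,
    compute_sleep_features,
    extract_daily_features,
    extract_features,
    haversine_m,
)
from daysense.windows import CANONICAL_WINDOWS, StationaryBand, TimeWindow

from conftest import make_calls, make_polls

BAND = StationaryBand()
AM, DAY, EVE, NIGHT = (CANONICAL_WINDOWS[w] for w in ("am", "day", "eve", "night"))


def random_day(rng, n=720):
    minutes = np.sort(rng.choice(1440, size=n, replace=False))
    rg = rng.uniform(0.0, 2.0, size=n)
    screen = rng.random(n) < 0.3
    return make_polls(minutes, rg, screen.astype(int))


class TestActivityAndScreen:
    def test_counts_polls_outside_stationary_band(self):
        polls = make_polls([400, 420, 440, 460], [1.0, 1.3, 0.7, 1.1])
        assert compute_activity_rate(polls, AM, BAND) == 2

    def test_stationary_day_is_zero_and_empty_day_is_missing(self):
        polls = make_polls([400, 420], [1.0, 1.1])
        assert compute_activity_rate(polls, AM, BAND) == 0
        assert np.isnan(compute_activity_rate(polls.iloc[0:0], AM, BAND))
        assert np.isnan(compute_screen_on_count(polls.iloc[0:0], NIGHT))

    def test_band_boundary_values_are_stationary(self):
        polls = make_polls([400, 420], [0.8, 1.2])
        assert compute_activity_rate(polls, AM, BAND) == 0

    def test_full_night_window_screen_on_capacity(self):
        polls = make_polls(np.arange(0, 360, 2), screen_on=np.ones(180, dtype=int))
        assert compute_screen_on_count(polls, NIGHT) == 180

    def test_counts_match_bruteforce_oracle_on_random_streams(self, rng):
        for _ in range(20):
            polls = random_day(rng, n=500)
            low, high = sorted(rng.uniform(0.2, 1.8, size=2))
            band = StationaryBand(low, high)
            window = CANONICAL_WINDOWS[rng.choice(["am", "day", "eve", "night"])]
            naive_active = sum(
                1
                for _, row in polls.iterrows()
                if window.start_min <= row.timestamp.hour * 60 + row.timestamp.minute < window.end_min
                and not (low <= row.relative_gravity <= high)
            )
            naive_screen = sum(
                1
                for _, row in polls.iterrows()
                if window.start_min <= row.timestamp.hour * 60 + row.timestamp.minute < window.end_min
                and row.screen_on
            )
            assert compute_activity_rate(polls, window, band) == naive_active
            assert compute_screen_on_count(polls, window) == naive_screen

    def test_window_partition_conservation(self, rng):
        polls = random_day(rng)
        total = compute_activity_rate(polls, None, BAND)
        parts = sum(compute_activity_rate(polls, w, BAND) for w in CANONICAL_WINDOWS.values())
        assert total == parts
        total_s = compute_screen_on_count(polls, None)
        parts_s = sum(compute_screen_on_count(polls, w) for w in CANONICAL_WINDOWS.values())
        assert total_s == parts_s

    def test_half_open_window_boundaries(self):
        polls = make_polls([360, 720], [1.5, 1.5])  # exactly 06:00 and 12:00
        assert compute_activity_rate(polls, AM, BAND) == 1  # 06:00 belongs to am
        assert compute_activity_rate(polls, DAY, BAND) == 1  # 12:00 belongs to day
        assert compute_activity_rate(polls, NIGHT, BAND) == 0

    def test_adding_out_of_band_poll_never_decreases_count(self, rng):
        polls = random_day(rng, n=100)
        before = compute_activity_rate(polls, None, BAND)
        extra = make_polls([700], [1.9])
        after = compute_activity_rate(pd.concat([polls, extra]), None, BAND)
        assert after == before + 1


class TestSleep:
    def test_full_stationary_screen_off_night_gives_360_minutes(self):
        polls = make_polls(np.arange(0, 360, 2))
        out = compute_sleep_features(polls)
        assert out["sleep_minutes"] == 360.0
        assert out["night_screen_ons"] == 0.0
        assert out["night_stationary_fraction"] == 1.0
        assert out["sleep_efficiency"] == 1.0
        assert out["wake_episodes"] == 0.0

    def test_alternating_screen_polls_force_two_minute_sleep(self):
        screen = np.arange(180) % 2
        polls = make_polls(np.arange(0, 360, 2), screen_on=screen)
        assert compute_sleep_features(polls)["sleep_minutes"] == 2.0

    def test_no_night_polls_gives_missing(self):
        polls = make_polls([400, 500])
        assert all(np.isnan(v) for v in compute_sleep_features(polls).values())

    def test_longest_run_matches_bruteforce_scan(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 180))
            minutes = np.sort(rng.choice(360, size=n, replace=False))
            rg = rng.uniform(0.5, 1.5, size=n)
            screen = (rng.random(n) < 0.4).astype(int)
            polls = make_polls(minutes, rg, screen)
            asleep = [(0.8 <= g <= 1.2) and not s for g, s in zip(rg, screen)]
            best = cur = 0
            for flag in asleep:
                cur = cur + 1 if flag else 0
                best = max(best, cur)
            assert compute_sleep_features(polls)["sleep_minutes"] == 2.0 * best


class TestMobility:
    def test_single_location_zero_distance(self):
        polls = make_polls([400, 420, 440], lat=[19.0] * 3, lon=[74.0] * 3)
        n_loc, dist = compute_mobility_features(polls)
        assert n_loc == 1 and dist == 0.0

    def test_one_degree_latitude_is_111km(self):
        polls = make_polls([400, 420], lat=[19.0, 20.0], lon=[74.0, 74.0])
        _, dist = compute_mobility_features(polls)
        assert dist == pytest.approx(111_195, rel=1e-3)

    def test_no_coordinates_gives_missing(self):
        polls = make_polls([400, 420])
        n_loc, dist = compute_mobility_features(polls)
        assert np.isnan(n_loc) and np.isnan(dist)

    def test_single_located_poll_distance_missing(self):
        polls = make_polls([400], lat=[19.0], lon=[74.0])
        n_loc, dist = compute_mobility_features(polls)
        assert n_loc == 1 and np.isnan(dist)

    def test_random_walk_matches_bruteforce_haversine_sum(self, rng):
        n = 100
        lat = 19.0 + np.cumsum(rng.normal(0, 0.002, n))
        lon = 74.0 + np.cumsum(rng.normal(0, 0.002, n))
        polls = make_polls(np.arange(0, 2 * n, 2), lat=lat, lon=lon)
        expected = 0.0
        for i in range(n - 1):
            hop = float(haversine_m(lat[i], lon[i], lat[i + 1], lon[i + 1]))
            if hop >= 20.0:
                expected += hop
        _, dist = compute_mobility_features(polls)
        assert dist == pytest.approx(expected, rel=1e-9)

    def test_jitter_below_floor_contributes_zero(self):
        # ~11 m hops: below the 20 m jitter floor
        polls = make_polls([0, 2, 4], lat=[19.0, 19.0001, 19.0002], lon=[74.0] * 3)
        _, dist = compute_mobility_features(polls)
        assert dist == 0.0


class TestCalls:
    def test_worked_example(self):
        calls = make_calls(
            [600, 610, 620, 630],
            ["made", "made", "received", "missed"],
            [3.0, 5.0, 4.0, 0.0],
            ["A", "A", "B", "C"],
        )
        out = compute_call_features(calls)
        assert out["calls_total"] == 3
        assert out["people_called"] == 2
        assert out["call_duration_total"] == 12.0
        assert out["calls_missed"] == 1
        assert out["call_duration_mean"] == pytest.approx(4.0)

    def test_absent_day_missing_but_covered_day_zero(self):
        empty = make_calls([], [], [], [])
        absent = compute_call_features(empty)
        assert all(np.isnan(v) for v in absent.values())
        covered = compute_call_features(empty, covered=True)
        assert covered["calls_total"] == 0.0
        assert np.isnan(covered["call_duration_mean"])  # division guard

    def test_peak_offpeak_partition(self, rng):
        n = 50
        calls = make_calls(
            rng.integers(0, 1440, n),
            rng.choice(["made", "received", "missed"], n),
            rng.uniform(0, 10, n).round(2),
            [f"c{int(i)}" for i in rng.integers(0, 10, n)],
        )
        out = compute_call_features(calls)
        for base in ("calls_total", "calls_made", "calls_received", "calls_missed", "call_duration_total"):
            assert out[f"{base}_peak"] + out[f"{base}_offpeak"] == pytest.approx(out[base])

    def test_random_day_matches_naive_aggregate_oracle(self, rng):
        n = 50
        minutes = rng.integers(0, 1440, n)
        directions = rng.choice(["made", "received", "missed"], n)
        durations = np.where(directions == "missed", 0.0, rng.uniform(0.5, 30, n).round(2))
        contacts = [f"c{int(i)}" for i in rng.integers(0, 12, n)]
        calls = make_calls(minutes, directions, durations, contacts)
        out = compute_call_features(calls)
        connected = [i for i in range(n) if directions[i] in ("made", "received")]
        assert out["calls_total"] == len(connected)
        assert out["calls_made"] == sum(directions == "made")
        assert out["calls_missed"] == sum(directions == "missed")
        assert out["call_duration_total"] == pytest.approx(sum(durations[i] for i in connected))
        assert out["people_called"] == len({contacts[i] for i in connected})

    def test_adding_a_call_never_decreases_total(self, rng):
        calls = make_calls([600, 700], ["made", "received"], [1.0, 2.0], ["A", "B"])
        before = compute_call_features(calls)["calls_total"]
        more = pd.concat([calls, make_calls([800], ["made"], [1.0], ["C"])])
        assert compute_call_features(more)["calls_total"] == before + 1


class TestDailyAssembly:
    def test_crafted_complete_day_has_no_missing_entries(self):
        polls = make_polls(
            np.arange(0, 1440, 2),
            relative_gravity=np.where(np.arange(720) % 7 == 0, 1.5, 1.0),
            screen_on=(np.arange(720) % 11 == 0).astype(int),
            lat=np.full(720, 19.0),
            lon=np.full(720, 74.0),
        )
        calls = make_calls(
            [500, 700, 1100], ["made", "received", "missed"], [2.0, 3.0, 0.0], ["A", "B", "A"]
        )
        row = extract_daily_features(polls, calls, "P001", "2016-01-04")
        values = {k: v for k, v in row.items() if k not in ("participant_id", "date")}
        assert len(values) == 53
        missing = [k for k, v in values.items() if isinstance(v, float) and np.isnan(v)]
        assert missing == []

    def test_stream_independence_polls_without_calls(self):
        polls = make_polls(np.arange(0, 1440, 2))
        row = extract_daily_features(polls, make_calls([], [], [], []), "P001", "2016-01-04")
        assert np.isnan(row["calls_total"])
        assert row["activity_total"] == 0.0
        assert row["screen_on_total"] == 0.0

    def test_unknown_registry_feature_raises(self):
        polls = make_polls([400])
        with pytest.raises(KeyError):
            extract_daily_features(polls, make_calls([], [], [], []), "P001", "2016-01-04",
                                   registry=["no_such_feature"])

    def test_bulk_extraction_covers_union_of_stream_days(self):
        polls = make_polls(np.arange(0, 1440, 2), date="2016-01-04")
        calls = make_calls([600], ["made"], [2.0], ["A"], date="2016-01-05")
        out = extract_features(polls, calls)
        assert len(out) == 2
        day1 = out[out["date"].astype(str) == "2016-01-05"].iloc[0]
        assert day1["calls_total"] == 1.0
        assert np.isnan(day1["activity_total"])


@settings(max_examples=25, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=1439), min_size=1, max_size=60, unique=True),
       st.integers(min_value=0, max_value=2**31 - 1))
def test_partition_conservation_property(minutes, seed):
    """Window sub-counts always sum to the day total for any poll layout."""
    rng = np.random.default_rng(seed)
    minutes = sorted(minutes)
    rg = rng.uniform(0.0, 2.0, size=len(minutes))
    screen = (rng.random(len(minutes)) < 0.5).astype(int)
    polls = make_polls(minutes, rg, screen)
    total = compute_activity_rate(polls, None, BAND)
    assert total == sum(compute_activity_rate(polls, w, BAND) for w in CANONICAL_WINDOWS.values())
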