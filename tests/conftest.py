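"""Shared fixtures: synthetic cohorts generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from daysense.features import extract_features
from daysense.labeling import label_cohort
from daysense.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 12-participant cohort with missingness, plus latent truth."""
    cfg = SimulationConfig(
        n_participants=12, study_days=28, missingness=0.2,
        prevalence_depressed=0.25, prevalence_mild=0.25, seed=42,
    )
    polls, calls, surveys, truth = simulate_cohort(cfg, return_truth=True)
    return cfg, polls, calls, surveys, truth


@pytest.fixture(scope="session")
def small_labeled(small_cohort):
    cfg, polls, calls, surveys, _ = small_cohort
    features = extract_features(polls, calls)
    labeled = label_cohort(features, surveys)
    return features, labeled


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the emulated study's scale: 46 participants, 8 weeks.

    Class-conditional channel parameters are the defaults; modest
    whole-day missingness leaves >2000 participant-days with
    communication data.
    """
    cfg = SimulationConfig(
        n_participants=46, study_days=56, missingness=0.15, seed=11,
    )
    polls, calls, surveys = simulate_cohort(cfg)
    features = extract_features(polls, calls)
    labeled = label_cohort(features, surveys)
    return cfg, labeled


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_polls(minutes, relative_gravity=None, screen_on=None, lat=None, lon=None,
               participant_id="P001", date="2016-01-04"):
    """Build a one-day poll frame from minutes-of-day and per-poll values."""
    minutes = np.asarray(minutes, dtype=int)
    n = len(minutes)
    base = pd.Timestamp(date)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": base + pd.to_timedelta(minutes, unit="m"),
            "relative_gravity": np.ones(n) if relative_gravity is None else np.asarray(relative_gravity, dtype=float),
            "screen_on": np.zeros(n, dtype=int) if screen_on is None else np.asarray(screen_on, dtype=int),
            "lat": np.full(n, np.nan) if lat is None else np.asarray(lat, dtype=float),
            "lon": np.full(n, np.nan) if lon is None else np.asarray(lon, dtype=float),
        }
    )


def make_calls(minutes, directions, durations, contacts, participant_id="P001", date="2016-01-04"):
    minutes = np.asarray(minutes, dtype=int)
    base = pd.Timestamp(date)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": base + pd.to_timedelta(minutes, unit="m"),
            "direction": list(directions),
            "duration_min": np.asarray(durations, dtype=float),
            "contact_id": list(contacts),
        }
    )
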