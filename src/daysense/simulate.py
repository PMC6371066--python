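"""Synthetic cohort simulator for passive smartphone-sensing studies.

The simulator generates raw streams — 2-minute sensor polls, call-log
events and biweekly PHQ-9 surveys — for a cohort in which each
participant-day's *extracted* daily aggregates follow configurable
class-conditional (mean, SD) targets.  Class D days (imputed PHQ-9 > 9)
and ND days draw from separate channel parameters, whose defaults are
the outlier-filtered summary statistics of the study population this
simulator emulates (lower daytime activity, more night screen-ons,
fewer calls and contacts among depressed participant-days; mobility
neutral between classes).

Mechanism, per participant-day:

* each behavioral channel draws a daily target from a gamma
  distribution moment-matched to the configured (mean, SD) — the
  standard choice for non-negative, right-skewed behavioral aggregates;
  count channels are then stochastically rounded (floor plus a
  Bernoulli on the fractional part) so expected counts equal the
  configured means exactly;
* communication channels (calls, people, duration) share a Gaussian
  copula factor so that "people called" never has to be clipped against
  the number of calls (the call count is raised to the people count in
  the rare residual violations);
* targets are realized as raw records: active/screen-on poll slots are
  placed uniformly within their window, calls within calling hours,
  GPS as a participant home point plus daytime excursions with ~3 m
  jitter;
* whole participant-day stream units are then dropped independently
  per stream with the configured missingness probability.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from daysense.windows import CANONICAL_WINDOWS, MINUTES_PER_DAY

logger = logging.getLogger(__name__)

#: Default class-conditional (mean, SD) of the daily aggregate per
#: behavioral channel.  The six channels with a documented
#: depressed/not-depressed contrast carry it; the remaining channels are
#: neutral between classes (mobility contrasts were reported as not
#: significant in the population emulated here).
DEFAULT_CHANNEL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "activity_am": {"D": (11.06, 7.93), "ND": (14.87, 10.80)},
    "activity_day": {"D": (12.95, 6.96), "ND": (18.61, 16.49)},
    "activity_eve": {"D": (14.0, 9.0), "ND": (14.0, 9.0)},
    "activity_night": {"D": (1.0, 1.5), "ND": (1.0, 1.5)},
    "screen_am": {"D": (22.0, 12.0), "ND": (22.0, 12.0)},
    "screen_day": {"D": (16.0, 9.0), "ND": (16.0, 9.0)},
    "screen_eve": {"D": (30.0, 14.0), "ND": (30.0, 14.0)},
    "screen_night": {"D": (4.58, 5.54), "ND": (1.32, 1.69)},
    "calls_total": {"D": (11.69, 7.58), "ND": (16.02, 11.54)},
    "people_called": {"D": (4.22, 2.37), "ND": (7.59, 5.34)},
    "call_duration": {"D": (15.24, 12.52), "ND": (21.36, 19.21)},
    "calls_missed": {"D": (1.2, 1.5), "ND": (1.2, 1.5)},
    "excursions": {"D": (2.0, 1.3), "ND": (2.0, 1.3)},
}

#: Channels jointly driven by a per-day "sociability" copula factor.
_COMM_CHANNELS = ("calls_total", "people_called", "call_duration")

#: Within-day intensity windows (minutes since midnight).
CALL_HOURS = (480, 1260)  # calls placed 8:00-21:00
EXCURSION_HOURS = (480, 1200)  # trips 8:00-20:00

_PHQ9_GROUP_BANDS = {"none": (0, 4), "mild": (5, 9), "major": (10, 27)}
_PHQ9_GROUP_NORMALS = {"none": (2.0, 1.5), "mild": (7.0, 1.2), "major": (14.0, 2.5)}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``prevalence_depressed`` is the fraction of participants with major
    depressive symptoms (survey scores > 9, class D days);
    ``prevalence_mild`` adds participants with mild symptoms (scores
    5-9) who belong to the ND univariate class but the positive
    machine-learning class, mirroring the two cutoffs used downstream.
    ``missingness`` is the per-stream probability that a whole
    participant-day of records is lost (a float applies to both the
    poll and call streams).
    """

    n_participants: int = 46
    study_days: int = 60
    survey_interval_days: int = 14
    poll_interval_min: int = 2
    prevalence_depressed: float = 0.12
    prevalence_mild: float = 0.28
    channel_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CHANNEL_PARAMS.items()}
    )
    mild_severity_shift: float = 0.5
    missingness: float | dict[str, float] = 0.3
    comm_correlation: float = 0.7
    start_date: dt.date = dt.date(2016, 1, 4)
    region_center: tuple[float, float] = (19.0, 74.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.study_days <= 0:
            raise ValueError("n_participants and study_days must be positive")
        if self.survey_interval_days <= 0 or self.poll_interval_min <= 0:
            raise ValueError("intervals must be positive")
        if MINUTES_PER_DAY % self.poll_interval_min != 0:
            raise ValueError("poll_interval_min must divide 1440 evenly")
        if self.study_days < self.survey_interval_days:
            raise ValueError("study_days must be at least survey_interval_days")
        for name, p in (
            ("prevalence_depressed", self.prevalence_depressed),
            ("prevalence_mild", self.prevalence_mild),
            ("comm_correlation", self.comm_correlation),
            ("mild_severity_shift", self.mild_severity_shift),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.prevalence_depressed + self.prevalence_mild > 1.0:
            raise ValueError("prevalence_depressed + prevalence_mild must not exceed 1")
        for stream, p in self.missingness_by_stream().items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness[{stream}] must lie in [0, 1]")
        for channel, per_class in self.channel_params.items():
            for cls, (mean, sd) in per_class.items():
                if mean < 0 or sd < 0:
                    raise ValueError(f"channel {channel}/{cls}: mean and SD must be >= 0")

    def missingness_by_stream(self) -> dict[str, float]:
        if isinstance(self.missingness, dict):
            out = {"polls": 0.0, "calls": 0.0}
            unknown = set(self.missingness) - set(out)
            if unknown:
                raise ValueError(f"unknown missingness streams: {sorted(unknown)}")
            out.update(self.missingness)
            return out
        return {"polls": float(self.missingness), "calls": float(self.missingness)}

    @property
    def polls_per_day(self) -> int:
        return MINUTES_PER_DAY // self.poll_interval_min


@dataclass
class ParticipantState:
    """Latent truth for one simulated participant."""

    participant_id: str
    group: str  # "none" | "mild" | "major"
    latent_phq9_trajectory: list[int] = field(default_factory=list)
    survey_days: list[int] = field(default_factory=list)
    class_per_day: list[str | None] = field(default_factory=list)  # "D"/"ND"/None


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Shape and scale of the gamma distribution with given moments."""
    if mean <= 0:
        return (0.0, 0.0)
    if sd <= 0:
        return (math.inf, 0.0)  # sentinel: degenerate at `mean`
    shape = (mean / sd) ** 2
    return (shape, sd * sd / mean)


def _draw_channel(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    shape, scale = _gamma_params(mean, sd)
    if shape == 0.0:
        return np.zeros(size)
    if not math.isfinite(shape):
        return np.full(size, mean)
    return rng.gamma(shape, scale, size=size)


def _gamma_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    shape, scale = _gamma_params(mean, sd)
    if shape == 0.0:
        return np.zeros_like(u)
    if not math.isfinite(shape):
        return np.full_like(u, mean)
    return stats.gamma.ppf(u, shape, scale=scale)


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integerize non-negative reals without bias: floor + Bernoulli(frac)."""
    lo = np.floor(x)
    return (lo + (rng.random(x.shape) < (x - lo))).astype(np.int64)


def simulate_phq9_trajectory(
    participant: ParticipantState, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Biweekly PHQ-9 surveys at day 0 and every interval thereafter.

    Scores are integers drawn within the participant group's severity
    band (none 0-4, mild 5-9, major 10-27), so the downstream
    between-survey averaging keeps each day in the same class as its
    participant.  Fills ``latent_phq9_trajectory``, ``survey_days`` and
    the imputation-rule-consistent ``class_per_day`` on the participant
    state, and returns the surveys as a data frame.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    days = list(range(0, config.study_days + 1, config.survey_interval_days))
    lo, hi = _PHQ9_GROUP_BANDS[participant.group]
    mu, sigma = _PHQ9_GROUP_NORMALS[participant.group]
    scores = np.clip(np.rint(rng.normal(mu, sigma, size=len(days))), lo, hi).astype(int)
    participant.survey_days = days
    participant.latent_phq9_trajectory = scores.tolist()
    classes: list[str | None] = []
    for d in range(config.study_days):
        if d > days[-1]:
            classes.append(None)  # beyond the last survey: unlabeled
            continue
        idx = np.searchsorted(days, d, side="right") - 1
        if days[idx] == d:
            score = float(scores[idx])
        else:
            score = (scores[idx] + scores[idx + 1]) / 2.0
        classes.append("D" if score > 9 else "ND")
    participant.class_per_day = classes
    dates = [config.start_date + dt.timedelta(days=d) for d in days]
    return pd.DataFrame(
        {
            "participant_id": participant.participant_id,
            "date": dates,
            "phq9_total": scores,
        }
    )


def _simulate_participant_day(
    rng: np.random.Generator,
    config: SimulationConfig,
    participant: ParticipantState,
    day: int,
    targets: dict[str, float],
    home: tuple[float, float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Realize one day's poll grid and call events from channel targets."""
    ppd = config.polls_per_day
    step = config.poll_interval_min
    base = dt.datetime.combine(config.start_date + dt.timedelta(days=day), dt.time())
    minutes = np.arange(ppd) * step

    # relative gravity: stationary noise inside the band, then carve out
    # active slots per window with values strictly outside the band
    rg = np.clip(rng.normal(1.0, 0.05, size=ppd), 0.805, 1.195)
    screen = np.zeros(ppd, dtype=bool)
    for wname, w in CANONICAL_WINDOWS.items():
        slots = np.flatnonzero((minutes >= w.start_min) & (minutes < w.end_min))
        k_active = min(int(targets[f"activity_{wname}"]), len(slots))
        if k_active:
            chosen = rng.choice(slots, size=k_active, replace=False)
            magnitude = np.abs(rng.normal(0.35, 0.25, size=k_active)) + 0.01
            above = rng.random(k_active) < 0.7
            rg[chosen] = np.where(above, 1.2 + magnitude, np.maximum(0.0, 0.8 - magnitude))
        k_screen = min(int(targets[f"screen_{wname}"]), len(slots))
        if k_screen:
            screen[rng.choice(slots, size=k_screen, replace=False)] = True

    # GPS: home point plus daytime excursions; ~3 m jitter per poll
    lat = np.full(ppd, home[0])
    lon = np.full(ppd, home[1])
    for _ in range(int(targets["excursions"])):
        dist = rng.uniform(300.0, 3000.0)
        bearing = rng.uniform(0.0, 2.0 * math.pi)
        dlat = dist * math.cos(bearing) / 111_320.0
        dlon = dist * math.sin(bearing) / (111_320.0 * math.cos(math.radians(home[0])))
        dur = rng.integers(20, 121)
        start = rng.integers(EXCURSION_HOURS[0], max(EXCURSION_HOURS[1] - dur, EXCURSION_HOURS[0] + 1))
        block = (minutes >= start) & (minutes < start + dur)
        lat[block] = home[0] + dlat
        lon[block] = home[1] + dlon
    jitter = 3.0 / 111_320.0
    lat = lat + rng.normal(0.0, jitter, size=ppd)
    lon = lon + rng.normal(0.0, jitter, size=ppd)

    polls = pd.DataFrame(
        {
            "participant_id": participant.participant_id,
            "timestamp": np.datetime64(base) + minutes.astype("timedelta64[m]"),
            "relative_gravity": np.round(rg, 4),
            "screen_on": screen.astype(int),
            "lat": np.round(lat, 6),
            "lon": np.round(lon, 6),
        }
    )

    # calls: targets already integerized and consistent (people <= calls)
    n_calls = int(targets["calls_total"])
    n_people = int(targets["people_called"])
    n_missed = int(targets["calls_missed"])
    records = []
    if n_calls:
        weights = rng.exponential(1.0, size=n_calls)
        durations = np.round(targets["call_duration"] * weights / weights.sum(), 2)
        contacts = np.concatenate(
            [np.arange(n_people), rng.integers(0, n_people, size=n_calls - n_people)]
        )
        rng.shuffle(contacts)
        directions = np.where(rng.random(n_calls) < 0.5, "made", "received")
        call_minutes = rng.integers(CALL_HOURS[0], CALL_HOURS[1], size=n_calls)
        for m, d, dur, c in zip(call_minutes, directions, durations, contacts):
            records.append((m, d, float(dur), c))
    for m in rng.integers(CALL_HOURS[0], CALL_HOURS[1], size=n_missed):
        records.append((int(m), "missed", 0.0, int(rng.integers(0, max(n_people, 1)))))
    records.sort(key=lambda r: r[0])
    calls = pd.DataFrame(
        {
            "participant_id": participant.participant_id,
            "timestamp": np.datetime64(base)
            + np.array([int(r[0]) for r in records], dtype="timedelta64[m]"),
            "direction": [r[1] for r in records],
            "duration_min": [r[2] for r in records],
            "contact_id": [f"{participant.participant_id}_c{int(r[3]):03d}" for r in records],
        }
    )
    return polls, calls


def _group_channel_params(config: SimulationConfig) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-group (major/mild/none) channel moments.

    Major-group days use the D parameters directly.  For channels with
    a D/ND contrast, mild-group days sit part-way along the contrast
    (dose-response; ``mild_severity_shift`` of the D-ND difference) and
    the none-group moments are solved so that the none+mild *mixture* —
    i.e. the ND univariate class — reproduces the configured ND mean
    and SD exactly.  Degenerate solutions (negative mean or variance)
    fall back to no shift for that channel.
    """
    alpha = config.mild_severity_shift
    p_mild, p_major = config.prevalence_mild, config.prevalence_depressed
    p_none = 1.0 - p_mild - p_major
    w = p_mild / (p_mild + p_none) if (p_mild + p_none) > 0 else 0.0
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for channel, per_class in config.channel_params.items():
        mean_d, sd_d = per_class["D"]
        mean_nd, sd_nd = per_class["ND"]
        mild = none = (mean_nd, sd_nd)
        if alpha > 0 and 0.0 < w < 1.0 and (mean_d, sd_d) != (mean_nd, sd_nd):
            mean_mild = mean_nd + alpha * (mean_d - mean_nd)
            mean_none = (mean_nd - w * mean_mild) / (1.0 - w)
            var_within = sd_nd**2 - w * (1.0 - w) * (mean_mild - mean_none) ** 2
            if mean_none >= 0.0 and var_within > 0.0:
                sd_within = math.sqrt(var_within)
                mild = (mean_mild, sd_within)
                none = (mean_none, sd_within)
        out[channel] = {"major": (mean_d, sd_d), "mild": mild, "none": none}
    return out


def _daily_targets(
    rng: np.random.Generator,
    params: dict[str, tuple[float, float]],
    comm_correlation: float,
    n_days: int,
) -> dict[str, np.ndarray]:
    """Draw all channel targets for ``n_days`` days of one group."""
    out: dict[str, np.ndarray] = {}
    # correlated communication trio via a Gaussian copula
    rho = comm_correlation
    z_shared = rng.normal(size=n_days)
    for channel in _COMM_CHANNELS:
        z = math.sqrt(rho) * z_shared + math.sqrt(1.0 - rho) * rng.normal(size=n_days)
        u = stats.norm.cdf(z)
        mean, sd = params[channel]
        out[channel] = _gamma_ppf(u, mean, sd)
    for channel, (mean, sd) in params.items():
        if channel in _COMM_CHANNELS:
            continue
        out[channel] = _draw_channel(rng, mean, sd, n_days)
    # integerize count channels without bias
    for channel in out:
        if channel == "call_duration":
            continue
        out[channel] = _stochastic_round(out[channel], rng).astype(float)
    # consistency: a day with calls involves at least one contact, and
    # never fewer calls than distinct contacts
    calls, people = out["calls_total"], out["people_called"]
    people = np.where(calls + people > 0, np.maximum(people, 1), 0)
    calls = np.maximum(calls, people)
    out["calls_total"], out["people_called"] = calls, people
    out["call_duration"] = np.where(calls > 0, out["call_duration"], 0.0)
    return out


def simulate_cohort(
    config: SimulationConfig, return_truth: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame] | tuple:
    """Generate (polls, calls, surveys) streams for a synthetic cohort.

    Reproducible: identical config (including seed) gives identical
    streams.  With ``return_truth=True`` also returns the list of
    :class:`ParticipantState` with latent trajectories and classes.
    """
    root = np.random.SeedSequence(config.seed)
    ss_assign, ss_survey, ss_days, ss_miss = root.spawn(4)
    rng_assign = np.random.default_rng(ss_assign)
    rng_survey = np.random.default_rng(ss_survey)
    rng_days = np.random.default_rng(ss_days)

    n = config.n_participants
    u = rng_assign.random(n)
    groups = np.where(
        u < config.prevalence_depressed,
        "major",
        np.where(u < config.prevalence_depressed + config.prevalence_mild, "mild", "none"),
    )
    participants = [
        ParticipantState(participant_id=f"P{i + 1:03d}", group=groups[i]) for i in range(n)
    ]

    group_params = _group_channel_params(config)
    all_polls, all_calls, all_surveys = [], [], []
    for p in participants:
        all_surveys.append(simulate_phq9_trajectory(p, config, rng_survey))
        home = (
            config.region_center[0] + rng_days.uniform(-0.05, 0.05),
            config.region_center[1] + rng_days.uniform(-0.05, 0.05),
        )
        params = {ch: per_group[p.group] for ch, per_group in group_params.items()}
        drawn = _daily_targets(rng_days, params, config.comm_correlation, config.study_days)
        for day in range(config.study_days):
            targets = {k: float(v[day]) for k, v in drawn.items()}
            polls, calls = _simulate_participant_day(rng_days, config, p, day, targets, home)
            all_polls.append(polls)
            if len(calls):
                all_calls.append(calls)

    polls = pd.concat(all_polls, ignore_index=True)
    calls = (
        pd.concat(all_calls, ignore_index=True)
        if all_calls
        else pd.DataFrame(
            columns=["participant_id", "timestamp", "direction", "duration_min", "contact_id"]
        )
    )
    surveys = pd.concat(all_surveys, ignore_index=True)

    miss = config.missingness_by_stream()
    miss_seeds = ss_miss.generate_state(2)
    polls = inject_missingness(polls, miss["polls"], int(miss_seeds[0]))
    calls = inject_missingness(calls, miss["calls"], int(miss_seeds[1]))
    logger.info(
        "simulated cohort: %d participants, %d days, %d polls, %d call events, %d surveys",
        n, config.study_days, len(polls), len(calls), len(surveys),
    )
    if return_truth:
        return polls, calls, surveys, participants
    return polls, calls, surveys


def inject_missingness(stream: pd.DataFrame, daily_dropout: float, seed: int) -> pd.DataFrame:
    """Drop whole (participant, day) units independently with the given probability.

    Surviving records are returned unmodified (original order kept).
    Whole-day loss models the dominant real failure modes — phones left
    at home, devices powered down, capture errors — rather than
    poll-level gaps.
    """
    if not 0.0 <= daily_dropout <= 1.0:
        raise ValueError("daily_dropout must lie in [0, 1]")
    if daily_dropout == 0.0 or len(stream) == 0:
        return stream.copy()
    rng = np.random.default_rng(seed)
    dates = pd.to_datetime(stream["timestamp"]).dt.date
    units = pd.MultiIndex.from_arrays([stream["participant_id"], dates])
    unique_units = sorted(set(units))
    dropped = {u for u in unique_units if rng.random() < daily_dropout}
    keep = ~units.isin(dropped)
    return stream.loc[keep].copy()
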