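"""Delimited-text interchange, structured configuration and pipeline orchestration.

All interchange is CSV with a header row; an empty cell means missing.
Writes are atomic (temporary file in the destination directory, then
rename), so an aborted run never leaves a truncated output behind.
Every stage logs its input/output instance counts; ``run_pipeline``
collects them into a machine-readable count ledger.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from daysense import classify, labeling, simulate, univariate
from daysense.features import extract_features
from daysense.registry import DEFAULT_REGISTRY

logger = logging.getLogger(__name__)


@dataclass
class StreamSchema:
    """Column names, dtypes and which columns hold timestamps/dates."""

    name: str
    columns: dict[str, str]  # column -> pandas dtype ("datetime" parsed)
    required: tuple[str, ...]

    @property
    def datetime_columns(self) -> list[str]:
        return [c for c, t in self.columns.items() if t == "datetime"]


POLLS_SCHEMA = StreamSchema(
    "polls",
    columns={
        "participant_id": "string",
        "timestamp": "datetime",
        "relative_gravity": "float64",
        "screen_on": "float64",
        "lat": "float64",
        "lon": "float64",
    },
    required=("participant_id", "timestamp", "relative_gravity", "screen_on"),
)

CALLS_SCHEMA = StreamSchema(
    "calls",
    columns={
        "participant_id": "string",
        "timestamp": "datetime",
        "direction": "string",
        "duration_min": "float64",
        "contact_id": "string",
    },
    required=("participant_id", "timestamp", "direction", "duration_min", "contact_id"),
)

SURVEYS_SCHEMA = StreamSchema(
    "surveys",
    columns={"participant_id": "string", "date": "datetime", "phq9_total": "float64"},
    required=("participant_id", "date", "phq9_total"),
)


def read_stream(path, schema: StreamSchema, on_error: str = "skip") -> pd.DataFrame:
    """Read and validate a delimited stream file.

    Rows that fail type coercion (unparseable timestamps or numbers,
    missing required fields) are reported with their line numbers and
    either skipped (``on_error='skip'``) or abort the read
    (``on_error='abort'``).
    """
    if on_error not in ("skip", "abort"):
        raise ValueError("on_error must be 'skip' or 'abort'")
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} for {schema.name}")
    bad = np.zeros(len(df), dtype=bool)
    out = pd.DataFrame(index=df.index)
    for col, dtype in schema.columns.items():
        if col not in df.columns:
            out[col] = np.nan
            continue
        raw = df[col].mask(df[col] == "")
        if dtype == "datetime":
            coerced = pd.to_datetime(raw, errors="coerce", format="ISO8601")
            bad |= coerced.isna().to_numpy() & (col in schema.required)
        elif dtype == "float64":
            coerced = pd.to_numeric(raw, errors="coerce")
            bad |= coerced.isna().to_numpy() & raw.notna().to_numpy()
            if col in schema.required:
                bad |= raw.isna().to_numpy()
        else:
            coerced = raw
            if col in schema.required:
                bad |= raw.isna().to_numpy()
        out[col] = coerced
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()  # +2: header and 1-based
        message = f"{path}: {int(bad.sum())} malformed row(s) at line(s) {lines[:20]}"
        if on_error == "abort":
            raise ValueError(message)
        logger.warning("%s -- skipped", message)
        out = out.loc[~bad]
    logger.info("read %d %s records from %s", len(out), schema.name, path)
    return out.reset_index(drop=True)


def atomic_write_csv(df: pd.DataFrame, path) -> None:
    """Write a CSV via a temporary file and rename (atomic on POSIX)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as handle:
            df.to_csv(handle, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            json.dump(obj, handle, indent=2, sort_keys=True)
            handle.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_streams(polls: pd.DataFrame, calls: pd.DataFrame, surveys: pd.DataFrame, out_dir) -> None:
    """Write the three raw stream files with ISO-8601 timestamps."""
    out_dir = Path(out_dir)
    polls = polls.copy()
    polls["timestamp"] = pd.to_datetime(polls["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    calls = calls.copy()
    if len(calls):
        calls["timestamp"] = pd.to_datetime(calls["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    surveys = surveys.copy()
    surveys["date"] = pd.to_datetime(surveys["date"]).dt.strftime("%Y-%m-%d")
    atomic_write_csv(polls, out_dir / "polls.csv")
    atomic_write_csv(calls, out_dir / "calls.csv")
    atomic_write_csv(surveys, out_dir / "surveys.csv")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; unknown keys are rejected on load."""

    out_dir: str = "daysense_output"
    seed: int = 0
    simulate: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    polls_path: str | None = None  # used when simulate=False
    calls_path: str | None = None
    surveys_path: str | None = None
    registry: list[str] = field(default_factory=lambda: list(DEFAULT_REGISTRY))
    univariate_cutoff: float = 9.0
    ml_cutoff: float = 5.0
    remove_outliers: bool = False
    alternative: str = "two-sided"
    test_fraction: float = 0.10
    cv_folds: int = 10
    methods: list[str] = field(default_factory=lambda: list(classify.ALL_METHODS))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**raw)

    def __post_init__(self) -> None:
        if self.univariate_cutoff < self.ml_cutoff:
            logger.warning("univariate cutoff below ML cutoff breaks class nesting")
        if self.alternative not in univariate.ALTERNATIVES:
            raise ValueError(f"alternative must be one of {univariate.ALTERNATIVES}")


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate (optional) -> extract -> label -> univariate -> classify.

    Writes every stage's output under ``config.out_dir`` and returns
    the machine-readable count ledger (also written as counts.json).
    """
    out_dir = Path(config.out_dir)
    ledger: dict[str, int | float] = {"seed": config.seed}
    if config.simulate:
        sim = simulate.SimulationConfig(seed=config.seed, **config.simulation)
        polls, calls, surveys = simulate.simulate_cohort(sim)
        write_streams(polls, calls, surveys, out_dir)
    else:
        if not (config.polls_path and config.calls_path and config.surveys_path):
            raise ValueError("simulate=False requires polls_path, calls_path and surveys_path")
        polls = read_stream(config.polls_path, POLLS_SCHEMA)
        calls = read_stream(config.calls_path, CALLS_SCHEMA)
        surveys = read_stream(config.surveys_path, SURVEYS_SCHEMA)
    ledger["polls"] = len(polls)
    ledger["call_events"] = len(calls)
    ledger["surveys"] = len(surveys)

    features = extract_features(polls, calls, registry=config.registry)
    atomic_write_csv(features, out_dir / "features.csv")
    ledger["participant_days"] = len(features)

    surveys_n = surveys.copy()
    surveys_n["date"] = pd.to_datetime(surveys_n["date"])
    labeled = labeling.label_cohort(
        features, surveys_n,
        univariate_cutoff=config.univariate_cutoff, ml_cutoff=config.ml_cutoff,
    )
    atomic_write_csv(labeled, out_dir / "labeled.csv")
    ledger["labeled_instances"] = len(labeled)
    ledger["instances_class_D"] = int((labeled["univariate_class"] == "D").sum())
    ledger["instances_class_D_ML"] = int((labeled["ml_class"] == "D-ML").sum())

    stats_table = univariate.run_univariate(
        labeled, variables=config.registry,
        remove_outliers=config.remove_outliers, alternative=config.alternative,
    )
    atomic_write_csv(stats_table, out_dir / "univariate.csv")

    reports = classify.run_classification(
        labeled, registry=config.registry, seed=config.seed,
        methods=config.methods, k=config.cv_folds, test_fraction=config.test_fraction,
    )
    atomic_write_json({m: r.to_dict() for m, r in reports.items()}, out_dir / "report.json")
    atomic_write_csv(classify.report_table(reports), out_dir / "report_table.csv")
    X, y = classify.assemble_dataset(labeled, config.registry)
    n_test = int(round(len(X) * config.test_fraction))
    ledger["complete_cases"] = len(X)
    ledger["training_instances"] = len(X) - n_test
    ledger["test_instances"] = n_test
    atomic_write_json(ledger, out_dir / "counts.json")
    logger.info("pipeline complete: %s", ledger)
    return ledger
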