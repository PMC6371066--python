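"""Attach imputed PHQ-9 scores and depression class labels to participant-days.

Scores are surveyed once every two weeks; every day strictly between
two consecutive surveys receives the *average* of the two totals, a day
falling on a survey date receives that survey's total, and days outside
the surveyed range stay unlabeled (an optional nearest-survey carry is
provided but off by default).  Two cutoffs are applied without
rounding: univariate class D at PHQ-9 > 9 (major symptoms) and the
broader machine-learning class D-ML at PHQ-9 >= 5 (mild to severe), so
D always nests inside D-ML.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNIVARIATE_CUTOFF = 9.0  # class D: score strictly greater
ML_CUTOFF = 5.0  # class D-ML: score greater or equal


def impute_daily_phq9(surveys: pd.DataFrame, date, allow_carry: bool = False) -> float:
    """Imputed PHQ-9 score for one participant on one date.

    ``surveys`` holds one participant's records with columns
    ``date`` and ``phq9_total``.  Raises on duplicate survey dates.
    Returns NaN for a date outside the surveyed range unless
    ``allow_carry`` extends the nearest survey's score outward.
    """
    if len(surveys) == 0:
        return np.nan
    sdates = pd.to_datetime(surveys["date"]).to_numpy(dtype="datetime64[D]")
    order = np.argsort(sdates)
    sdates = sdates[order]
    totals = surveys["phq9_total"].to_numpy(dtype=float)[order]
    if len(np.unique(sdates)) != len(sdates):
        raise ValueError("duplicate PHQ-9 survey on a single date")
    d = np.datetime64(pd.Timestamp(date).date(), "D")
    idx = np.searchsorted(sdates, d, side="right") - 1
    if idx >= 0 and sdates[idx] == d:
        return float(totals[idx])
    if idx < 0 or idx >= len(sdates) - 1:
        if allow_carry:
            return float(totals[0] if idx < 0 else totals[-1])
        return np.nan
    return float((totals[idx] + totals[idx + 1]) / 2.0)


def assign_classes(
    imputed_phq9: float,
    univariate_cutoff: float = UNIVARIATE_CUTOFF,
    ml_cutoff: float = ML_CUTOFF,
) -> tuple[str | float, str | float]:
    """(univariate_class, ml_class) for an imputed score.

    Thresholds are applied exactly and without rounding: strictly
    greater than the univariate cutoff gives D, greater-or-equal to the
    ML cutoff gives D-ML.  A missing score yields missing labels
    (instance excluded from both analyses).
    """
    if imputed_phq9 is None or (isinstance(imputed_phq9, float) and math.isnan(imputed_phq9)):
        return (np.nan, np.nan)
    if not 0.0 <= imputed_phq9 <= 27.0:
        raise ValueError(f"PHQ-9 score out of range [0, 27]: {imputed_phq9}")
    univariate = "D" if imputed_phq9 > univariate_cutoff else "ND"
    ml = "D-ML" if imputed_phq9 >= ml_cutoff else "ND-ML"
    return (univariate, ml)


def label_cohort(
    features: pd.DataFrame,
    surveys: pd.DataFrame,
    allow_carry: bool = False,
    univariate_cutoff: float = UNIVARIATE_CUTOFF,
    ml_cutoff: float = ML_CUTOFF,
) -> pd.DataFrame:
    """One labeled instance per feature vector with a non-missing imputed score.

    Returns the feature table augmented with ``imputed_phq9``,
    ``univariate_class`` and ``ml_class``, restricted to labeled days.
    Participants present in the features but absent from the surveys
    are dropped with a warning.
    """
    duplicated = features.duplicated(subset=["participant_id", "date"])
    if duplicated.any():
        raise ValueError(
            f"duplicate participant-day feature rows: "
            f"{features.loc[duplicated, ['participant_id', 'date']].values[:5].tolist()}"
        )
    survey_groups = {pid: g for pid, g in surveys.groupby("participant_id")}
    missing_participants = sorted(set(features["participant_id"]) - set(survey_groups))
    if missing_participants:
        logger.warning(
            "dropping %d participants with feature days but no surveys: %s",
            len(missing_participants), missing_participants,
        )
    scores = np.full(len(features), np.nan)
    for i, (pid, date) in enumerate(zip(features["participant_id"], features["date"])):
        g = survey_groups.get(pid)
        if g is not None:
            scores[i] = impute_daily_phq9(g, date, allow_carry=allow_carry)
    labeled = features.copy()
    labeled["imputed_phq9"] = scores
    classes = [assign_classes(s, univariate_cutoff, ml_cutoff) for s in scores]
    labeled["univariate_class"] = [c[0] for c in classes]
    labeled["ml_class"] = [c[1] for c in classes]
    labeled = labeled[~np.isnan(scores)].reset_index(drop=True)
    logger.info(
        "labeled %d of %d participant-day instances (%d D, %d D-ML)",
        len(labeled), len(features),
        int((labeled["univariate_class"] == "D").sum()),
        int((labeled["ml_class"] == "D-ML").sum()),
    )
    return labeled
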