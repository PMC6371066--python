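"""Unequal-variance group comparison of derived sensing variables.

Participant-day instances are split into depression classes D (imputed
PHQ-9 > 9) and ND per variable, and compared with the Welch t-test:

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)

with Welch-Satterthwaite degrees of freedom.  Group sizes differ by
variable because missing values are never imputed — an instance simply
drops out of the comparison for the variables it lacks.  An optional
Tukey 1.5*IQR fence removes outliers per variable per class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass
class WelchResult:
    """One variable's two-sample unequal-variance comparison."""

    variable: str
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    t: float
    df: float
    p: float
    alternative: str = "two-sided"
    outliers_removed: bool = False
    testable: bool = True


def welch_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    alternative: str = "two-sided",
    variable: str = "",
) -> WelchResult:
    """Welch t-test from group summary statistics (means, SDs, sizes).

    Enables consistency checks against published summary tables without
    raw data.  ``alternative='less'``/``'greater'`` refer to group 1's
    mean relative to group 2's.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1 = sd1 * sd1 / n1
    v2 = sd2 * sd2 / n2
    se = np.sqrt(v1 + v2)
    if se == 0.0:
        t = 0.0 if mean1 == mean2 else np.inf * np.sign(mean1 - mean2)
        df = n1 + n2 - 2.0
    else:
        t = (mean1 - mean2) / se
        df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    return WelchResult(
        variable=variable,
        n1=int(n1), mean1=float(mean1), sd1=float(sd1),
        n2=int(n2), mean2=float(mean2), sd2=float(sd2),
        t=float(t), df=float(df), p=float(min(max(p, 0.0), 1.0)),
        alternative=alternative,
    )


def welch_t_test(x1, x2, alternative: str = "two-sided", variable: str = "") -> WelchResult:
    """Welch t-test on two raw samples (NaNs dropped).

    Identical to :func:`welch_from_summary` applied to the samples'
    means, sample SDs (ddof=1) and sizes.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 non-missing values")
    return welch_from_summary(
        a.mean(), a.std(ddof=1), len(a),
        b.mean(), b.std(ddof=1), len(b),
        alternative=alternative, variable=variable,
    )


def tukey_filter(values) -> np.ndarray:
    """Keep values within the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Applied per variable per class before the "without outliers"
    analysis.  Samples smaller than 4, or samples the fences would
    shrink below 2 values, are returned unchanged with a warning.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 4:
        warnings.warn("tukey_filter: fewer than 4 values, sample returned unchanged")
        return v
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    kept = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    if len(kept) < 2:
        warnings.warn("tukey_filter: fences would leave fewer than 2 values, sample returned unchanged")
        return v
    return kept


def run_univariate(
    instances: pd.DataFrame,
    variables=None,
    remove_outliers: bool = False,
    alternative: str = "two-sided",
    adjust: str | None = None,
    class_column: str = "univariate_class",
) -> pd.DataFrame:
    """Per-variable Welch comparison of D vs ND participant-day instances.

    Returns one row per requested variable with the group summaries
    actually used (group sizes differ by variable because missingness
    is never imputed).  ``adjust`` optionally appends multiplicity-
    adjusted p-values ('bonferroni' or 'fdr_bh'); none is applied by
    default.  Variables with fewer than 2 values in either class are
    flagged untestable rather than dropped.
    """
    if variables is None:
        reserved = {"participant_id", "date", "imputed_phq9", "univariate_class", "ml_class"}
        variables = [c for c in instances.columns if c not in reserved]
    is_d = instances[class_column] == "D"
    rows = []
    for var in variables:
        x1 = instances.loc[is_d, var].to_numpy(dtype=float)
        x2 = instances.loc[~is_d, var].to_numpy(dtype=float)
        x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
        if remove_outliers:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                x1, x2 = tukey_filter(x1), tukey_filter(x2)
        try:
            res = welch_t_test(x1, x2, alternative=alternative, variable=var)
            res.outliers_removed = remove_outliers
        except ValueError:
            res = WelchResult(
                variable=var,
                n1=len(x1), mean1=float(x1.mean()) if len(x1) else np.nan,
                sd1=float(x1.std(ddof=1)) if len(x1) > 1 else np.nan,
                n2=len(x2), mean2=float(x2.mean()) if len(x2) else np.nan,
                sd2=float(x2.std(ddof=1)) if len(x2) > 1 else np.nan,
                t=np.nan, df=np.nan, p=np.nan,
                alternative=alternative, outliers_removed=remove_outliers,
                testable=False,
            )
        rows.append(res)
    table = pd.DataFrame([r.__dict__ for r in rows])
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        mask = table["p"].notna()
        adjusted = np.full(len(table), np.nan)
        if mask.any():
            adjusted[mask.to_numpy()] = multipletests(table.loc[mask, "p"], method=adjust)[1]
        table["p_adjusted"] = adjusted
    logger.info(
        "univariate comparison of %d variables (%s outliers)",
        len(table), "without" if remove_outliers else "with",
    )
    return table
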