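"""Age-acceleration statistics and clock accuracy summaries.

Two complementary error measures are used throughout:

* ``AA_diff`` — predicted minus actual age. Direct and interpretable, but
  sensitive to the mean age of a cohort and to preprocessing choices: a
  cohort normalized differently can be shifted up or down wholesale.
* ``AA_resid`` — the residual of an ordinary least-squares regression of
  predicted age on actual age, computed within each evaluation group
  (held-out cohort). By construction it has mean zero and zero correlation
  with actual age inside the group, so it is insensitive to the cohort's
  mean age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: significance threshold used throughout the package
P_SIGNIFICANT = 0.005


def compute_aa(
    predicted: Sequence[float],
    actual: Sequence[float],
    group_ids: Sequence | None = None,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample age-acceleration table.

    ``aa_diff`` is predicted - actual; ``aa_resid`` the within-group OLS
    residual of predicted on actual (NaN for groups with fewer than 3
    samples, where the regression is meaningless).
    """
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.shape != act.shape:
        raise ValueError("predicted and actual age vectors differ in length")
    n = len(pred)
    groups = np.asarray(group_ids if group_ids is not None else ["all"] * n)
    if len(groups) != n:
        raise ValueError("group_ids length mismatch")
    ids = list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(n)]

    aa_resid = np.full(n, np.nan)
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 3:
            continue
        x, y = act[idx], pred[idx]
        if np.ptp(x) == 0:  # degenerate regression: intercept-only
            aa_resid[idx] = y - y.mean()
            continue
        slope, intercept = np.polyfit(x, y, 1)
        aa_resid[idx] = y - (intercept + slope * x)

    return pd.DataFrame({
        "sample_id": ids,
        "group": groups,
        "predicted_age": pred,
        "actual_age": act,
        "aa_diff": pred - act,
        "aa_resid": aa_resid,
    })


def summarize_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group accuracy summary.

    Columns: ``group``, ``n``, ``r`` (Pearson correlation of predicted vs
    actual age; NaN when the group's age is invariant or n < 4),
    ``median_abs_aa_diff``, ``mean_aa_diff``, ``median_abs_aa_resid``.
    """
    rows = []
    for g, sub in table.groupby("group", sort=False):
        act = sub["actual_age"].to_numpy()
        pred = sub["predicted_age"].to_numpy()
        n = len(sub)
        if n >= 4 and np.ptp(act) > 0 and np.ptp(pred) > 0:
            r = float(stats.pearsonr(pred, act).statistic)
        else:
            r = np.nan  # "not computed": age-invariant or too small a group
        rows.append({
            "group": g,
            "n": n,
            "r": r,
            "median_abs_aa_diff": float(np.median(np.abs(sub["aa_diff"]))),
            "mean_aa_diff": float(np.mean(sub["aa_diff"])),
            "median_abs_aa_resid": float(np.nanmedian(np.abs(sub["aa_resid"])))
            if sub["aa_resid"].notna().any() else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass
class ClockComparison:
    mean_difference: float
    t: float
    p: float
    significant: bool


def compare_clocks(abs_aa_clock1, abs_aa_clock2) -> ClockComparison:
    """Paired two-sided t-test on absolute age accelerations of two clocks
    evaluated on the same samples. Significance at p < 0.005."""
    a = np.asarray(abs_aa_clock1, dtype=float)
    b = np.asarray(abs_aa_clock2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired samples")
    d = a - b
    if np.all(d == 0):
        return ClockComparison(0.0, 0.0, 1.0, False)
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    p = float(res.pvalue)
    return ClockComparison(float(d.mean()), float(res.statistic), p, p < P_SIGNIFICANT)
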