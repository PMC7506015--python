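"""Germline age differential (GLAD) and group comparisons.

GLAD expresses epigenetic age acceleration as a ratio:

    GLAD = predicted_age / actual_age - 1

A positive GLAD means the sperm methylome looks older than the man's
chronological age. Within each age category, GLAD is compared between
the high-BMI and normal-BMI sub-categories by Welch's two-tailed t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["compute_glad", "compare_glad"]


def compute_glad(predictions: pd.DataFrame) -> pd.DataFrame:
    """Append a ``glad`` column to a (id, actual_age, predicted_age) table."""
    required = {"id", "actual_age", "predicted_age"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"predictions table lacks columns: {sorted(missing)}")
    actual = predictions["actual_age"].to_numpy(dtype=float)
    if np.any(~np.isfinite(actual)) or np.any(actual <= 0):
        raise ValueError("actual age must be finite and > 0 for every sample")
    out = predictions.copy()
    out["glad"] = out["predicted_age"].to_numpy(dtype=float) / actual - 1.0
    return out


def _welch(x: np.ndarray, y: np.ndarray):
    if np.allclose(x.var(ddof=1) + y.var(ddof=1), 0.0) and np.isclose(x.mean(), y.mean()):
        return 0.0, 1.0
    stat, p = stats.ttest_ind(x, y, equal_var=False)
    return float(stat), float(p)


def compare_glad(
    glad: pd.DataFrame,
    cohort: pd.DataFrame,
    within: str = "age_category",
    compare: str = "bmi_category",
    high_label: str = "high",
    bonferroni: bool = False,
):
    """Per-age-category GLAD comparison between BMI sub-categories.

    Returns ``(summary, tests, long)``:

    - summary: per (age, BMI) cell — n, mean GLAD, SE;
    - tests: per age category — mean difference (high − normal), Welch
      t statistic and two-tailed p (optionally Bonferroni-adjusted over
      the age categories);
    - long: one row per sample with category labels, ready for boxplots.
    """
    labels = cohort.set_index("id")[[within, compare]]
    long = glad.merge(labels, left_on="id", right_index=True, how="left")
    if long[within].isna().any() or long[compare].isna().any():
        missing = long.loc[long[within].isna() | long[compare].isna(), "id"].tolist()
        raise ValueError(f"samples without category labels: {missing}")

    summary = (
        long.groupby([within, compare], sort=False)["glad"]
        .agg(n="size", mean_glad="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    if (summary["n"] == 0).any():
        raise ValueError("empty cohort cell")

    rows = []
    for stratum, sub in long.groupby(within, sort=False):
        grp = {k: v["glad"].to_numpy(dtype=float) for k, v in sub.groupby(compare, sort=False)}
        if len(grp) != 2:
            raise ValueError(f"age category {stratum!r} does not have exactly 2 BMI groups")
        other = next(k for k in grp if k != high_label)
        if high_label not in grp:
            raise ValueError(f"no {high_label!r} BMI group in age category {stratum!r}")
        stat, p = _welch(grp[high_label], grp[other])
        rows.append(
            {
                within: stratum,
                "mean_diff": grp[high_label].mean() - grp[other].mean(),
                "stat": stat,
                "p": p,
            }
        )
    tests = pd.DataFrame(rows)
    if bonferroni:
        tests["p_bonf"] = np.minimum(1.0, tests["p"] * len(tests))
    return summary, tests, long
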