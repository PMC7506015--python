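"""Three-level differential methylation screen with Bonferroni control.

Methylation differences between two groups of samples are tested at
three resolutions: every CpG individually (point), region averages
(regional), and the array-wide mean per sample (global). Each unit is
compared with Welch's two-sample t-test on M-values and corrected within
its level's family by Bonferroni; a unit is called significant when the
adjusted p falls below alpha (default 0.05).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import RegionMap
from .preprocess import aggregate_regions

__all__ = [
    "point_tests",
    "regional_tests",
    "global_test",
    "bonferroni",
    "three_level_screen",
]

_COLUMNS = ["unit_id", "level", "mean_g1", "mean_g2", "diff", "stat", "p_raw", "p_bonf", "significant"]


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m).

    ``m`` defaults to the number of tests supplied; it may be larger when
    the family extends beyond the units passed in.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, p * m)


def _check_groups(matrix: pd.DataFrame, group1, group2):
    g1, g2 = list(group1), list(group2)
    overlap = set(g1) & set(g2)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = [s for s in g1 + g2 if s not in matrix.columns]
    if missing:
        raise KeyError(f"samples absent from matrix: {missing}")
    return g1, g2


def _welch_table(matrix: pd.DataFrame, g1, g2, level: str, alpha: float, family_m: int | None):
    """Vectorized per-row Welch t-tests; pairwise-complete per unit."""
    a = matrix[g1].to_numpy(dtype=float)
    b = matrix[g2].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    testable = (n1 >= 2) & (n2 >= 2)

    mean1 = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=1)
    mean2 = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=1)
    diff = mean2 - mean1

    with np.errstate(invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate case: both groups constant and equal -> no evidence of effect
    zero_var = np.isnan(stat) & np.isclose(diff, 0.0)
    stat = np.where(zero_var, 0.0, stat)
    p = np.where(zero_var, 1.0, p)

    out = pd.DataFrame(
        {
            "unit_id": matrix.index,
            "level": level,
            "mean_g1": mean1,
            "mean_g2": mean2,
            "diff": diff,
            "stat": -stat,  # scipy computes g1-g2; report in g2-g1 orientation

            "p_raw": p,
            "p_bonf": np.nan,
            "significant": False,
        }
    )
    out.loc[~testable, ["stat", "p_raw"]] = np.nan
    tested = out["p_raw"].notna()
    m = family_m if family_m is not None else int(tested.sum())
    if tested.any():
        out.loc[tested, "p_bonf"] = bonferroni(out.loc[tested, "p_raw"].to_numpy(), m=m)
        out.loc[tested, "significant"] = out.loc[tested, "p_bonf"] < alpha
    return out[_COLUMNS].reset_index(drop=True)


def point_tests(m: pd.DataFrame, group1, group2, alpha: float = 0.05, family_m: int | None = None) -> pd.DataFrame:
    """Welch t-test per CpG on M-values; Bonferroni over all tested CpGs."""
    g1, g2 = _check_groups(m, group1, group2)
    return _welch_table(m, g1, g2, "point", alpha, family_m)


def regional_tests(
    region_m: pd.DataFrame, group1, group2, alpha: float = 0.05, family_m: int | None = None
) -> pd.DataFrame:
    """Welch t-test per region mean; Bonferroni over regions."""
    g1, g2 = _check_groups(region_m, group1, group2)
    return _welch_table(region_m, g1, g2, "regional", alpha, family_m)


def global_test(m: pd.DataFrame, group1, group2, alpha: float = 0.05) -> pd.DataFrame:
    """One test on the per-sample array-wide mean M (family size 1)."""
    g1, g2 = _check_groups(m, group1, group2)
    global_means = m.mean(axis=0, skipna=True)
    row = pd.DataFrame([global_means], index=pd.Index(["global"], name="unit_id"))
    return _welch_table(row, g1, g2, "global", alpha, family_m=1)


def three_level_screen(
    m: pd.DataFrame,
    region_map: RegionMap,
    pheno: pd.DataFrame,
    within: str = "age_category",
    compare: str = "bmi_category",
    alpha: float = 0.05,
):
    """Run point/regional/global comparisons within every stratum.

    For each level of ``within`` (age category), the two levels of
    ``compare`` (BMI sub-category) are tested against each other at all
    three resolutions; the Bonferroni family is all tests of one level
    within one stratum. Returns ``(results, summary)`` where results is
    the concatenated table with a stratum column and summary counts
    significant units per stratum and level.
    """
    region_m = aggregate_regions(m, region_map)
    frames = []
    summary = []
    for stratum, sub in pheno.groupby(within, sort=False):
        groups = {k: list(v["id"]) for k, v in sub.groupby(compare, sort=False)}
        if len(groups) != 2:
            raise ValueError(f"stratum {stratum!r}: expected exactly 2 comparison groups, got {len(groups)}")
        (label1, g1), (label2, g2) = sorted(groups.items())
        for frame in (
            point_tests(m, g1, g2, alpha=alpha),
            regional_tests(region_m, g1, g2, alpha=alpha),
            global_test(m, g1, g2, alpha=alpha),
        ):
            frame.insert(0, within, stratum)
            frame.insert(1, "group1", label1)
            frame.insert(2, "group2", label2)
            frames.append(frame)
            summary.append(
                {
                    within: stratum,
                    "level": frame["level"].iloc[0],
                    "n_tests": int(frame["p_raw"].notna().sum()),
                    "n_significant": int(frame["significant"].sum()),
                }
            )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(summary)
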