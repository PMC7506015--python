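"""Accuracy metrics and the with-BMI vs without-BMI model comparison.

Each clock is scored by the r² of the simple linear regression of
predicted on actual age and by the mean absolute error (MAE, years).
Because two scalar r² values cannot be t-tested directly, the models are
compared by a paired two-tailed t-test on the per-sample absolute
prediction errors — the operational reading of comparing predictive
power on the same samples; the scalar metrics are reported side by side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["r_squared", "mae", "compare_models", "ComparisonReport"]


def _aligned(actual, predicted):
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    return a, p


def r_squared(actual, predicted) -> float:
    """Squared Pearson correlation of actual vs predicted age."""
    a, p = _aligned(actual, predicted)
    if a.size < 3:
        raise ValueError("need at least 3 samples for r^2")
    if np.allclose(a, a[0]) or np.allclose(p, p[0]):
        raise ValueError("r^2 undefined for a constant vector")
    r = np.corrcoef(a, p)[0, 1]
    return float(r * r)


def mae(actual, predicted) -> float:
    """Mean absolute error in years."""
    a, p = _aligned(actual, predicted)
    if a.size < 1:
        raise ValueError("need at least one sample")
    return float(np.mean(np.abs(p - a)))


@dataclass
class ComparisonReport:
    """Side-by-side metrics for two clocks plus the paired error test."""

    labels: tuple
    r_squared: dict
    mae: dict
    test_statistic: float
    p_value: float
    n: int
    winner_by_mae: str
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "models": {
                label: {"r_squared": self.r_squared[label], "mae": self.mae[label]}
                for label in self.labels
            },
            "paired_test": {
                "kind": "paired two-tailed t-test on per-sample absolute errors",
                "statistic": self.test_statistic,
                "p_value": self.p_value,
                "n": self.n,
            },
            "winner_by_mae": self.winner_by_mae,
            "config": self.config,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def compare_models(
    pred_a: pd.DataFrame,
    pred_b: pd.DataFrame,
    labels: tuple = ("without_bmi", "with_bmi"),
    config: dict | None = None,
) -> ComparisonReport:
    """Compare two prediction tables over the same samples.

    Each table needs columns (id, actual_age, predicted_age). The sample
    sets must match exactly; rows are aligned by id. If both models make
    identical predictions the paired test degenerates to no evidence of
    a difference (statistic 0, p = 1).
    """
    a = pred_a.set_index("id")
    b = pred_b.set_index("id")
    if set(a.index) != set(b.index):
        raise ValueError("prediction tables cover different sample sets")
    b = b.reindex(a.index)
    actual = a["actual_age"].to_numpy(dtype=float)
    if not np.allclose(actual, b["actual_age"].to_numpy(dtype=float), equal_nan=True):
        raise ValueError("actual ages disagree between the two tables")

    err_a = np.abs(a["predicted_age"].to_numpy(dtype=float) - actual)
    err_b = np.abs(b["predicted_age"].to_numpy(dtype=float) - actual)
    if np.allclose(err_a, err_b):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_rel(err_a, err_b)
        stat, p = float(stat), float(p)

    r2 = {labels[0]: r_squared(actual, a["predicted_age"]), labels[1]: r_squared(actual, b["predicted_age"])}
    maes = {labels[0]: mae(actual, a["predicted_age"]), labels[1]: mae(actual, b["predicted_age"])}
    winner = labels[0] if maes[labels[0]] <= maes[labels[1]] else labels[1]
    return ComparisonReport(
        labels=tuple(labels),
        r_squared=r2,
        mae=maes,
        test_statistic=stat,
        p_value=p,
        n=len(actual),
        winner_by_mae=winner,
        config=config or {},
    )
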