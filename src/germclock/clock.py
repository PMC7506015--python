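"""Elastic-net germ-line age clock fit by cyclic coordinate descent.

The clock is a penalized linear regression of chronological age on
region-level methylation features (optionally plus BMI), minimizing

    (1/2n) * ||y - X b||^2 + lam * ( alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 )

over standardized features and centered ages. ``alpha`` mixes the lasso
and ridge penalties, ``lam`` sets the overall strength; ``lam`` is
chosen by k-fold cross-validation along a log-spaced path with warm
starts, exactly the pathwise strategy of the classical glmnet solver.

The solver and CV machinery are self-contained; predictions use the
standardization parameters stored at training time, so a serialized
model is portable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "fit_elastic_net",
    "elastic_net_objective",
    "lambda_max",
    "lambda_path",
    "cv_select_lambda",
    "ClockModel",
    "train_clock",
    "predict_age",
    "clock_features",
]

MODEL_FORMAT_VERSION = 1


class ConvergenceWarning(UserWarning):
    pass


def _cd_sweeps(X, r, beta, col_sq, g, denom, tol, max_sweeps, n):
    """Cyclic coordinate-descent sweeps; mutates ``r`` and ``beta``.

    Returns (n_sweeps, last_max_delta). Compiled with numba when
    available — the clock's region features are strongly correlated, so
    small penalties need many sweeps.
    """
    max_delta = 0.0
    for sweep in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(X.shape[1]):
            bj = beta[j]
            z = 0.0
            for i in range(X.shape[0]):
                z += X[i, j] * r[i]
            z = z / n + col_sq[j] * bj
            if z > g:
                bj_new = (z - g) / denom[j]
            elif z < -g:
                bj_new = (z + g) / denom[j]
            else:
                bj_new = 0.0
            if bj_new != bj:
                d = bj - bj_new
                for i in range(X.shape[0]):
                    r[i] += X[i, j] * d
                beta[j] = bj_new
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if max_delta < tol:
            return sweep, max_delta
    return max_sweeps, max_delta


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _cd_sweeps = njit(cache=True)(_cd_sweeps)
except ImportError:  # pragma: no cover
    pass


def elastic_net_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, alpha: float, lam: float) -> float:
    """Value of the penalized least-squares objective (y assumed centered)."""
    n = X.shape[0]
    r = y - X @ beta
    return float(
        0.5 / n * r @ r + lam * (alpha * np.abs(beta).sum() + 0.5 * (1.0 - alpha) * beta @ beta)
    )


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    lam: float = 0.0,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
    beta_init: np.ndarray | None = None,
):
    """Cyclic coordinate descent for the elastic net.

    ``X`` must be standardized (columns mean 0, population SD 1) and
    ``y`` is centered internally. Each coordinate update is

        b_j <- S(z_j, lam*alpha) / (c_j + lam*(1-alpha)),
        z_j = (1/n) sum_i x_ij * (r_i + x_ij b_j),  c_j = (1/n) sum_i x_ij^2

    with S the soft-threshold operator; for standardized columns c_j = 1.
    Converges when the largest coefficient change in a sweep drops below
    ``tol`` scaled by the SD of the centered response — a relative
    criterion, so the fit is exactly equivariant under rescaling of y.
    Returns ``(coef, intercept, n_sweeps)`` with intercept = mean(y).

    Raises on non-finite input; warns if ``max_sweeps`` is exhausted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")

    intercept = float(y.mean())
    yc = y - intercept
    beta = np.zeros(p) if beta_init is None else np.array(beta_init, dtype=float)
    X = np.ascontiguousarray(X)
    r = yc - X @ beta
    col_sq = (X * X).sum(axis=0) / n  # = 1 for standardized columns
    g = lam * alpha
    denom = col_sq + lam * (1.0 - alpha)
    y_scale = float(yc.std())
    eff_tol = tol * (y_scale if y_scale > 0 else 1.0)

    sweeps, max_delta = _cd_sweeps(X, r, beta, col_sq, g, denom, eff_tol, max_sweeps, float(n))
    if sweeps >= max_sweeps and max_delta >= tol:
        warnings.warn(
            f"coordinate descent did not converge in {max_sweeps} sweeps "
            f"(last max coefficient change {max_delta:.3e})",
            ConvergenceWarning,
        )
    return beta, intercept, sweeps


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty at which every coefficient is zero.

    For alpha below 0.001 the lasso threshold diverges; the conventional
    floor of 0.001 is applied (as in glmnet).
    """
    n = X.shape[0]
    yc = y - y.mean()
    z = np.abs(X.T @ yc) / n
    return float(z.max() / max(alpha, 1e-3))


def lambda_path(lam_max: float, n_lambda: int = 100, ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced penalty grid from lam_max down to lam_max * ratio."""
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD, so columns satisfy (1/n) sum x^2 = 1
    if np.any(sd == 0):
        raise ValueError("constant feature cannot be standardized")
    return (X - mean) / sd, mean, sd


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    k_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    rule: str = "min",
    tol: float = 1e-7,
):
    """k-fold cross-validated penalty selection along the lambda path.

    Standardization is redone inside every training fold so no test-fold
    information leaks into the fit. Returns ``(lam, curve)`` where curve
    is a DataFrame (lam, cv_mse, cv_se, n_nonzero). ``rule`` is "min"
    (CV-minimum, default) or "1se" (largest lam within one SE of the
    minimum).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > n:
        raise ValueError("more folds than samples")
    if lambda_grid is None:
        Xs, _, _ = _standardize(X)
        yn = (y - y.mean()) / y.std()
        lambda_grid = lambda_path(lambda_max(Xs, yn, alpha))
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    order = np.argsort(lambda_grid)[::-1]  # descending, for warm starts
    grid = lambda_grid[order]

    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(k_folds), int(np.ceil(n / k_folds)))[:n]
    fold_of = fold_of[rng.permutation(n)]

    sq_err = np.zeros((grid.size, n))
    for k in range(k_folds):
        test = fold_of == k
        Xtr, ytr = X[~test], y[~test]
        Xs, mean, sd = _standardize(Xtr)
        # response standardized within the training fold (as in glmnet),
        # so the penalty is dimensionless and no test-fold data leaks in
        y_mean, y_sd = ytr.mean(), ytr.std()
        if y_sd == 0:
            y_sd = 1.0
        yn = (ytr - y_mean) / y_sd
        beta = np.zeros(X.shape[1])
        Xte_s = (X[test] - mean) / sd
        for gi, lam in enumerate(grid):
            beta, _, _ = fit_elastic_net(Xs, yn, alpha=alpha, lam=lam, tol=tol, beta_init=beta)
            pred = y_mean + (Xte_s @ beta) * y_sd
            sq_err[gi, test] = (y[test] - pred) ** 2

    cv_mse = sq_err.mean(axis=1)
    # SE of the CV estimate from fold-level means
    fold_mse = np.vstack([sq_err[:, fold_of == k].mean(axis=1) for k in range(k_folds)]).T
    cv_se = fold_mse.std(axis=1, ddof=1) / np.sqrt(k_folds)

    i_min = int(np.argmin(cv_mse))
    if rule == "min":
        chosen = grid[i_min]
    elif rule == "1se":
        within = np.where(cv_mse <= cv_mse[i_min] + cv_se[i_min])[0]
        chosen = grid[within.min()]  # grid is descending: smallest index = largest lam
    else:
        raise ValueError(f"unknown selection rule {rule!r}")

    # refit along the path once on all data to report sparsity
    Xs, _, _ = _standardize(X)
    y_sd = y.std() or 1.0
    yn = (y - y.mean()) / y_sd
    nnz = []
    beta = np.zeros(X.shape[1])
    for lam in grid:
        beta, _, _ = fit_elastic_net(Xs, yn, alpha=alpha, lam=lam, tol=tol, beta_init=beta)
        # numerically-active count: at lam = lambda_max the entering
        # coefficient sits exactly on the soft threshold and roundoff can
        # leave an O(1e-17) residue
        nnz.append(int(np.sum(np.abs(beta) > 1e-12)))
    curve = pd.DataFrame({"lam": grid, "cv_mse": cv_mse, "cv_se": cv_se, "n_nonzero": nnz})
    return float(chosen), curve


@dataclass
class ClockModel:
    """A fitted germ-line age clock, portable via JSON.

    Coefficients are on the standardized-feature scale; stored feature
    means/SDs reproduce the training standardization at predict time.
    """

    feature_names: list
    coef: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    alpha: float
    lam: float
    includes_bmi: bool
    metadata: dict = field(default_factory=dict)
    version: int = MODEL_FORMAT_VERSION

    def to_json(self, path=None) -> str:
        payload = {
            "format_version": self.version,
            "feature_names": list(self.feature_names),
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "feature_means": [float(v) for v in self.feature_means],
            "feature_sds": [float(v) for v in self.feature_sds],
            "alpha": float(self.alpha),
            "lambda": float(self.lam),
            "includes_bmi": bool(self.includes_bmi),
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ClockModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            feature_names=list(payload["feature_names"]),
            coef=np.array(payload["coef"], dtype=float),
            intercept=float(payload["intercept"]),
            feature_means=np.array(payload["feature_means"], dtype=float),
            feature_sds=np.array(payload["feature_sds"], dtype=float),
            alpha=float(payload["alpha"]),
            lam=float(payload["lambda"]),
            includes_bmi=bool(payload["includes_bmi"]),
            metadata=dict(payload.get("metadata", {})),
            version=int(payload.get("format_version", MODEL_FORMAT_VERSION)),
        )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def clock_features(
    region_matrix: pd.DataFrame,
    clock_regions: list,
    cohort: pd.DataFrame | None = None,
    include_bmi: bool = False,
) -> pd.DataFrame:
    """Build the samples x features table for the clock.

    Features are the clock regions' methylation means (rows of
    ``region_matrix``, transposed) plus, optionally, a BMI column taken
    from the cohort table.
    """
    missing = [r for r in clock_regions if r not in region_matrix.index]
    if missing:
        raise KeyError(f"clock regions absent from the region matrix: {missing}")
    feats = region_matrix.loc[clock_regions].T.copy()
    feats.index.name = "id"
    if include_bmi:
        if cohort is None or "bmi" not in cohort.columns:
            raise ValueError("BMI feature requested but no cohort BMI column available")
        bmi = cohort.set_index("id")["bmi"]
        feats["bmi"] = bmi.reindex(feats.index)
        if feats["bmi"].isna().any():
            raise ValueError("BMI missing for some samples")
    return feats


def train_clock(
    features: pd.DataFrame,
    ages,
    include_bmi: bool = False,
    alpha: float = 0.5,
    k_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    lam: float | None = None,
    seed: int = 0,
    tol: float = 1e-7,
) -> ClockModel:
    """Standardize features, pick lambda by CV, and fit the final model.

    ``features`` is samples x features; a "bmi" column is kept or
    dropped according to ``include_bmi``. Passing ``lam`` explicitly
    skips cross-validation (useful for simulation studies and tests).

    As in glmnet, the response is standardized internally before the
    penalized fit and the coefficients are rescaled back to years, so
    ``lam`` is dimensionless and the whole procedure is exactly
    equivariant under rescaling of the ages.
    """
    feats = features.copy()
    if include_bmi and "bmi" not in feats.columns:
        raise ValueError("include_bmi=True but features have no 'bmi' column")
    if not include_bmi and "bmi" in feats.columns:
        feats = feats.drop(columns=["bmi"])
    y = np.asarray(ages, dtype=float)
    if len(y) != feats.shape[0]:
        raise ValueError("ages not aligned to feature rows")
    X = feats.to_numpy(dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in features or ages")

    cv_curve = None
    if lam is None:
        lam, cv_curve = cv_select_lambda(
            X, y, alpha=alpha, k_folds=k_folds, lambda_grid=lambda_grid, seed=seed, tol=tol
        )
    Xs, mean, sd = _standardize(X)
    y_sd = y.std() or 1.0
    yn = (y - y.mean()) / y_sd
    coef_n, _, sweeps = fit_elastic_net(Xs, yn, alpha=alpha, lam=lam, tol=tol)
    coef = coef_n * y_sd
    intercept = float(y.mean())
    metadata = {
        "seed": int(seed),
        "k_folds": int(k_folds),
        "n_lambda": int(len(cv_curve)) if cv_curve is not None else 0,
        "cv_used": cv_curve is not None,
        "n_training_samples": int(X.shape[0]),
        "sweeps": int(sweeps),
    }
    return ClockModel(
        feature_names=list(feats.columns),
        coef=coef,
        intercept=intercept,
        feature_means=mean,
        feature_sds=sd,
        alpha=alpha,
        lam=float(lam),
        includes_bmi=include_bmi,
        metadata=metadata,
    )


def predict_age(model: ClockModel, features: pd.DataFrame, ages=None) -> pd.DataFrame:
    """Predict age for every sample in the feature table.

    Feature columns must match the model's features exactly (order is
    reconciled internally). Returns a DataFrame ``(id, actual_age,
    predicted_age)``; actual_age is NaN when ages are not supplied.
    """
    have = set(features.columns)
    want = set(model.feature_names)
    if have != want:
        extra, missing = sorted(have - want), sorted(want - have)
        raise ValueError(f"feature mismatch: missing {missing}, unexpected {extra}")
    X = features[model.feature_names].to_numpy(dtype=float)
    Xs = (X - model.feature_means) / model.feature_sds
    pred = model.intercept + Xs @ model.coef
    out = pd.DataFrame({"id": features.index, "predicted_age": pred})
    if ages is not None:
        out.insert(1, "actual_age", np.asarray(ages, dtype=float))
    else:
        out.insert(1, "actual_age", np.nan)
    return out.reset_index(drop=True)
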