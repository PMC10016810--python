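"""Ridge prediction of motor recovery with nested leave-one-out CV.

The outer loop leaves one patient out.  Inside each fold: features are
standardized on the training patients only (population SD); for the
connectivity-augmented feature sets the most collinear feature is
iteratively dropped by variance inflation factor (VIF) until a threshold
is met, with the clinical benchmark features protected; the ridge penalty
is chosen by an inner leave-one-out grid search on the training patients;
the fitted weights then predict the held-out patient.  Accuracy is the
coefficient of determination with the denominator centred on the mean of
the *predictions*:

    R^2 = 1 - sum (Y - Y')^2 / sum (Y - mean(Y'))^2

(the conventional observed-mean denominator is available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTable

__all__ = [
    "RidgeModel",
    "PredictionResult",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_VIF_THRESHOLD",
    "DEFAULT_PROTECTED",
    "standardize_fold",
    "vif",
    "vif_select",
    "ridge_fit",
    "ridge_predict",
    "inner_lambda_search",
    "loo_predict",
    "r_squared",
    "vif_sweep",
]

#: logarithmic ridge-penalty grid searched in the inner loop
DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 25)

#: default VIF threshold of the pipeline (a config value, never selected
#: from the outer accuracy curve)
DEFAULT_VIF_THRESHOLD = 23.0

#: features never eliminated by the VIF step
DEFAULT_PROTECTED = ("age", "initial_fma", "cst_asymmetry")


@dataclass(frozen=True)
class RidgeModel:
    beta: np.ndarray
    lam: float
    y_mean: float
    feature_names: tuple

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("coefficients must be finite")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class PredictionResult:
    ids: list
    y: np.ndarray
    y_pred: np.ndarray
    r2: float
    fold_features: list
    fold_weights: list  # dict feature -> weight per fold
    fold_lambda: list
    selection_count: dict
    weight_mean: dict
    weight_sd: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"observed": self.y, "predicted": self.y_pred}, index=self.ids
        )


# ---------------------------------------------------------------------------


def standardize_fold(
    train_X: pd.DataFrame, test_X: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Z-score on training statistics only (population SD, divisor n).

    Zero-variance training columns are removed from both frames and listed
    in the returned stats under ``"dropped"``.
    """
    if len(train_X) < 2:
        raise ValueError("need >= 2 training rows")
    mean = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=0)
    dropped = list(sd.index[sd == 0])
    if len(dropped) == len(train_X.columns):
        raise ValueError("all feature columns are constant in the training fold")
    if dropped:
        warnings.warn(f"dropping constant training columns: {dropped}", stacklevel=2)
    keep = [c for c in train_X.columns if c not in dropped]
    train_Z = (train_X[keep] - mean[keep]) / sd[keep]
    test_Z = (test_X[keep] - mean[keep]) / sd[keep]
    stats = {"mean": mean[keep], "sd": sd[keep], "dropped": dropped}
    return train_Z, test_Z, stats


def vif(Z: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per feature: ``1 / (1 - R^2_j)`` from an
    OLS regression (with intercept) of feature j on all others.

    With as many or more features than rows the auxiliary regressions are
    ridge-stabilized (penalty 1e-8) and perfectly collinear features still
    report +inf.  A single feature has VIF 1 by convention.
    """
    cols = list(Z.columns)
    n, p = Z.shape
    if p == 1:
        return pd.Series([1.0], index=cols)
    X = Z.to_numpy(dtype=float)
    out = {}
    for j, cj in enumerate(cols):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        if n > A.shape[1]:
            coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        else:
            coef = np.linalg.solve(A.T @ A + 1e-8 * np.eye(A.shape[1]), A.T @ yj)
        resid = yj - A @ coef
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[cj] = np.inf
            continue
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        out[cj] = np.inf if r2 >= 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_select(
    Z: pd.DataFrame,
    threshold: float,
    protected: tuple = DEFAULT_PROTECTED,
) -> list:
    """Iteratively drop the most collinear non-protected feature.

    Repeats until all VIFs are at or below ``threshold``; ties at the
    maximum are broken by reverse column order (later-added connectivity
    columns go first).  If only protected features remain while VIFs still
    exceed the threshold, the protected set is returned with a warning.
    Returned names keep the original column order.
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    cols = list(Z.columns)
    current = cols[:]
    while True:
        v = vif(Z[current])
        if np.nanmax(v.to_numpy()) <= threshold:
            break
        eligible = [c for c in current if c not in protected]
        if not eligible:
            warnings.warn(
                "VIF threshold unreachable with only protected features left",
                stacklevel=2,
            )
            break
        vmax = max(v[c] for c in eligible)
        tied = [c for c in eligible if v[c] == vmax or (np.isinf(v[c]) and np.isinf(vmax))]
        # reverse column order: remove the latest-added tied column
        drop = max(tied, key=lambda c: current.index(c))
        current.remove(drop)
    return [c for c in cols if c in current]


def ridge_fit(Z: pd.DataFrame, y: np.ndarray, lam: float) -> RidgeModel:
    """Solve ``(Z'Z + N*lam*I) beta = Z'y`` with y centred on its mean.

    This is the stationarity condition of ``(1/N)||y - Z beta||^2 +
    lam ||beta||^2``; the intercept is handled by target centring.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = Z.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = X.shape
    y_mean = float(yv.mean())
    yc = yv - y_mean
    A = X.T @ X + n * lam * np.eye(p)
    try:
        beta = np.linalg.solve(A, X.T @ yc)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular ridge system (collinear features at lambda=0); "
            "use a nonzero lambda"
        ) from exc
    if lam == 0 and not np.all(np.isfinite(beta)):
        raise np.linalg.LinAlgError(
            "non-finite OLS solution for collinear features; use nonzero lambda"
        )
    return RidgeModel(
        beta=beta, lam=float(lam), y_mean=y_mean, feature_names=tuple(Z.columns)
    )


def ridge_predict(model: RidgeModel, Z_test: pd.DataFrame) -> np.ndarray:
    X = Z_test[list(model.feature_names)].to_numpy(dtype=float)
    return model.y_mean + X @ model.beta


def inner_lambda_search(
    train_Z: pd.DataFrame,
    train_y: np.ndarray,
    grid=DEFAULT_LAMBDA_GRID,
) -> float:
    """Leave-one-out grid search for the ridge penalty on the training fold.

    For every grid value the mean squared LOO prediction error over the
    training patients is computed by honest refits; ties go to the
    smallest penalty.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    X = train_Z.to_numpy(dtype=float)
    yv = np.asarray(train_y, dtype=float)
    n, p = X.shape
    order = np.argsort(grid, kind="stable")
    best_lam, best_err = None, np.inf
    for lam in grid[order]:
        errs = np.empty(n)
        ok = True
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            Xi, yi = X[mask], yv[mask]
            ym = yi.mean()
            A = Xi.T @ Xi + (n - 1) * lam * np.eye(p)
            try:
                beta = np.linalg.solve(A, Xi.T @ (yi - ym))
            except np.linalg.LinAlgError:
                ok = False
                break
            errs[i] = (yv[i] - (ym + X[i] @ beta)) ** 2
        if not ok:
            continue
        err = float(errs.mean())
        if err < best_err - 1e-15:
            best_err, best_lam = err, float(lam)
    if best_lam is None:
        raise np.linalg.LinAlgError("no lambda on the grid yielded a solvable system")
    return best_lam


def r_squared(Y, Yprime, convention: str = "prediction-mean") -> float:
    """Coefficient of determination.

    Default denominator is centred on the mean of the predictions
    (``sum (Y - mean(Y'))^2``); ``convention="observed-mean"`` gives the
    standard definition.
    """
    y = np.asarray(Y, dtype=float)
    yp = np.asarray(Yprime, dtype=float)
    if y.shape != yp.shape or y.size < 2:
        raise ValueError("Y and Y' must have equal length >= 2")
    centre = yp.mean() if convention == "prediction-mean" else y.mean()
    denom = float(((y - centre) ** 2).sum())
    if denom == 0:
        raise ZeroDivisionError("zero denominator in R^2")
    return 1.0 - float(((y - yp) ** 2).sum()) / denom


def loo_predict(
    ft: FeatureTable,
    vif_threshold: float | None = None,
    grid=DEFAULT_LAMBDA_GRID,
    protected: tuple = DEFAULT_PROTECTED,
) -> PredictionResult:
    """Leave-one-subject-out prediction over the cohort.

    ``vif_threshold=None`` disables the selection step (feature sets
    without the connectivity battery); otherwise standardization, VIF
    selection and the inner penalty search all see only the training fold.
    """
    X, y = ft.X, ft.y.to_numpy(dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 patients")
    ids = list(X.index)
    y_pred = np.empty(n)
    fold_features, fold_weights, fold_lambda = [], [], []
    for i in range(n):
        train_idx = [k for k in range(n) if k != i]
        y_tr = y[train_idx]
        if np.std(y_tr) == 0:
            raise ValueError(f"zero-variance target in fold {i}")
        train_Z, test_Z, _ = standardize_fold(
            X.iloc[train_idx], X.iloc[[i]]
        )
        if vif_threshold is not None:
            kept = vif_select(train_Z, vif_threshold, protected)
        else:
            kept = list(train_Z.columns)
        train_Z = train_Z[kept]
        test_Z = test_Z[kept]
        lam = inner_lambda_search(train_Z, y_tr, grid)
        model = ridge_fit(train_Z, y_tr, lam)
        y_pred[i] = ridge_predict(model, test_Z)[0]
        fold_features.append(kept)
        fold_weights.append(dict(zip(kept, model.beta.tolist())))
        fold_lambda.append(lam)
    all_feats = list(X.columns)
    selection_count = {
        f: sum(f in ff for ff in fold_features) for f in all_feats
    }
    weight_mean, weight_sd = {}, {}
    for f in all_feats:
        w = np.array([fw[f] for fw in fold_weights if f in fw])
        weight_mean[f] = float(w.mean()) if len(w) else np.nan
        weight_sd[f] = float(w.std(ddof=0)) if len(w) else np.nan
    return PredictionResult(
        ids=ids,
        y=y,
        y_pred=y_pred,
        r2=r_squared(y, y_pred),
        fold_features=fold_features,
        fold_weights=fold_weights,
        fold_lambda=fold_lambda,
        selection_count=selection_count,
        weight_mean=weight_mean,
        weight_sd=weight_sd,
    )


def vif_sweep(
    ft: FeatureTable,
    thresholds=range(5, 201),
    grid=DEFAULT_LAMBDA_GRID,
    protected: tuple = DEFAULT_PROTECTED,
) -> pd.DataFrame:
    """Outer accuracy curve over VIF thresholds (diagnostic only: the
    pipeline's operating threshold is a configuration value, not the
    argmax of this curve)."""
    rows = []
    for t in thresholds:
        res = loo_predict(ft, vif_threshold=float(t), grid=grid, protected=protected)
        n_feat = float(np.mean([len(ff) for ff in res.fold_features]))
        rows.append({"threshold": float(t), "r2": res.r2, "n_features": n_feat})
    return pd.DataFrame(rows)
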