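"""Fitter/non-fitter labelling, classification metrics and cohort statistics.

"Fitters" are patients whose recovery follows the ~70% proportional
recovery rule; operationally a patient is a fitter when the FMA recovery
score exceeds 30% (strictly).  A clustering-based labelling of the same
split — agglomerative clustering of patients in the plane of expected
(0.7 * initial impairment) versus actually recovered FMA points — is
provided as the cross-check; on well separated cohorts the two labelings
coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr

__all__ = [
    "ClassificationResult",
    "BootstrapCI",
    "FITTER_THRESHOLD",
    "label_fitters_threshold",
    "label_fitters_clustering",
    "classification_metrics",
    "bootstrap_r2_ci",
    "spearman_bonferroni",
    "wilcoxon_ranksum",
    "feature_dendrogram",
]

#: recovery-score cutoff separating fitters (>) from non-fitters (<=)
FITTER_THRESHOLD = 30.0

#: proportional-recovery fraction of initial impairment
PROPORTIONAL_FRACTION = 0.7

#: largest pooled sample for which the rank-sum p-value is computed by
#: exact enumeration of group assignments
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class ClassificationResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class BootstrapCI:
    point_r2: float
    lower: float
    upper: float
    n_draws: int
    subsample_size: int
    seed: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower > upper")


def label_fitters_threshold(recovery_scores) -> np.ndarray:
    """Fitter (True) iff recovery score strictly exceeds 30%."""
    scores = np.asarray(recovery_scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("recovery scores must be finite")
    return scores > FITTER_THRESHOLD


def label_fitters_clustering(
    expected_recovery_points, actual_recovery_points
) -> np.ndarray:
    """Two-group split of patients in the (expected, actual) recovery plane.

    ``expected_i = 0.7 * (66 - FMA_2w_i)`` and ``actual_i = FMA_3m_i -
    FMA_2w_i``.  Patients are clustered agglomeratively (average linkage,
    Euclidean distance on jointly standardized coordinates) and cut at two
    clusters; the cluster with the higher mean actual/expected ratio is
    the fitter group.  Both axes are in FMA points, so standardization
    uses one common scale (the SD of all centred coordinates) — per-axis
    z-scoring would inflate whichever axis happens to vary least and
    destroy the group separation.  Degenerate input (all points identical)
    yields all non-fitters with a warning.
    """
    exp = np.asarray(expected_recovery_points, dtype=float)
    act = np.asarray(actual_recovery_points, dtype=float)
    if exp.shape != act.shape or exp.size < 4:
        raise ValueError("need >= 4 aligned patients")
    pts = np.column_stack([exp, act])
    centred = pts - pts.mean(axis=0)
    scale = centred.std(ddof=0)
    if scale == 0:
        warnings.warn("all patients identical; returning a single group", stacklevel=2)
        return np.zeros(len(exp), dtype=bool)
    z = centred / scale
    tree = linkage(z, method="average", metric="euclidean")
    labels = fcluster(tree, t=2, criterion="maxclust")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp > 0, act / exp, 0.0)
    means = [ratio[labels == g].mean() for g in (1, 2)]
    fitter_group = 1 + int(np.argmax(means))
    return labels == fitter_group


def classification_metrics(labels_true, labels_pred) -> ClassificationResult:
    """Confusion counts and derived metrics with fitter as the positive
    class; ratios with zero denominators are reported as None."""
    yt = np.asarray(labels_true, dtype=bool)
    yp = np.asarray(labels_pred, dtype=bool)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("labels must be nonempty and aligned")
    tp = int(np.sum(yt & yp))
    fp = int(np.sum(~yt & yp))
    tn = int(np.sum(~yt & ~yp))
    fn = int(np.sum(yt & ~yp))

    def ratio(a: int, b: int) -> float | None:
        return a / b if b > 0 else None

    return ClassificationResult(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


def bootstrap_r2_ci(
    Y,
    Yprime,
    n_draws: int = 10_000,
    subsample: int = 32,
    seed: int = 0,
    replace: bool = False,
) -> BootstrapCI:
    """Percentile CI for R^2 from repeated subsamples of the predictions.

    Each draw takes ``subsample`` patients without replacement (a
    with-replacement mode is available), computes the prediction-mean R^2,
    and the 2.5/97.5 percentiles of the resulting distribution form the
    interval.  Degenerate draws (zero denominator) are skipped.
    """
    from .prediction import r_squared

    y = np.asarray(Y, dtype=float)
    yp = np.asarray(Yprime, dtype=float)
    if subsample < 2:
        raise ValueError("subsample must be >= 2")
    if not replace and subsample > len(y):
        raise ValueError("subsample larger than the cohort")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_draws)
    vals.fill(np.nan)
    for d in range(n_draws):
        idx = rng.choice(len(y), size=subsample, replace=replace)
        try:
            vals[d] = r_squared(y[idx], yp[idx])
        except ZeroDivisionError:
            continue
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("all bootstrap draws degenerate")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapCI(
        point_r2=r_squared(y, yp),
        lower=float(lo),
        upper=float(hi),
        n_draws=n_draws,
        subsample_size=subsample,
        seed=seed,
    )


def spearman_bonferroni(
    features: pd.DataFrame, target, m_tests: int | None = None
) -> pd.DataFrame:
    """Spearman rho of each feature with the target, Bonferroni-corrected.

    Average ranks for ties, p from the t approximation; constant features
    report missing values.
    """
    y = np.asarray(target, dtype=float)
    if len(y) < 3:
        raise ValueError("need n >= 3")
    m = m_tests if m_tests is not None else features.shape[1]
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"feature": col, "rho": np.nan, "p_raw": np.nan, "p_adj": np.nan})
            continue
        rho, p = spearmanr(x, y)
        rows.append(
            {
                "feature": col,
                "rho": float(rho),
                "p_raw": float(p),
                "p_adj": min(1.0, m * float(p)),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def _ranks(pooled: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties."""
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _u_stat(ranks_b: np.ndarray, n_b: int) -> float:
    """Mann-Whitney U of group b from its pooled ranks."""
    return float(ranks_b.sum() - n_b * (n_b + 1) / 2.0)


def wilcoxon_ranksum(group_a, group_b) -> dict:
    """Rank-sum test between two groups.

    Returns the Mann-Whitney ``U`` of the second group (the count of
    pairs where b exceeds a, ties half-weighted), the tie-corrected
    standardized ``z`` and the two-sided ``p``.  For pooled samples of at
    most 12 observations the p-value comes from exact enumeration of all
    group assignments (tie-safe); larger samples use the normal
    approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    if n < 2:
        raise ValueError("need at least 2 observations")
    pooled = np.concatenate([a, b])
    ranks = _ranks(pooled)
    u = _u_stat(ranks[n_a:], n_b)
    mu = n_a * n_b / 2.0
    # tie-corrected variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = 0.0 if var == 0 else (u - mu) / sqrt(var)
    if n <= EXACT_RANKSUM_MAX_N:
        dev = abs(u - mu)
        hits = 0
        for idx_b in combinations(range(n), n_b):
            u_perm = _u_stat(ranks[list(idx_b)], n_b)
            if abs(u_perm - mu) >= dev - 1e-12:
                hits += 1
        p = hits / comb(n, n_b)
    else:
        p = 1.0 if var == 0 else 2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0))))
        p = min(1.0, p)
    return {"U": u, "z": float(z), "p": float(p)}


def feature_dendrogram(feature_matrix: pd.DataFrame):
    """Average-linkage tree on Spearman correlation distance between
    features (``1 - rho``); returns the linkage matrix and the two feature
    groups of the first (topmost) split.  Constant features are excluded
    with a warning.
    """
    if feature_matrix.shape[1] < 3:
        raise ValueError("need >= 3 features")
    keep = [c for c in feature_matrix.columns if feature_matrix[c].std() > 0]
    excluded = [c for c in feature_matrix.columns if c not in keep]
    if excluded:
        warnings.warn(f"excluding constant features: {excluded}", stacklevel=2)
    if len(keep) < 3:
        raise ValueError("fewer than 3 non-constant features")
    sub = feature_matrix[keep]
    rho = spearmanr(sub.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    iu = np.triu_indices(len(keep), 1)
    tree = linkage(dist[iu], method="average")
    two = fcluster(tree, t=2, criterion="maxclust")
    group1 = [c for c, g in zip(keep, two) if g == 1]
    group2 = [c for c, g in zip(keep, two) if g == 2]
    return tree, (group1, group2)
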