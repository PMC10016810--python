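"""Clinical/benchmark features and the five nested feature sets.

Feature sets follow the standard benchmark ladder for motor-recovery
prediction: (1) age + initial FMA, (2) + lesion volume, (3) + CST
asymmetry (the literature benchmark), (4) + the connectivity measure
battery, (5) like 4 but without CST asymmetry.  The prediction target is
either the FMA recovery score (percent of maximal possible improvement)
or the raw 3-month FMA outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_measures import MEASURE_NAMES
from .phantom import Cohort
from .virtual_lesion import LesionMask

__all__ = [
    "FeatureTable",
    "fma_recovery_score",
    "cst_asymmetry",
    "lesion_volume",
    "assemble_feature_set",
    "BENCHMARK_FEATURES",
]

#: benchmark feature column names, in assembly order
BENCHMARK_FEATURES = ["age", "initial_fma", "lesion_volume", "cst_asymmetry"]

#: FMA ceiling (upper-extremity items)
FMA_MAX = 66


@dataclass(frozen=True)
class FeatureTable:
    """Design matrix X, target y and bookkeeping for one feature set."""

    X: pd.DataFrame
    y: pd.Series
    target_kind: str = "recovery"
    set_id: int | None = None

    def __post_init__(self) -> None:
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("feature table must have no missing values")
        if len(set(self.X.columns)) != len(self.X.columns):
            raise ValueError("feature names must be unique")
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must be aligned on patient ids")

    @property
    def ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def fma_recovery_score(fma_2w: int, fma_3m: int) -> float:
    """Percentage of the maximal possible improvement that was achieved:
    ``100 * (FMA_3m - FMA_2w) / (66 - FMA_2w)``.  Negative if the score
    declined; undefined at a 2-week ceiling of 66."""
    if not 0 <= fma_2w <= FMA_MAX or not 0 <= fma_3m <= FMA_MAX:
        raise ValueError("FMA scores must be in [0, 66]")
    if fma_2w == FMA_MAX:
        raise ZeroDivisionError(
            "recovery score undefined for a 2-week FMA at ceiling (66)"
        )
    return 100.0 * (fma_3m - fma_2w) / (FMA_MAX - fma_2w)


def cst_asymmetry(fa_h: float, fa_l: float) -> float:
    """Stinear asymmetry index ``(FA_H - FA_L) / (FA_H + FA_L)`` between
    the healthy- and lesioned-hemisphere cortico-spinal tracts."""
    if fa_h < 0 or fa_l < 0:
        raise ValueError("FA values must be nonnegative")
    if fa_h + fa_l == 0:
        raise ZeroDivisionError("both FA values are zero")
    val = (fa_h - fa_l) / (fa_h + fa_l)
    if abs(val) == 1.0:
        import warnings

        warnings.warn("boundary asymmetry +/-1: one FA value is zero", stacklevel=2)
    return val


def lesion_volume(m: LesionMask, voxel_size=(1.0, 1.0, 1.0)) -> float:
    """Lesion volume = voxel count times voxel volume."""
    return len(m) * float(np.prod(voxel_size))


def assemble_feature_set(
    set_id: int,
    cohort: Cohort,
    measures: pd.DataFrame | None = None,
    target_kind: str = "recovery",
    voxel_size=(1.0, 1.0, 1.0),
) -> FeatureTable:
    """Build the design matrix for feature sets 1-5.

    ``measures`` (patients x measure names, indexed by patient id) is
    required for sets 4 and 5; connectivity columns enter in the canonical
    measure order so selection traces are reproducible.
    """
    if set_id not in (1, 2, 3, 4, 5):
        raise ValueError("set_id must be 1..5")
    if target_kind not in ("recovery", "outcome"):
        raise ValueError("target_kind must be 'recovery' or 'outcome'")
    ids = cohort.ids()
    rows = {}
    for p in cohort.patients:
        rows[p.id] = {
            "age": p.age,
            "initial_fma": float(p.fma_2w),
            "lesion_volume": lesion_volume(p.lesion, voxel_size),
            "cst_asymmetry": cst_asymmetry(p.fa_h, p.fa_l),
        }
    bench = pd.DataFrame.from_dict(rows, orient="index").loc[ids]
    cols = {
        1: ["age", "initial_fma"],
        2: ["age", "initial_fma", "lesion_volume"],
        3: BENCHMARK_FEATURES,
        4: BENCHMARK_FEATURES,
        5: ["age", "initial_fma", "lesion_volume"],
    }[set_id]
    X = bench[cols].copy()
    if set_id in (4, 5):
        if measures is None:
            raise ValueError(f"set {set_id} needs the connectivity measure table")
        missing = set(ids) - set(measures.index)
        if missing:
            raise ValueError(f"patients missing from measure table: {sorted(missing)}")
        X = pd.concat([X, measures.loc[ids, MEASURE_NAMES]], axis=1)
    if target_kind == "recovery":
        y = pd.Series(
            [fma_recovery_score(p.fma_2w, p.fma_3m) for p in cohort.patients],
            index=ids,
            name="recovery",
        )
    else:
        y = pd.Series(
            [float(p.fma_3m) for p in cohort.patients], index=ids, name="outcome"
        )
    return FeatureTable(X=X, y=y, target_kind=target_kind, set_id=set_id)
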