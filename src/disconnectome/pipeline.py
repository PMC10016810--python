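"""End-to-end orchestration: lesion -> virtual lesioning -> measures ->
feature sets -> LOO prediction -> evaluation.

The pipeline runs either in synthetic mode (phantom data generated from a
:class:`~disconnectome.phantom.PhantomConfig`) or external mode (NIfTI
parcellation and masks, TCK/JSON-lines tractograms, cohort CSV).  Every
random choice is routed through seeds derived from the configuration, so
a run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .evaluation import (
    FITTER_THRESHOLD,
    PROPORTIONAL_FRACTION,
    bootstrap_r2_ci,
    classification_metrics,
    label_fitters_clustering,
    label_fitters_threshold,
    spearman_bonferroni,
    wilcoxon_ranksum,
)
from .features import FMA_MAX, assemble_feature_set, fma_recovery_score
from .graph_measures import MEASURE_NAMES, connectome_measures, patient_measure_average
from .phantom import Cohort, PatientRecord, PhantomConfig, generate_cohort, generate_phantom
from .prediction import (
    DEFAULT_LAMBDA_GRID,
    DEFAULT_VIF_THRESHOLD,
    loo_predict,
    r_squared,
)
from .virtual_lesion import LesionMask, Parcellation, StreamlineCache, StreamlineSet

__all__ = ["PipelineConfig", "run_pipeline", "compute_measure_table", "make_fixtures"]

_SEED_MOD = 2**31 - 1


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    # external-mode paths
    parcellation_path: str | None = None
    streamline_paths: tuple = ()
    cohort_csv: str | None = None
    # analysis settings
    vif_threshold: float = DEFAULT_VIF_THRESHOLD
    lambda_grid: tuple = tuple(DEFAULT_LAMBDA_GRID)
    sets: tuple = (1, 2, 3, 4, 5)
    target_kind: str = "recovery"
    seed: int = 0
    bootstrap_draws: int = 10_000
    bootstrap_subsample: int = 32
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "external"):
            raise ValueError("mode must be 'synthetic' or 'external'")
        if self.mode == "external":
            for name in ("parcellation_path", "cohort_csv"):
                val = getattr(self, name)
                if val is None:
                    raise ValueError(f"external mode requires '{name}'")
                if not Path(val).exists():
                    raise FileNotFoundError(f"{name}: {val} does not exist")
            if not self.streamline_paths:
                raise ValueError("external mode requires 'streamline_paths'")
            for sp in self.streamline_paths:
                if not Path(sp).exists():
                    raise FileNotFoundError(f"streamline_paths entry {sp} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "phantom" in raw and isinstance(raw["phantom"], dict):
            ph = dict(raw["phantom"])
            if "grid_shape" in ph:
                ph["grid_shape"] = tuple(ph["grid_shape"])
            if "planted_betas" in ph:
                ph["planted_betas"] = tuple(ph["planted_betas"])
            raw["phantom"] = PhantomConfig(**ph)
        for key in ("lambda_grid", "sets", "streamline_paths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _measure_seed(base: int, patient_idx: int, subject_idx: int) -> int:
    return int((base + 100_003 * (patient_idx + 1) + subject_idx) % _SEED_MOD)


def compute_measure_table(
    cohort: Cohort,
    caches: list[StreamlineCache],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient connectivity measures, averaged over the virtually
    lesioned healthy connectomes (one row per patient)."""
    rows = {}
    for i, patient in enumerate(cohort.patients):
        per_conn = [
            connectome_measures(
                cache.connectome(patient.lesion),
                seed=_measure_seed(seed, i, s),
            )
            for s, cache in enumerate(caches)
        ]
        means, counts = patient_measure_average(per_conn)
        low = {k: v for k, v in counts.items() if v < len(caches)}
        if low:
            warnings.warn(
                f"patient {patient.id}: measures averaged over fewer "
                f"connectomes than available: {low}",
                stacklevel=2,
            )
        rows[patient.id] = means
    return pd.DataFrame.from_dict(rows, orient="index")[MEASURE_NAMES]


def _load_external(cfg: PipelineConfig) -> tuple[Parcellation, list[StreamlineSet], Cohort]:
    parc = dio.read_parcellation(cfg.parcellation_path)
    healthy = [
        dio.read_streamlines(p, grid_shape=parc.grid_shape)
        for p in cfg.streamline_paths
    ]
    df = pd.read_csv(cfg.cohort_csv)
    base = Path(cfg.cohort_csv).parent
    patients = []
    for _, row in df.iterrows():
        lesion = dio.read_lesion_mask(base / row["lesion_path"])
        patients.append(
            PatientRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                fma_2w=int(row["fma_2w"]),
                fma_3m=int(row["fma_3m"]),
                lesion=lesion,
                fa_h=float(row["fa_h"]),
                fa_l=float(row["fa_l"]),
            )
        )
    return parc, healthy, Cohort(patients=tuple(patients), provenance="external")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and return (and optionally write) the
    report bundle."""
    if cfg.mode == "synthetic":
        parc, healthy = generate_phantom(cfg.phantom)
        caches = [StreamlineCache.precompute(s, parc) for s in healthy]
        cohort = generate_cohort(cfg.phantom, parc, healthy, caches=caches)
    else:
        parc, healthy, cohort = _load_external(cfg)
        caches = [StreamlineCache.precompute(s, parc) for s in healthy]

    measures = compute_measure_table(cohort, caches, seed=cfg.seed)

    report: dict = {
        "config": {
            "mode": cfg.mode,
            "vif_threshold": cfg.vif_threshold,
            "target_kind": cfg.target_kind,
            "seed": cfg.seed,
            "sets": list(cfg.sets),
        },
        "n_patients": len(cohort),
        "n_healthy": len(caches),
        "sets": {},
    }
    if cfg.mode == "synthetic":
        report["config"]["phantom"] = dataclasses.asdict(cfg.phantom)

    recovery = np.array(
        [fma_recovery_score(p.fma_2w, p.fma_3m) for p in cohort.patients]
    )
    labels_true = label_fitters_threshold(recovery)
    expected = np.array(
        [PROPORTIONAL_FRACTION * (FMA_MAX - p.fma_2w) for p in cohort.patients]
    )
    actual = np.array([p.fma_3m - p.fma_2w for p in cohort.patients])
    labels_clust = label_fitters_clustering(expected, actual)
    report["fitters"] = {
        "n_fitters": int(labels_true.sum()),
        "n_non_fitters": int((~labels_true).sum()),
        "threshold_vs_clustering_agreement": float(
            (labels_true == labels_clust).mean()
        ),
    }

    ft4 = None
    results = {}
    for set_id in cfg.sets:
        ft = assemble_feature_set(
            set_id, cohort, measures=measures, target_kind=cfg.target_kind
        )
        if set_id == 4:
            ft4 = ft
        vif_thr = cfg.vif_threshold if set_id in (4, 5) else None
        res = loo_predict(ft, vif_threshold=vif_thr, grid=cfg.lambda_grid)
        results[set_id] = res
        subsample = min(cfg.bootstrap_subsample, len(cohort))
        ci = bootstrap_r2_ci(
            res.y,
            res.y_pred,
            n_draws=cfg.bootstrap_draws,
            subsample=subsample,
            seed=cfg.seed,
        )
        entry = {
            "r2": res.r2,
            "lambda_per_fold": res.fold_lambda,
            "selection_count": res.selection_count,
            "weight_mean": res.weight_mean,
            "weight_sd": res.weight_sd,
            "bootstrap_ci": [ci.lower, ci.upper],
        }
        if cfg.target_kind == "recovery":
            pred_labels = res.y_pred > FITTER_THRESHOLD
            cm = classification_metrics(labels_true, pred_labels)
            entry["classification"] = {
                "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
                "ppv": cm.ppv,
                "npv": cm.npv,
            }
        report["sets"][set_id] = entry

    # univariate statistics on the full (set-4 style) feature table
    if ft4 is None:
        ft4 = assemble_feature_set(4, cohort, measures=measures, target_kind="recovery")
    spear = spearman_bonferroni(ft4.X, recovery, m_tests=ft4.X.shape[1])
    report["spearman"] = {
        f: {"rho": r.rho, "p_raw": r.p_raw, "p_adj": r.p_adj}
        for f, r in spear.iterrows()
    }
    wil = {}
    for col in ft4.X.columns:
        vals = ft4.X[col].to_numpy(dtype=float)
        if labels_true.any() and (~labels_true).any():
            wil[col] = wilcoxon_ranksum(vals[~labels_true], vals[labels_true])
    report["wilcoxon_fitters_vs_non"] = wil

    report = _jsonable(report)
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_frame().to_csv(out / "cohort.csv", index=False)
        dio.write_measure_table(measures, out / "measures.csv")
        for set_id, res in results.items():
            res.to_frame().to_csv(out / f"predictions_set{set_id}.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def make_fixtures(seed: int = 0, output_dir: str | Path = "fixtures") -> PipelineConfig:
    """Write a minute-scale on-disk data set (16^3 grid, 12 regions, 8
    healthy subjects of 500 streamlines, 12 patients) exercising the
    external-mode readers end to end."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ph = PhantomConfig(
        grid_shape=(16, 16, 16),
        n_regions=12,
        n_healthy=8,
        n_streamlines=500,
        n_patients=12,
        seed=seed,
    )
    parc, healthy = generate_phantom(ph)
    cohort = generate_cohort(ph, parc, healthy)
    dio.write_parcellation(parc, out / "parcellation.nii")
    spaths = []
    for s in healthy:
        path = out / f"{s.subject_id}.jsonl"
        dio.write_streamlines_jsonl(s, path)
        spaths.append(str(path))
    rows = []
    for p in cohort.patients:
        lesion_path = f"lesion_{p.id}.nii"
        dio.write_lesion_mask(p.lesion, out / lesion_path)
        rows.append(
            {
                "id": p.id,
                "age": p.age,
                "fma_2w": p.fma_2w,
                "fma_3m": p.fma_3m,
                "lesion_path": lesion_path,
                "fa_h": p.fa_h,
                "fa_l": p.fa_l,
            }
        )
    pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)
    return PipelineConfig(
        mode="external",
        parcellation_path=str(out / "parcellation.nii"),
        streamline_paths=tuple(spaths),
        cohort_csv=str(out / "cohort.csv"),
        seed=seed,
        bootstrap_draws=500,
        bootstrap_subsample=10,
        output_dir=str(out / "results"),
    )
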