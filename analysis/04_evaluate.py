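"""Evaluation layer: fitter labelling, classification and statistics.

Labels patients as fitters/non-fitters of the 70% proportional recovery
rule (30% recovery-score threshold, cross-checked against hierarchical
clustering), scores each feature set's fitter classification, bootstraps
R^2 confidence intervals, and computes the univariate statistics
(Spearman correlations with recovery, Bonferroni corrected; rank-sum
tests between fitters and non-fitters; the feature dendrogram).
Writes results/evaluation.json.
"""

import argparse
import importlib.util
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from disconnectome import io as dio
from disconnectome.evaluation import (
    bootstrap_r2_ci,
    classification_metrics,
    feature_dendrogram,
    label_fitters_clustering,
    label_fitters_threshold,
    spearman_bonferroni,
    wilcoxon_ranksum,
)
from disconnectome.features import FMA_MAX, assemble_feature_set, fma_recovery_score

ROOT = Path(__file__).resolve().parents[1]
_spec = importlib.util.spec_from_file_location(
    "step02", Path(__file__).parent / "02_virtual_lesion_measures.py"
)
_step02 = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_step02)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--measures", type=Path, default=ROOT / "results" / "measures.csv")
    ap.add_argument("--predictions", type=Path, default=ROOT / "results")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "evaluation.json")
    args = ap.parse_args()

    warnings.filterwarnings("ignore", category=UserWarning)
    _, _, cohort = _step02.load_dataset(args.data)
    measures = dio.read_measure_table(args.measures)
    recovery = np.array(
        [fma_recovery_score(p.fma_2w, p.fma_3m) for p in cohort.patients]
    )
    labels = label_fitters_threshold(recovery)
    expected = np.array([0.7 * (FMA_MAX - p.fma_2w) for p in cohort.patients])
    actual = np.array([p.fma_3m - p.fma_2w for p in cohort.patients])
    clust = label_fitters_clustering(expected, actual)
    report = {
        "n_fitters": int(labels.sum()),
        "n_non_fitters": int((~labels).sum()),
        "label_agreement": float((labels == clust).mean()),
        "sets": {},
    }
    print(
        f"fitters {labels.sum()}/{len(labels)}; "
        f"threshold vs clustering agreement {report['label_agreement']:.0%}"
    )

    for set_id in (1, 2, 3, 4, 5):
        path = Path(args.predictions) / f"predictions_set{set_id}.csv"
        if not path.exists():
            continue
        pred = pd.read_csv(path, index_col=0)
        y, yp = pred["observed"].to_numpy(), pred["predicted"].to_numpy()
        cm = classification_metrics(labels, yp > 30.0)
        ci = bootstrap_r2_ci(y, yp, n_draws=10_000, subsample=32, seed=args.seed)
        report["sets"][set_id] = {
            "r2": ci.point_r2,
            "ci": [ci.lower, ci.upper],
            "specificity": cm.specificity,
            "sensitivity": cm.sensitivity,
            "ppv": cm.ppv,
            "npv": cm.npv,
        }
        print(
            f"Set {set_id}: R^2 {ci.point_r2:.3f} "
            f"[{ci.lower:.3f}, {ci.upper:.3f}]  "
            f"spec {cm.specificity}  sens {cm.sensitivity}"
        )

    ft4 = assemble_feature_set(4, cohort, measures=measures)
    spear = spearman_bonferroni(ft4.X, recovery, m_tests=ft4.X.shape[1])
    report["spearman"] = {
        f: {"rho": None if np.isnan(r.rho) else r.rho,
            "p_adj": None if np.isnan(r.p_adj) else r.p_adj}
        for f, r in spear.iterrows()
    }
    report["wilcoxon"] = {
        col: wilcoxon_ranksum(
            ft4.X[col].to_numpy()[~labels], ft4.X[col].to_numpy()[labels]
        )
        for col in ft4.X.columns
        if labels.any() and (~labels).any()
    }
    try:
        _, (g1, g2) = feature_dendrogram(ft4.X)
        report["dendrogram_first_split"] = [sorted(g1), sorted(g2)]
    except ValueError:
        report["dendrogram_first_split"] = None

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    top = spear["rho"].abs().sort_values(ascending=False).head(5)
    print("strongest recovery correlates:")
    print(top.to_string())


if __name__ == "__main__":
    main()
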