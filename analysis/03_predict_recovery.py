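"""Predict motor recovery from the five feature sets.

Runs nested leave-one-out ridge regression (with VIF feature selection
for the connectivity-augmented sets 4 and 5) on each feature ladder rung
and reports the prediction-centred R^2, per-fold feature selection counts
and fold-averaged weights.  Writes per-set prediction CSVs and
results/prediction_summary.json.
"""

import argparse
import importlib.util
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from disconnectome import io as dio
from disconnectome.features import assemble_feature_set
from disconnectome.prediction import loo_predict

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
    ap.add_argument("--vif-threshold", type=float, default=23.0)
    ap.add_argument("--target", choices=["recovery", "outcome"], default="recovery")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    _, _, cohort = _step02.load_dataset(args.data)
    measures = dio.read_measure_table(args.measures)
    args.out.mkdir(parents=True, exist_ok=True)

    summary = {}
    warnings.filterwarnings("ignore", category=UserWarning)
    for set_id in (1, 2, 3, 4, 5):
        ft = assemble_feature_set(
            set_id, cohort, measures=measures, target_kind=args.target
        )
        vif_thr = args.vif_threshold if set_id in (4, 5) else None
        res = loo_predict(ft, vif_threshold=vif_thr)
        res.to_frame().to_csv(args.out / f"predictions_set{set_id}.csv")
        summary[f"set{set_id}"] = {
            "r2": res.r2,
            "n_features": ft.X.shape[1],
            "mean_selected": float(np.mean([len(f) for f in res.fold_features])),
            "selection_count": res.selection_count,
            "weight_mean": res.weight_mean,
            "weight_sd": res.weight_sd,
            "lambda_median": float(np.median(res.fold_lambda)),
        }
        print(
            f"Set {set_id}: R^2 = {res.r2:.3f}  "
            f"(features {ft.X.shape[1]}, selected on average "
            f"{summary[f'set{set_id}']['mean_selected']:.1f})"
        )
    with open(args.out / "prediction_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    always = [
        f for f, c in summary["set4"]["selection_count"].items()
        if c == len(cohort)
    ]
    print(f"features selected in every Set-4 fold: {len(always)}/{len(summary['set4']['selection_count'])}")


if __name__ == "__main__":
    main()
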