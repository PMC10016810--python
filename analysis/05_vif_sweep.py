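"""Accuracy of the Set-4 model across VIF selection thresholds.

Sweeps the VIF elimination threshold and records the outer leave-one-out
R^2 and the mean number of retained features, reproducing the
accuracy-versus-collinearity trade-off curve.  The operating threshold of
the pipeline remains a configuration value; this curve is diagnostic
output, not a selection procedure.  Writes results/vif_sweep.csv and a
plot results/vif_sweep.png.
"""

import argparse
import importlib.util
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from disconnectome import io as dio
from disconnectome.features import assemble_feature_set
from disconnectome.prediction import vif_sweep

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
    ap.add_argument("--lo", type=int, default=5)
    ap.add_argument("--hi", type=int, default=200)
    ap.add_argument("--step", type=int, default=5,
                    help="threshold stride (1 reproduces the every-unit sweep)")
    ap.add_argument("--set", dest="set_id", type=int, default=4, choices=(4, 5))
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    warnings.filterwarnings("ignore", category=UserWarning)
    _, _, cohort = _step02.load_dataset(args.data)
    measures = dio.read_measure_table(args.measures)
    ft = assemble_feature_set(args.set_id, cohort, measures=measures)
    curve = vif_sweep(ft, thresholds=range(args.lo, args.hi + 1, args.step))
    args.out.mkdir(parents=True, exist_ok=True)
    curve.to_csv(args.out / "vif_sweep.csv", index=False)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["threshold"], curve["r2"], marker=".", lw=1)
    ax.set_xlabel("VIF threshold")
    ax.set_ylabel("leave-one-out $R^2$")
    ax.set_title(f"Set {args.set_id}: accuracy vs collinearity threshold")
    fig.tight_layout()
    fig.savefig(args.out / "vif_sweep.png", dpi=150)

    best = curve.loc[curve["r2"].idxmax()]
    print(curve.head(10).to_string(index=False))
    print(
        f"max R^2 {best['r2']:.3f} at threshold {best['threshold']:.0f} "
        f"({best['n_features']:.1f} features on average)"
    )


if __name__ == "__main__":
    main()
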