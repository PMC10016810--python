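"""Generate the synthetic study data set.

Builds the phantom brain (36-region, two-hemisphere parcellation), 60
healthy jittered tractograms and a 40-patient stroke cohort whose
recovery follows the planted model, and writes everything in the
external-mode on-disk layout under results/data/ so the later steps (and
any external tool) can consume it from disk.
"""

import argparse
from pathlib import Path

import pandas as pd

from disconnectome import io as dio
from disconnectome.phantom import PhantomConfig, generate_cohort, generate_phantom
from disconnectome.virtual_lesion import StreamlineCache

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "data")
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    cfg = PhantomConfig(seed=args.seed)
    parc, healthy = generate_phantom(cfg)
    caches = [StreamlineCache.precompute(s, parc) for s in healthy]
    cohort = generate_cohort(cfg, parc, healthy, caches=caches)

    dio.write_parcellation(parc, out / "parcellation.nii")
    for s in healthy:
        dio.write_streamlines_jsonl(s, out / f"{s.subject_id}.jsonl")
    rows = []
    for p in cohort.patients:
        dio.write_lesion_mask(p.lesion, out / f"lesion_{p.id}.nii")
        rows.append(
            {
                "id": p.id, "age": p.age, "fma_2w": p.fma_2w, "fma_3m": p.fma_3m,
                "lesion_path": f"lesion_{p.id}.nii", "fa_h": p.fa_h, "fa_l": p.fa_l,
            }
        )
    pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)
    cohort.truth.to_csv(out / "cohort_truth.csv")

    print(f"phantom data set written to {out}")
    print(f"  {cfg.n_healthy} healthy tractograms x {cfg.n_streamlines} streamlines")
    print(f"  {cfg.n_patients} patients; recovery summary:")
    print(cohort.truth["recovery"].describe().to_string())


if __name__ == "__main__":
    main()
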