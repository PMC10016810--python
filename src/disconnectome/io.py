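"""Readers and writers for the on-disk formats of the pipeline.

Volumes (parcellations, lesion masks) are NIfTI via nibabel; streamlines
are TCK (nibabel.streamlines) or JSON-lines (one polyline per line as a
list of ``[x, y, z]`` vertices); connectomes and tables are CSV.  All
voxel coordinates assume an identity affine unless a NIfTI affine says
otherwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .virtual_lesion import Connectome, LesionMask, Parcellation, StreamlineSet

__all__ = [
    "write_parcellation", "read_parcellation",
    "write_lesion_mask", "read_lesion_mask",
    "write_streamlines_jsonl", "read_streamlines_jsonl",
    "write_streamlines_tck", "read_streamlines_tck",
    "write_connectome_csv", "read_connectome_csv",
    "write_measure_table", "read_measure_table",
]


def write_parcellation(p: Parcellation, path) -> None:
    affine = np.diag(list(p.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(p.label_volume.astype(np.int32), affine), str(path))


def read_parcellation(path) -> Parcellation:
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Parcellation(
        label_volume=np.asarray(img.dataobj).astype(np.int32), voxel_size=vox
    )


def write_lesion_mask(m: LesionMask, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(m.to_volume(), affine), str(path))


def read_lesion_mask(path) -> LesionMask:
    img = nib.load(str(path))
    return LesionMask.from_volume(np.asarray(img.dataobj))


def write_streamlines_jsonl(s: StreamlineSet, path) -> None:
    with open(path, "w") as fh:
        for sl in s.streamlines:
            fh.write(json.dumps(np.asarray(sl).tolist()) + "\n")


def read_streamlines_jsonl(path, subject_id: str = "", grid_shape=None) -> StreamlineSet:
    sls = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                sls.append(np.asarray(json.loads(line), dtype=float))
    sid = subject_id or Path(path).stem
    return StreamlineSet(streamlines=sls, subject_id=sid, grid_shape=grid_shape)


def write_streamlines_tck(s: StreamlineSet, path) -> None:
    tracto = nib.streamlines.Tractogram(
        [np.asarray(sl, dtype=np.float32) for sl in s.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tracto, str(path))


def read_streamlines_tck(path, subject_id: str = "", grid_shape=None) -> StreamlineSet:
    tck = nib.streamlines.load(str(path))
    sid = subject_id or Path(path).stem
    return StreamlineSet(
        streamlines=[np.asarray(sl, dtype=float) for sl in tck.streamlines],
        subject_id=sid,
        grid_shape=grid_shape,
    )


def read_streamlines(path, subject_id: str = "", grid_shape=None) -> StreamlineSet:
    path = Path(path)
    if path.suffix == ".tck":
        return read_streamlines_tck(path, subject_id, grid_shape)
    return read_streamlines_jsonl(path, subject_id, grid_shape)


def write_connectome_csv(c: Connectome, path) -> None:
    n = c.n_regions
    pd.DataFrame(
        c.weights, index=range(1, n + 1), columns=range(1, n + 1)
    ).to_csv(path)


def read_connectome_csv(path) -> Connectome:
    df = pd.read_csv(path, index_col=0)
    return Connectome(weights=df.to_numpy(dtype=float))


def write_measure_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="id")


def read_measure_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
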