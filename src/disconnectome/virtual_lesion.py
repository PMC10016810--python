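"""Virtual lesioning of healthy streamline sets.

A patient's lesion mask is intersected with streamline tractograms from
healthy subjects: every streamline whose path crosses a lesioned voxel is
deleted, and the surviving streamlines are aggregated into a
volume-normalized region-by-region connectome.  This yields an indirect
estimate of the patient's structural connectome without any
diffusion-weighted acquisition of the patient.

Coordinates are continuous, 0-based voxel coordinates: voxel ``(i, j, k)``
spans the half-open cube ``[i, i+1) x [j, j+1) x [k, k+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Parcellation",
    "StreamlineSet",
    "LesionMask",
    "Connectome",
    "StreamlineCache",
    "rasterize_streamline",
    "rasterize_set",
    "apply_virtual_lesion",
    "assign_endpoints",
    "build_connectome",
]

#: supersampling step (voxels) used when rasterizing a streamline segment
RASTER_STEP = 0.5

#: default Chebyshev radius for endpoint-to-region assignment
DEFAULT_ASSIGN_RADIUS = 2


@dataclass(frozen=True)
class Parcellation:
    """Labelled voxel grid splitting the brain into hemisphere-tagged regions.

    ``label_volume`` holds integer region IDs with 0 for background; IDs
    ``1..N/2`` are left-hemisphere, ``N/2+1..N`` right-hemisphere.
    """

    label_volume: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        lv = np.asarray(self.label_volume)
        if lv.ndim != 3:
            raise ValueError("label_volume must be a 3-D integer grid")
        object.__setattr__(self, "label_volume", lv.astype(np.int32))
        n = int(lv.max())
        if n < 2 or n % 2 != 0:
            raise ValueError(f"number of regions must be even and >= 2, got {n}")
        counts = np.bincount(lv.ravel(), minlength=n + 1)
        if np.any(counts[1:] == 0):
            empty = np.nonzero(counts[1:] == 0)[0] + 1
            raise ValueError(f"regions with no voxels: {empty.tolist()}")

    @property
    def n_regions(self) -> int:
        return int(self.label_volume.max())

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.label_volume.shape)  # type: ignore[return-value]

    @property
    def region_volume(self) -> np.ndarray:
        """Voxel count per region, index 0 unused."""
        return np.bincount(self.label_volume.ravel(), minlength=self.n_regions + 1)

    def hemisphere_of(self, region: int) -> str:
        if not 1 <= region <= self.n_regions:
            raise ValueError(f"region {region} out of range 1..{self.n_regions}")
        return "L" if region <= self.n_regions // 2 else "R"


@dataclass(frozen=True)
class StreamlineSet:
    """A set of polylines (continuous voxel coordinates) for one subject."""

    streamlines: list[np.ndarray]
    subject_id: str = ""
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        sls = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in sls:
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError("each streamline needs >= 2 vertices of 3 coords")
        object.__setattr__(self, "streamlines", sls)

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass(frozen=True)
class LesionMask:
    """Set of lesioned voxels on a grid."""

    voxels: frozenset
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxels", frozenset(map(tuple, self.voxels)))
        for v in self.voxels:
            if any(c < 0 or c >= s for c, s in zip(v, self.grid_shape)):
                raise ValueError(f"voxel {v} outside grid {self.grid_shape}")

    @classmethod
    def from_volume(cls, volume: np.ndarray) -> "LesionMask":
        vol = np.asarray(volume)
        voxels = frozenset(map(tuple, np.argwhere(vol > 0).tolist()))
        return cls(voxels=voxels, grid_shape=tuple(vol.shape))

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid_shape, dtype=np.uint8)
        if self.voxels:
            idx = np.array(sorted(self.voxels))
            vol[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        return vol

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass(frozen=True)
class Connectome:
    """Symmetric volume-normalized streamline-count matrix.

    Entry ``(i, j)`` is ``c_ij / (V_i + V_j)`` where ``c_ij`` counts the
    streamlines with endpoints in regions ``i`` and ``j`` and ``V`` are
    region voxel volumes.
    """

    weights: np.ndarray
    n_streamlines_used: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------------------
# rasterization


def _supersample(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Points along segment a->b at spacing <= RASTER_STEP, both ends included."""
    length = float(np.linalg.norm(b - a))
    n = max(int(np.ceil(length / RASTER_STEP)), 1)
    t = np.linspace(0.0, 1.0, n + 1)
    return a[None, :] + t[:, None] * (b - a)[None, :]


def rasterize_streamline(polyline: np.ndarray, grid_shape) -> set:
    """Voxels entered by a polyline.

    Each segment is supersampled at step <= 0.5 voxel and sample points are
    floored to voxel indices; both endpoint voxels are always included.
    Samples are clipped into the grid.
    """
    poly = np.asarray(polyline, dtype=float)
    pts = np.concatenate(
        [_supersample(poly[i], poly[i + 1]) for i in range(len(poly) - 1)]
    )
    idx = np.floor(pts).astype(np.int64)
    np.clip(idx, 0, np.asarray(grid_shape) - 1, out=idx)
    return set(map(tuple, idx.tolist()))


def rasterize_set(s: StreamlineSet, grid_shape) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized rasterization of a whole streamline set.

    Returns ``(flat_voxels, offsets)``: ``flat_voxels`` concatenates the
    unique linear voxel indices of every streamline and
    ``flat_voxels[offsets[k]:offsets[k+1]]`` are the voxels of streamline
    ``k``.  Agrees with :func:`rasterize_streamline` per streamline.
    """
    shape = np.asarray(grid_shape)
    per_stream: list[np.ndarray] = []
    for poly in s.streamlines:
        a = poly[:-1]
        b = poly[1:]
        seg_len = np.linalg.norm(b - a, axis=1)
        n = np.maximum(np.ceil(seg_len / RASTER_STEP).astype(int), 1)
        # sample every segment, endpoints included
        reps = n + 1
        total = int(reps.sum())
        seg_id = np.repeat(np.arange(len(a)), reps)
        within = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps)
        t = within / n[seg_id]
        pts = a[seg_id] + t[:, None] * (b[seg_id] - a[seg_id])
        idx = np.floor(pts).astype(np.int64)
        np.clip(idx, 0, shape - 1, out=idx)
        lin = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), tuple(shape))
        per_stream.append(np.unique(lin))
    offsets = np.zeros(len(per_stream) + 1, dtype=np.int64)
    np.cumsum([len(v) for v in per_stream], out=offsets[1:])
    flat = (
        np.concatenate(per_stream)
        if per_stream
        else np.empty(0, dtype=np.int64)
    )
    return flat, offsets


# ---------------------------------------------------------------------------
# virtual lesioning


def _crossing_flags(s: StreamlineSet, m: LesionMask) -> np.ndarray:
    """Boolean flag per streamline: does it traverse any lesioned voxel."""
    if not m.voxels:
        return np.zeros(len(s), dtype=bool)
    flat, offsets = rasterize_set(s, m.grid_shape)
    mask = np.zeros(int(np.prod(m.grid_shape)), dtype=bool)
    idx = np.array(sorted(m.voxels))
    mask[np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), m.grid_shape)] = True
    hit = mask[flat]
    out = np.zeros(len(s), dtype=bool)
    nonempty = offsets[1:] > offsets[:-1]
    if hit.size:
        agg = np.maximum.reduceat(hit, offsets[:-1][nonempty])
        out[nonempty] = agg
    return out


def apply_virtual_lesion(s: StreamlineSet, m: LesionMask) -> StreamlineSet:
    """Delete every streamline passing through the lesioned area.

    A streamline is transected when any of its rasterized voxels lies in
    the mask.  Order of survivors is preserved; the input is not modified.
    """
    if s.grid_shape is not None and tuple(s.grid_shape) != tuple(m.grid_shape):
        raise ValueError(
            f"grid mismatch: streamlines {s.grid_shape} vs mask {m.grid_shape}"
        )
    crossing = _crossing_flags(s, m)
    kept = [sl for sl, hit in zip(s.streamlines, crossing) if not hit]
    return StreamlineSet(
        streamlines=kept, subject_id=s.subject_id, grid_shape=m.grid_shape
    )


# ---------------------------------------------------------------------------
# endpoint assignment and connectome construction


def _assign_point(point: np.ndarray, labels: np.ndarray, radius: int) -> int:
    """Region of the voxel containing ``point``; nearest labelled voxel
    within Chebyshev ``radius`` if that voxel is background; 0 if none."""
    shape = np.asarray(labels.shape)
    v = np.floor(point).astype(int)
    v = np.clip(v, 0, shape - 1)
    lab = int(labels[tuple(v)])
    if lab > 0:
        return lab
    for r in range(1, int(radius) + 1):
        lo = np.maximum(v - r, 0)
        hi = np.minimum(v + r + 1, shape)
        block = labels[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]]
        cand = np.argwhere(block > 0)
        if len(cand):
            cand_abs = cand + lo
            cheb = np.abs(cand_abs - v).max(axis=1)
            order = np.lexsort((cand_abs[:, 2], cand_abs[:, 1], cand_abs[:, 0], cheb))
            return int(labels[tuple(cand_abs[order[0]])])
    return 0


def assign_endpoints(
    polyline: np.ndarray,
    p: Parcellation,
    radius: int = DEFAULT_ASSIGN_RADIUS,
) -> tuple[int, int] | None:
    """Map a streamline's two endpoints to parcellation regions.

    Returns ``None`` when either endpoint is in background with no labelled
    voxel within the Chebyshev search radius.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    poly = np.asarray(polyline, dtype=float)
    r1 = _assign_point(poly[0], p.label_volume, radius)
    r2 = _assign_point(poly[-1], p.label_volume, radius)
    if r1 == 0 or r2 == 0:
        return None
    return (r1, r2)


def endpoint_regions(
    s: StreamlineSet, p: Parcellation, radius: int = DEFAULT_ASSIGN_RADIUS
) -> np.ndarray:
    """Per-streamline endpoint region pairs, 0 marking unassigned ends."""
    labels = p.label_volume
    shape = np.asarray(labels.shape)
    ends = np.array([[sl[0], sl[-1]] for sl in s.streamlines], dtype=float)
    if len(ends) == 0:
        return np.empty((0, 2), dtype=np.int64)
    out = np.empty((len(ends), 2), dtype=np.int64)
    for side in (0, 1):
        v = np.floor(ends[:, side, :]).astype(np.int64)
        np.clip(v, 0, shape - 1, out=v)
        lab = labels[v[:, 0], v[:, 1], v[:, 2]].astype(np.int64)
        bg = lab == 0
        for i in np.nonzero(bg)[0]:
            lab[i] = _assign_point(ends[i, side], labels, radius)
        out[:, side] = lab
    return out


def build_connectome(
    s: StreamlineSet,
    p: Parcellation,
    radius: int = DEFAULT_ASSIGN_RADIUS,
) -> Connectome:
    """Count streamlines per region pair and normalize by summed volumes.

    Streamlines with an unassignable endpoint or with both endpoints in the
    same region are excluded from the matrix (the diagonal stays zero) and
    do not count towards ``n_streamlines_used``.
    """
    n = p.n_regions
    vol = p.region_volume
    pairs = endpoint_regions(s, p, radius)
    counts = np.zeros((n + 1, n + 1), dtype=np.int64)
    if len(pairs):
        valid = (pairs[:, 0] > 0) & (pairs[:, 1] > 0) & (pairs[:, 0] != pairs[:, 1])
        lo = np.minimum(pairs[valid, 0], pairs[valid, 1])
        hi = np.maximum(pairs[valid, 0], pairs[valid, 1])
        np.add.at(counts, (lo, hi), 1)
    c = counts[1:, 1:]
    c = c + c.T
    denom = vol[1:, None] + vol[None, 1:]
    weights = c / denom
    np.fill_diagonal(weights, 0.0)
    used = int(c.sum() // 2)
    return Connectome(weights=weights, n_streamlines_used=used)


# ---------------------------------------------------------------------------
# precomputed fast path


@dataclass
class StreamlineCache:
    """Precomputed rasterization and endpoint assignment for one subject.

    Intersecting the same healthy tractogram with many different lesion
    masks only needs each streamline's traversed voxels and endpoint region
    pair once; afterwards every virtual lesion is a vectorized lookup.
    Results are identical to :func:`apply_virtual_lesion` followed by
    :func:`build_connectome` (tested as a property).
    """

    flat_voxels: np.ndarray
    offsets: np.ndarray
    pairs: np.ndarray
    n_regions: int
    region_volume: np.ndarray
    grid_shape: tuple[int, int, int]

    @classmethod
    def precompute(
        cls,
        s: StreamlineSet,
        p: Parcellation,
        radius: int = DEFAULT_ASSIGN_RADIUS,
    ) -> "StreamlineCache":
        flat, offsets = rasterize_set(s, p.grid_shape)
        pairs = endpoint_regions(s, p, radius)
        return cls(
            flat_voxels=flat,
            offsets=offsets,
            pairs=pairs,
            n_regions=p.n_regions,
            region_volume=p.region_volume.copy(),
            grid_shape=p.grid_shape,
        )

    def _mask_flat(self, m: LesionMask) -> np.ndarray:
        if tuple(m.grid_shape) != tuple(self.grid_shape):
            raise ValueError("grid mismatch between cache and mask")
        mask = np.zeros(int(np.prod(self.grid_shape)), dtype=bool)
        if m.voxels:
            idx = np.array(sorted(m.voxels))
            mask[
                np.ravel_multi_index(
                    (idx[:, 0], idx[:, 1], idx[:, 2]), self.grid_shape
                )
            ] = True
        return mask

    def surviving(self, m: LesionMask) -> np.ndarray:
        """Boolean flag per streamline: survives the lesion."""
        mask = self._mask_flat(m)
        n = len(self.offsets) - 1
        hit = mask[self.flat_voxels]
        out = np.zeros(n, dtype=bool)
        nonempty = self.offsets[1:] > self.offsets[:-1]
        if hit.size:
            out[nonempty] = np.maximum.reduceat(
                hit, self.offsets[:-1][nonempty]
            )
        return ~out

    def connectome(self, m: LesionMask | None = None) -> Connectome:
        """Volume-normalized connectome of the surviving streamlines."""
        n = self.n_regions
        if m is None:
            alive = np.ones(len(self.offsets) - 1, dtype=bool)
        else:
            alive = self.surviving(m)
        pairs = self.pairs[alive]
        counts = np.zeros((n + 1, n + 1), dtype=np.int64)
        if len(pairs):
            valid = (
                (pairs[:, 0] > 0) & (pairs[:, 1] > 0) & (pairs[:, 0] != pairs[:, 1])
            )
            lo = np.minimum(pairs[valid, 0], pairs[valid, 1])
            hi = np.maximum(pairs[valid, 0], pairs[valid, 1])
            np.add.at(counts, (lo, hi), 1)
        c = counts[1:, 1:]
        c = c + c.T
        denom = self.region_volume[1:, None] + self.region_volume[None, 1:]
        weights = c / denom
        np.fill_diagonal(weights, 0.0)
        return Connectome(weights=weights, n_streamlines_used=int(c.sum() // 2))
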