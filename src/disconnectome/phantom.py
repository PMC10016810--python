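"""Synthetic phantom brains, tractograms, lesions and patient cohorts.

The generator emulates the data the analysis assumes: a two-hemisphere
parcellation of a voxel grid, ~60 healthy whole-brain streamline sets that
differ only by small per-subject jitter of a shared template, focal
ellipsoidal lesions of controllable size and placement, and a stroke cohort
whose recovery follows a planted linear model

    recovery% = b0 + b1 * FMA_2w + b2 * asymmetry + b3 * damage + noise

clipped to [0, 100], where ``damage`` is the drop in mean weighted global
efficiency actually caused by the patient's lesion (computed through the
virtual-lesioning machinery, not assumed).  Clipping at 0 produces the
mass of barely-recovering patients ("non-fitters") that real cohorts show.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph_measures import global_efficiency_weighted
from .virtual_lesion import (
    LesionMask,
    Parcellation,
    StreamlineCache,
    StreamlineSet,
    rasterize_set,
)

__all__ = [
    "PhantomConfig",
    "PatientRecord",
    "Cohort",
    "generate_phantom",
    "generate_lesion",
    "generate_cohort",
    "traversal_density",
]

#: fractional-anisotropy attenuation per unit fraction of CST transected
FA_ATTENUATION = 0.5

#: severity range sampled for patients
SEVERITY_RANGE = (0.05, 0.9)

#: lesion-centre placement mix over (cst, random, hub)
CENTRE_BIAS_MIX = (0.5, 0.25, 0.25)


@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of the synthetic study.

    ``planted_betas`` are (intercept, initial-FMA, CST-asymmetry,
    network-damage) coefficients of the planted recovery model, in
    percentage points of recovery; ``noise_sd`` is the SD of the additive
    recovery noise in the same units.
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    n_regions: int = 36
    n_healthy: int = 60
    n_streamlines: int = 5000
    n_patients: int = 40
    hub_exponent: float = 1.0
    noise_sd: float = 2.0
    planted_betas: tuple[float, float, float, float] = (25.0, 1.0, -100.0, -60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_regions % 2 != 0:
            raise ValueError("n_regions must be even and >= 2")
        for name in ("n_healthy", "n_streamlines", "n_patients"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(g < 2 for g in self.grid_shape):
            raise ValueError("grid_shape dims must be >= 2")
        if self.hub_exponent < 0:
            raise ValueError("hub_exponent must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.planted_betas) != 4:
            raise ValueError("planted_betas must have 4 entries")


@dataclass(frozen=True)
class PatientRecord:
    id: str
    age: float
    fma_2w: int
    fma_3m: int
    lesion: LesionMask
    fa_h: float
    fa_l: float

    def __post_init__(self) -> None:
        if not 0 <= self.fma_2w <= 55:
            raise ValueError("fma_2w must be in [0, 55] (inclusion criterion)")
        if not 0 <= self.fma_3m <= 66:
            raise ValueError("fma_3m must be in [0, 66]")
        if self.fa_h <= 0 or self.fa_l <= 0:
            raise ValueError("FA values must be strictly positive")


@dataclass(frozen=True)
class Cohort:
    patients: tuple
    provenance: object = "external"
    #: planted ground truth per patient (severity, damage, asymmetry,
    #: recovery%) -- only present for synthetic cohorts
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")
        object.__setattr__(self, "patients", tuple(self.patients))

    def __len__(self) -> int:
        return len(self.patients)

    def ids(self) -> list[str]:
        return [p.id for p in self.patients]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self.patients],
                "age": [p.age for p in self.patients],
                "fma_2w": [p.fma_2w for p in self.patients],
                "fma_3m": [p.fma_3m for p in self.patients],
                "fa_h": [p.fa_h for p in self.patients],
                "fa_l": [p.fa_l for p in self.patients],
            }
        )


# ---------------------------------------------------------------------------
# parcellation


def _factor3(n: int) -> tuple[int, int, int]:
    """Most cubic factorization n = a*b*c, a <= b <= c."""
    best = (1, 1, n)
    best_spread = n
    for a in range(1, int(round(n ** (1 / 3))) + 2):
        if n % a:
            continue
        m = n // a
        for b in range(a, int(np.sqrt(m)) + 1):
            if m % b:
                continue
            c = m // b
            if c - a < best_spread:
                best_spread = c - a
                best = (a, b, c)
    return best


def _build_parcellation(grid_shape, n_regions: int) -> Parcellation:
    nx_, ny, nz = grid_shape
    half = n_regions // 2
    a, b, c = _factor3(half)
    # split each hemisphere (x < nx/2 is left) into a*b*c contiguous boxes
    hx = nx_ // 2
    if hx < a or ny < b or nz < c:
        raise ValueError(
            f"grid {grid_shape} too small for {n_regions} regions "
            f"(needs >= {a} x-slabs per hemisphere, {b} y, {c} z)"
        )
    labels = np.zeros(grid_shape, dtype=np.int32)
    for hemi, (x0, x1) in enumerate([(0, hx), (hx, nx_)]):
        x_edges = np.linspace(x0, x1, a + 1).astype(int)
        y_edges = np.linspace(0, ny, b + 1).astype(int)
        z_edges = np.linspace(0, nz, c + 1).astype(int)
        rid = hemi * half + 1
        for i in range(a):
            for j in range(b):
                for k in range(c):
                    labels[
                        x_edges[i]: x_edges[i + 1],
                        y_edges[j]: y_edges[j + 1],
                        z_edges[k]: z_edges[k + 1],
                    ] = rid
                    rid += 1
    return Parcellation(label_volume=labels)


# ---------------------------------------------------------------------------
# streamline template and subjects


def _region_voxels(p: Parcellation) -> list[np.ndarray]:
    """Voxel index arrays per region (1-based list, entry 0 unused)."""
    out = [np.empty((0, 3), dtype=int)]
    for r in range(1, p.n_regions + 1):
        out.append(np.argwhere(p.label_volume == r))
    return out


def _make_template(
    cfg: PhantomConfig, p: Parcellation, rng: np.random.Generator
) -> list[np.ndarray]:
    """Straight polylines between region pairs drawn by preferential
    attachment on current endpoint counts (degree^hub_exponent, +1 smoothing)."""
    nreg = p.n_regions
    voxels = _region_voxels(p)
    deg = np.zeros(nreg)
    template: list[np.ndarray] = []
    for _ in range(cfg.n_streamlines):
        wts = (deg + 1.0) ** cfg.hub_exponent
        pr = wts / wts.sum()
        r1 = int(rng.choice(nreg, p=pr)) + 1
        wts2 = wts.copy()
        wts2[r1 - 1] = 0.0
        pr2 = wts2 / wts2.sum()
        r2 = int(rng.choice(nreg, p=pr2)) + 1
        deg[r1 - 1] += 1
        deg[r2 - 1] += 1
        a = voxels[r1][rng.integers(len(voxels[r1]))] + rng.random(3)
        b = voxels[r2][rng.integers(len(voxels[r2]))] + rng.random(3)
        n_pts = max(int(np.ceil(np.linalg.norm(b - a))) + 1, 2)
        t = np.linspace(0.0, 1.0, n_pts)
        template.append(a[None, :] + t[:, None] * (b - a)[None, :])
    return template


def generate_phantom(
    config: PhantomConfig,
) -> tuple[Parcellation, list[StreamlineSet]]:
    """Build the phantom parcellation and the healthy streamline sets.

    Subjects share one template tractogram and differ only by seeded
    Gaussian vertex jitter (SD 0.3 voxel), preserving the semantics of
    averaging measures over healthy connectomes.
    """
    rng = np.random.default_rng(config.seed)
    parc = _build_parcellation(config.grid_shape, config.n_regions)
    template = _make_template(config, parc, rng)
    hi = np.asarray(config.grid_shape, dtype=float) - 1e-3
    subjects = []
    for s in range(config.n_healthy):
        jittered = []
        for poly in template:
            q = poly + rng.normal(0.0, 0.3, size=poly.shape)
            np.clip(q, 0.0, hi, out=q)
            jittered.append(q)
        subjects.append(
            StreamlineSet(
                streamlines=jittered,
                subject_id=f"sub{s:02d}",
                grid_shape=tuple(config.grid_shape),
            )
        )
    return parc, subjects


def traversal_density(streamlines: StreamlineSet | list[np.ndarray], grid_shape) -> np.ndarray:
    """Per-voxel count of streamlines traversing it."""
    if not isinstance(streamlines, StreamlineSet):
        streamlines = StreamlineSet(
            streamlines=list(streamlines), grid_shape=tuple(grid_shape)
        )
    flat, _ = rasterize_set(streamlines, grid_shape)
    dens = np.bincount(flat, minlength=int(np.prod(grid_shape)))
    return dens.reshape(grid_shape)


# ---------------------------------------------------------------------------
# lesions


def generate_lesion(
    parcellation: Parcellation,
    severity: float,
    centre_bias: str = "random",
    seed: int = 0,
    density_volume: np.ndarray | None = None,
    cst_centre: np.ndarray | None = None,
    hemisphere: str | None = None,
) -> LesionMask:
    """Ellipsoidal lesion blob of size controlled by ``severity``.

    For a fixed seed the blob is a nested family: raising severity only
    grows the ellipsoid (same centre, same axis ratios), so masks at lower
    severity are voxel subsets of masks at higher severity.  ``severity=1``
    is capped to cover at least half of the brain voxels.

    centre_bias:
        ``hub``     centre at the voxel with highest streamline traversal
                    density (requires ``density_volume``);
        ``cst``     centre at the designated CST corridor (``cst_centre``);
        ``random``  uniform over labelled voxels.
    Placement can be restricted to one ``hemisphere`` ("L"/"R").
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    shape = np.asarray(parcellation.grid_shape)
    labels = parcellation.label_volume
    if severity == 0.0:
        return LesionMask(voxels=frozenset(), grid_shape=tuple(shape))
    rng = np.random.default_rng(seed)
    hemi_ok = np.ones(tuple(shape), dtype=bool)
    if hemisphere is not None:
        hx = shape[0] // 2
        if hemisphere == "L":
            hemi_ok[hx:, :, :] = False
        elif hemisphere == "R":
            hemi_ok[:hx, :, :] = False
        else:
            raise ValueError("hemisphere must be 'L' or 'R'")
    brain = (labels > 0) & hemi_ok
    if centre_bias == "random":
        cand = np.argwhere(brain)
        centre_vox = cand[rng.integers(len(cand))]
    elif centre_bias == "hub":
        if density_volume is None:
            raise ValueError("centre_bias='hub' needs density_volume")
        dens = np.where(brain, density_volume, -1)
        centre_vox = np.array(np.unravel_index(np.argmax(dens), tuple(shape)))
    elif centre_bias == "cst":
        if cst_centre is None:
            raise ValueError("centre_bias='cst' needs cst_centre")
        centre_vox = np.asarray(cst_centre, dtype=int)
    else:
        raise ValueError(f"unknown centre_bias {centre_bias!r}")
    if centre_bias != "random":
        # seeded jitter so repeated draws around the same anchor differ
        centre_vox = centre_vox + rng.integers(-2, 3, size=3)
        centre_vox = np.clip(centre_vox, 0, shape - 1)
    centre = centre_vox + 0.5
    ratios = rng.uniform(0.7, 1.3, size=3)  # fixed per seed: nestedness
    n_brain = int((labels > 0).sum())
    r50 = 1.3 * (0.5 * n_brain * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

    def ellipsoid(radius: float) -> np.ndarray:
        grid = np.indices(tuple(shape)).reshape(3, -1).T + 0.5
        dist = ((grid - centre) / (ratios * radius)) ** 2
        inside = dist.sum(axis=1) <= 1.0
        return inside.reshape(tuple(shape)) & (labels > 0)

    radius = severity * r50
    blob = ellipsoid(radius)
    if severity == 1.0:
        while blob.sum() < 0.5 * n_brain:
            radius *= 1.1
            blob = ellipsoid(radius)
    return LesionMask.from_volume(blob)


# ---------------------------------------------------------------------------
# cohort


def _cst_regions(p: Parcellation) -> dict[str, int]:
    """Per hemisphere, the region whose centroid is nearest the hemisphere
    centroid: its streamlines stand in for the cortico-spinal tract."""
    out = {}
    half = p.n_regions // 2
    for hemi, rng_ids in (("L", range(1, half + 1)), ("R", range(half + 1, p.n_regions + 1))):
        cents, ids = [], []
        for r in rng_ids:
            vox = np.argwhere(p.label_volume == r)
            cents.append(vox.mean(axis=0))
            ids.append(r)
        cents = np.array(cents)
        target = cents.mean(axis=0)
        out[hemi] = ids[int(np.argmin(((cents - target) ** 2).sum(axis=1)))]
    return out


def generate_cohort(
    config: PhantomConfig,
    parcellation: Parcellation,
    healthy: list[StreamlineSet],
    caches: list[StreamlineCache] | None = None,
) -> Cohort:
    """Draw a patient cohort whose recovery follows the planted model.

    Per patient: a lesion of drawn severity is placed (biased towards the
    CST corridor, random cortex, or the densest hub); ipsilesional CST FA
    is attenuated by the fraction of CST streamlines the lesion transects;
    network damage is the lesion-induced drop in mean weighted global
    efficiency over the healthy connectomes; recovery% is the planted
    linear model plus Gaussian noise, clipped to [0, 100], and converted
    to a 3-month FMA score.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    if caches is None:
        caches = [StreamlineCache.precompute(s, parcellation) for s in healthy]
    dens = traversal_density(healthy[0], parcellation.grid_shape)
    cst_region = _cst_regions(parcellation)
    cst_centroid = {
        h: np.argwhere(parcellation.label_volume == r).mean(axis=0).astype(int)
        for h, r in cst_region.items()
    }
    # CST bundle per subject per hemisphere: streamlines with an endpoint
    # in the designated CST region
    cst_idx = {
        h: [
            np.nonzero((c.pairs[:, 0] == r) | (c.pairs[:, 1] == r))[0]
            for c in caches
        ]
        for h, r in cst_region.items()
    }
    intact_ge = [global_efficiency_weighted(c.connectome()) for c in caches]
    b0, b1, b2, b3 = config.planted_betas
    records, truth_rows = [], []
    for i in range(config.n_patients):
        pseed = int(rng.integers(0, 2**31 - 1))
        hemi = "L" if rng.random() < 0.5 else "R"
        severity = rng.uniform(*SEVERITY_RANGE)
        bias = rng.choice(["cst", "random", "hub"], p=CENTRE_BIAS_MIX)
        age = float(np.clip(rng.normal(65.0, 12.0), 28.0, 85.0))
        lesion = generate_lesion(
            parcellation,
            severity,
            centre_bias=str(bias),
            seed=pseed,
            density_volume=dens,
            cst_centre=cst_centroid[hemi],
            hemisphere=hemi,
        )
        # CST damage -> FA asymmetry
        fracs = []
        for c, idx in zip(caches, cst_idx[hemi]):
            if len(idx) == 0:
                continue
            alive = c.surviving(lesion)
            fracs.append(1.0 - alive[idx].mean())
        frac_hit = float(np.mean(fracs)) if fracs else 0.0
        fa0 = rng.uniform(0.5, 0.6)
        fa_l = fa0 * (1.0 - FA_ATTENUATION * frac_hit)
        fa_h = fa0
        asym = (fa_h - fa_l) / (fa_h + fa_l)
        # network damage: drop in mean weighted global efficiency
        lesioned_ge = [
            global_efficiency_weighted(c.connectome(lesion)) for c in caches
        ]
        damage = float(np.mean(intact_ge) - np.mean(lesioned_ge))
        fma_2w = int(np.clip(round(55.0 * (1.0 - severity) + rng.normal(0.0, 3.0)), 0, 55))
        eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
        recovery = float(np.clip(b0 + b1 * fma_2w + b2 * asym + b3 * damage + eps, 0.0, 100.0))
        fma_3m = int(round(fma_2w + recovery / 100.0 * (66 - fma_2w)))
        records.append(
            PatientRecord(
                id=f"p{i:03d}",
                age=age,
                fma_2w=fma_2w,
                fma_3m=fma_3m,
                lesion=lesion,
                fa_h=fa_h,
                fa_l=fa_l,
            )
        )
        truth_rows.append(
            {
                "id": f"p{i:03d}",
                "severity": severity,
                "hemisphere": hemi,
                "centre_bias": str(bias),
                "cst_fraction_hit": frac_hit,
                "asymmetry": asym,
                "damage": damage,
                "recovery": recovery,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("id")
    return Cohort(patients=tuple(records), provenance=config, truth=truth)
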