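"""Synthetic RAVENS-like cohorts with known ground truth.

Real trial imaging data of the kind this pipeline analyses sit behind data
use agreements, so every downstream stage is exercised against cohorts
generated here: per-subject gray-matter-density volumes on a common grid,
binary treatment assignment, nuisance covariates (intracranial volume, age,
clinic site, time from randomization to scan), and categorical demographics
for balance tables.  The generator plants a localized density reduction in
the treated arm (the analogue of a treatment-associated gray-matter loss)
and records everything it planted in a :class:`GroundTruth`, so detection
can be scored exactly.

The subject model for voxel v of subject s is::

    x_s(v) = baseline(v) + sum_c beta_c * (c_s - c_ref)
             + site_offset(site_s) + noise_s(v)
             - effect_size * [s treated] * [v in effect_mask]

clipped at 0.  ``baseline`` is a fixed smooth template (constant 0.5 plus
low-frequency cosine ripples), noise is white Gaussian smoothed to a stated
FWHM and rescaled to ``noise_sigma``; covariate slopes act on covariates
centered at nominal values so defaults never drive densities negative.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridGeometry, VolumeMap, save_volume

__all__ = [
    "Covariates",
    "SubjectRecord",
    "SynthConfig",
    "GroundTruth",
    "LabelAtlas",
    "DetectionScore",
    "ellipsoid_mask",
    "ball_mask",
    "generate_atlas",
    "generate_cohort",
    "generate_demographics",
    "score_detection",
    "cohort_to_frame",
    "write_cohort",
]

# nominal centering points for covariate effects (age in years, ICV in cm^3,
# time from randomization to scan in years)
_AGE_REF = 72.5
_ICV_REF = 1400.0
_TIME_REF = 2.2


@dataclass
class Covariates:
    """Per-subject nuisance covariates, arm assignment and sensitivity flags."""

    icv: float
    age: float
    site: str
    time_to_scan: float
    group: int  # 1 = treated, 0 = placebo
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.icv <= 0:
            raise ValueError("icv must be > 0")
        if self.age <= 0:
            raise ValueError("age must be > 0")
        if self.time_to_scan < 0:
            raise ValueError("time_to_scan must be >= 0")
        if self.group not in (0, 1):
            raise ValueError("group must be 0 (placebo) or 1 (treated)")


@dataclass
class SubjectRecord:
    subject_id: str
    covariates: Covariates
    volume: VolumeMap


@dataclass
class GroundTruth:
    """What the generator actually planted (for exact scoring)."""

    effect_mask: np.ndarray
    effect_size: float
    covariate_effects: dict
    site_offsets: dict


@dataclass
class LabelAtlas:
    """Synthetic anatomical parcellation: integer labels, names, sides."""

    grid: GridGeometry
    labels: np.ndarray
    names: dict
    sides: dict

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape must equal grid shape")
        for lab in np.unique(self.labels):
            if lab != 0 and int(lab) not in self.names:
                raise ValueError(f"label {lab} has no name")


@dataclass
class DetectionScore:
    sensitivity: float
    specificity: float
    dice: float


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the package's desk-scale study
    conditions (24^3 grid, ellipsoidal brain mask, 1 mm voxels)."""

    grid: GridGeometry = None
    n_per_group: int = 20
    effect_mask: np.ndarray = None
    effect_size: float = 0.1
    noise_sigma: float = 0.08
    smoothness_fwhm: float = 2.0
    covariate_effects: dict = None
    site_offsets: dict = None
    n_sites: int = 4
    seed: int = 0
    icv_mean: float = _ICV_REF
    icv_cv: float = 0.10
    flag_prob: float = 0.06

    def __post_init__(self):
        if self.grid is None:
            self.grid = GridGeometry.centered((24, 24, 24))
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.covariate_effects is None:
            self.covariate_effects = {"icv": 2e-4, "age": -4e-3, "time_to_scan": -1e-2}
        if self.site_offsets is None:
            offs = np.linspace(-0.03, 0.03, self.n_sites)
            self.site_offsets = {_site_name(i): float(o) for i, o in enumerate(offs)}
        if len(self.site_offsets) != self.n_sites:
            raise ValueError("site_offsets must have one entry per site")
        if self.effect_mask is None:
            # small ball in the anterior-left part of the mask
            center = tuple(
                int(round(s * f)) for s, f in zip(self.grid.shape, (0.38, 0.62, 0.55))
            )
            self.effect_mask = ball_mask(self.grid, center, radius_vox=3.0)
        self.effect_mask = np.asarray(self.effect_mask, dtype=bool)
        if self.effect_mask.shape != self.grid.shape:
            raise ValueError("effect_mask shape must match grid shape")


def _site_name(i: int) -> str:
    return f"S{i + 1:02d}"


def ellipsoid_mask(grid: GridGeometry, semi_frac: float = 0.42) -> np.ndarray:
    """Ellipsoidal 'brain' mask with semi-axes ``semi_frac * shape`` voxels."""
    shape = np.array(grid.shape)
    center = (shape - 1) / 2.0
    semi = np.maximum(semi_frac * shape, 1.0)
    idx = np.indices(grid.shape)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def ball_mask(grid: GridGeometry, center_vox, radius_vox: float) -> np.ndarray:
    idx = np.indices(grid.shape)
    r2 = sum((idx[a] - center_vox[a]) ** 2 for a in range(3))
    return r2 <= radius_vox**2


def _baseline_field(grid: GridGeometry) -> np.ndarray:
    """Fixed smooth template: 0.5 plus low-frequency cosine ripples."""
    shape = grid.shape
    ax = [np.arange(s) / max(s - 1, 1) for s in shape]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    f = (
        0.5
        + 0.06 * np.cos(2 * np.pi * ii + 0.7)
        + 0.05 * np.cos(2 * np.pi * jj + 1.3)
        + 0.04 * np.cos(2 * np.pi * kk + 2.1)
        + 0.03 * np.cos(2 * np.pi * (ii + jj))
    )
    return f


def _smooth_noise(rng, shape, sigma, fwhm_mm, voxel_size) -> np.ndarray:
    """White Gaussian noise smoothed to the stated FWHM, rescaled to sigma."""
    white = rng.standard_normal(shape)
    if fwhm_mm > 0:
        sig_vox = [fwhm_mm / 2.354820045 / v for v in voxel_size]
        sm = ndimage.gaussian_filter(white, sig_vox, mode="nearest")
    else:
        sm = white
    sd = sm.std()
    if sd > 0 and sigma > 0:
        sm = sm * (sigma / sd)
    elif sigma == 0:
        sm = np.zeros(shape)
    return sm


def generate_cohort(config: SynthConfig, mask: np.ndarray | None = None):
    """Generate ``2 * n_per_group`` subjects plus the ground truth.

    Returns
    -------
    (list of SubjectRecord, GroundTruth)
        Treated subjects carry ``group=1`` and a density reduction of
        ``effect_size`` inside ``effect_mask``.  Fully reproducible from
        ``config.seed``.
    """
    grid = config.grid
    if mask is None:
        mask = ellipsoid_mask(grid)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape must match grid shape")
    rng = np.random.default_rng(config.seed)
    n_total = 2 * config.n_per_group
    baseline = _baseline_field(grid)
    site_labels = sorted(config.site_offsets)

    groups = np.repeat([1, 0], config.n_per_group)
    ages = rng.uniform(65.0, 80.0, n_total)
    icvs = rng.normal(config.icv_mean, config.icv_cv * config.icv_mean, n_total)
    icvs = np.clip(icvs, 0.5 * config.icv_mean, None)
    sites = rng.choice(site_labels, n_total)
    times = rng.uniform(1.4, 3.0, n_total)
    low_3ms = rng.random(n_total) < config.flag_prob
    diabetes = rng.random(n_total) < config.flag_prob

    eff = config.covariate_effects
    records = []
    for s in range(n_total):
        shift = (
            eff.get("icv", 0.0) * (icvs[s] - _ICV_REF)
            + eff.get("age", 0.0) * (ages[s] - _AGE_REF)
            + eff.get("time_to_scan", 0.0) * (times[s] - _TIME_REF)
            + config.site_offsets[sites[s]]
        )
        vals = baseline + shift + _smooth_noise(
            rng, grid.shape, config.noise_sigma, config.smoothness_fwhm, grid.voxel_size
        )
        if groups[s] == 1 and config.effect_size != 0:
            vals = vals - config.effect_size * config.effect_mask
        vals = np.clip(vals, 0.0, None)
        cov = Covariates(
            icv=float(icvs[s]),
            age=float(ages[s]),
            site=str(sites[s]),
            time_to_scan=float(times[s]),
            group=int(groups[s]),
            flags={"low_3ms": bool(low_3ms[s]), "diabetes": bool(diabetes[s])},
        )
        records.append(
            SubjectRecord(
                subject_id=f"sub-{s + 1:04d}",
                covariates=cov,
                volume=VolumeMap(grid=grid, values=vals, mask=mask),
            )
        )
    truth = GroundTruth(
        effect_mask=config.effect_mask & mask,
        effect_size=config.effect_size,
        covariate_effects=dict(eff),
        site_offsets=dict(config.site_offsets),
    )
    return records, truth


def generate_atlas(
    grid: GridGeometry, n_regions: int, seed: int, mask: np.ndarray | None = None
) -> LabelAtlas:
    """Partition the mask into ``n_regions`` connected regions.

    Seeded region growing: ``n_regions`` random in-mask seeds grow as a
    6-connected breadth-first wavefront until the mask is exhausted, so every
    region is connected within the mask.  Side (L/R) is assigned by the sign
    of the region centroid's x coordinate relative to the grid midline.
    """
    if mask is None:
        mask = ellipsoid_mask(grid)
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_regions < 1 or n_regions > n_vox:
        raise ValueError(f"n_regions must be in [1, {n_vox}], got {n_regions}")
    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask)
    seed_idx = rng.choice(n_vox, size=n_regions, replace=False)
    labels = np.zeros(grid.shape, dtype=np.int32)
    queue = deque()
    for lab, si in enumerate(seed_idx, start=1):
        i, j, k = coords[si]
        labels[i, j, k] = lab
        queue.append((int(i), int(j), int(k)))
    nbrs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    shape = grid.shape
    while queue:
        i, j, k = queue.popleft()
        lab = labels[i, j, k]
        for di, dj, dk in nbrs:
            a, b, c = i + di, j + dj, k + dk
            if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= c < shape[2]:
                if mask[a, b, c] and labels[a, b, c] == 0:
                    labels[a, b, c] = lab
                    queue.append((a, b, c))
    # mask voxels disconnected from every seed (possible only for pathological
    # masks): attach to the nearest labeled voxel
    left = mask & (labels == 0)
    if left.any():
        lab_coords = np.argwhere(labels > 0)
        for i, j, k in np.argwhere(left):
            d2 = ((lab_coords - (i, j, k)) ** 2).sum(axis=1)
            src = lab_coords[int(np.argmin(d2))]
            labels[i, j, k] = labels[tuple(src)]
    names, sides = {}, {}
    for lab in range(1, n_regions + 1):
        vox = np.argwhere(labels == lab)
        com_x = grid.voxel_to_mm(vox.mean(axis=0))[0]
        sides[lab] = "L" if com_x < 0 else "R"
        names[lab] = f"Region {lab:02d}"
    return LabelAtlas(grid=grid, labels=labels, names=names, sides=sides)


def generate_demographics(n_per_group: int, category_probs: dict, seed: int) -> dict:
    """Multinomial per-arm counts for each categorical variable.

    Returns a map variable -> ContingencyTable (arms are columns).
    """
    from .cohort_stats import ContingencyTable

    rng = np.random.default_rng(seed)
    out = {}
    for var, probs in category_probs.items():
        probs = np.asarray(probs, dtype=float)
        if np.any(probs < 0):
            raise ValueError(f"negative probability for {var}")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"probabilities for {var} must sum to 1")
        counts = np.stack(
            [rng.multinomial(n_per_group, probs) for _ in range(2)], axis=1
        )
        out[var] = ContingencyTable(
            row_labels=[f"{var}_{i}" for i in range(len(probs))],
            col_labels=["arm1", "arm2"],
            counts=counts,
        )
    return out


def score_detection(
    detected_mask: np.ndarray, truth: GroundTruth, mask: np.ndarray
) -> DetectionScore:
    """Sensitivity / specificity / Dice of a detection against ground truth.

    Specificity is the true-negative fraction over the in-mask background
    (voxels inside the analysis mask but outside the true effect).
    """
    det = np.asarray(detected_mask, dtype=bool)
    tru = np.asarray(truth.effect_mask, dtype=bool) & mask
    if det.shape != tru.shape:
        raise ValueError("detected mask and truth must share one grid")
    n_true = int(tru.sum())
    if n_true == 0:
        raise ValueError("empty truth mask")
    det = det & mask
    tp = int((det & tru).sum())
    background = mask & ~tru
    tn = int((background & ~det).sum())
    n_det = int(det.sum())
    sens = tp / n_true
    spec = tn / max(int(background.sum()), 1)
    dice = 2 * tp / (n_det + n_true) if (n_det + n_true) > 0 else 0.0
    return DetectionScore(sensitivity=sens, specificity=spec, dice=dice)


def cohort_to_frame(cohort) -> pd.DataFrame:
    """Covariate table for a cohort (one row per subject)."""
    rows = []
    for rec in cohort:
        c = rec.covariates
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": c.group,
                "icv": c.icv,
                "age": c.age,
                "site": c.site,
                "time_to_scan": c.time_to_scan,
                "low_3ms": bool(c.flags.get("low_3ms", False)),
                "diabetes": bool(c.flags.get("diabetes", False)),
            }
        )
    return pd.DataFrame(rows)


def write_cohort(cohort, outdir, mask: np.ndarray | None = None) -> None:
    """Write one NIfTI per subject plus a covariates CSV (and the mask)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = cohort[0].volume.grid
    for rec in cohort:
        save_volume(outdir / f"{rec.subject_id}.nii.gz", rec.volume.values, grid)
    if mask is None:
        mask = cohort[0].volume.mask
    save_volume(outdir / "mask.nii.gz", mask.astype(np.float32), grid)
    cohort_to_frame(cohort).to_csv(outdir / "covariates.csv", index=False)
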