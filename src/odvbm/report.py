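"""Atlas-partitioned reporting of significant voxels.

Significant voxels are partitioned by an anatomical label atlas and each
region is reported as one row: region name, side, mm coordinates of the
center of mass, number of significant voxels N, and the two-sample t of the
per-subject mean density over the region's detected voxels (placebo minus
treated for "less" comparisons, so a deficit in the treated group gives a
positive t).  Coordinates are in the working template's mm frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridGeometry
from .synthetic import LabelAtlas

__all__ = ["RegionRow", "partition_by_atlas", "region_t", "center_of_mass", "make_report"]

_EPS = 1e-12


@dataclass
class RegionRow:
    comparison: str
    level: str  # "fwe" or "trend"
    region_name: str
    side: str
    com_xyz: tuple
    N: int
    t: float


def partition_by_atlas(sig_mask: np.ndarray, atlas: LabelAtlas) -> dict:
    """Map atlas label -> (N, 3) voxel triples of significant voxels.

    Label 0 (background) voxels are included under key 0 as unassigned;
    they are reported, never dropped.
    """
    sig_mask = np.asarray(sig_mask, dtype=bool)
    if sig_mask.shape != atlas.labels.shape:
        raise ValueError("significance mask and atlas must share one grid")
    out = {}
    for i, j, k in np.argwhere(sig_mask):
        lab = int(atlas.labels[i, j, k])
        out.setdefault(lab, []).append((i, j, k))
    return {lab: np.array(vox) for lab, vox in out.items()}


def region_t(maps, labels, detected_voxels: np.ndarray, direction: str = "less") -> float:
    """Two-sample pooled t of per-subject mean density over detected voxels.

    Signed placebo-minus-treated for ``direction="less"``.  Zero pooled
    variance is reported as t = 0.
    """
    detected_voxels = np.asarray(detected_voxels)
    if detected_voxels.size == 0:
        raise ValueError("empty voxel set")
    y = np.asarray(labels).astype(int)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("each group needs >= 2 subjects")
    idx = tuple(detected_voxels.T)
    subj_means = np.array([m.values[idx].mean() for m in maps])
    d = subj_means[y == 0].mean() - subj_means[y == 1].mean()
    ss = ((subj_means[y == 0] - subj_means[y == 0].mean()) ** 2).sum() + (
        (subj_means[y == 1] - subj_means[y == 1].mean()) ** 2
    ).sum()
    pooled = ss / (n0 + n1 - 2)
    if pooled < _EPS:
        return 0.0
    t = d / np.sqrt(pooled * (1.0 / n0 + 1.0 / n1))
    return float(t if direction == "less" else -t)


def center_of_mass(voxel_set: np.ndarray, grid: GridGeometry) -> np.ndarray:
    """Unweighted mean of member voxel centers, mapped to mm coordinates."""
    voxel_set = np.asarray(voxel_set, dtype=float)
    if voxel_set.size == 0:
        raise ValueError("empty voxel set")
    return grid.voxel_to_mm(voxel_set.mean(axis=0))


def make_report(sig_masks: dict, atlas: LabelAtlas, maps, labels,
                comparison: str = "treated < placebo",
                direction: str = "less") -> pd.DataFrame:
    """Region table for one comparison.

    Parameters
    ----------
    sig_masks : dict level -> 3D boolean
        e.g. ``{"fwe": corrected_mask, "trend": uncorrected_mask}``.

    Returns
    -------
    DataFrame with columns comparison, level, region, side, x, y, z, N, t,
    sorted by N descending within each level.  Unassigned (background)
    significant voxels appear as region "unassigned".
    """
    maps = list(maps)
    rows = []
    for level, mask3 in sig_masks.items():
        parts = partition_by_atlas(np.asarray(mask3, dtype=bool), atlas)
        level_rows = []
        for lab, vox in parts.items():
            com = center_of_mass(vox, atlas.grid)
            t = region_t(maps, labels, vox, direction=direction)
            name = atlas.names.get(lab, "unassigned") if lab != 0 else "unassigned"
            side = atlas.sides.get(lab, "-") if lab != 0 else "-"
            level_rows.append(
                {
                    "comparison": comparison, "level": level, "region": name,
                    "side": side, "x": com[0], "y": com[1], "z": com[2],
                    "N": len(vox), "t": t,
                }
            )
        level_rows.sort(key=lambda r: (-r["N"], r["region"]))
        rows.extend(level_rows)
    cols = ["comparison", "level", "region", "side", "x", "y", "z", "N", "t"]
    return pd.DataFrame(rows, columns=cols)


def format_report(report: pd.DataFrame) -> str:
    """Fixed-width text rendering of the region table."""
    if report.empty:
        header = f"{'comparison':<20} {'level':<6} {'region':<22} {'side':<4} "
        header += f"{'x':>8} {'y':>8} {'z':>8} {'N':>6} {'t':>7}"
        return header + "\n(no significant voxels)"
    lines = []
    lines.append(
        f"{'comparison':<20} {'level':<6} {'region':<22} {'side':<4} "
        f"{'x':>8} {'y':>8} {'z':>8} {'N':>6} {'t':>7}"
    )
    for _, r in report.iterrows():
        lines.append(
            f"{r.comparison:<20} {r.level:<6} {r.region:<22} {r.side:<4} "
            f"{r.x:8.2f} {r.y:8.2f} {r.z:8.2f} {r.N:6d} {r.t:7.2f}"
        )
    return "\n".join(lines)
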