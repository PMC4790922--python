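"""Conventional VBM baseline: Gaussian smoothing + voxelwise t.

The standard approach this package's adaptive filtering is benchmarked
against: smooth every subject's map with a fixed isotropic Gaussian kernel,
compute a mass-univariate two-sample t per voxel, and assign permutation
p-values with the same pooled-rank convention used for the discriminative
map (so thresholds are matched exactly).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid import stack_cohort
from .inference import PermutationScheme, PValueMap, _pooled_pvalues

__all__ = ["smooth_maps", "t_map", "smoothed_t_pvalues"]

_FWHM_TO_SIGMA = 2.354820045


def smooth_maps(maps, fwhm_mm: float) -> np.ndarray:
    """Gaussian-smooth each subject volume; returns (n, n_in_mask) matrix."""
    out = []
    mask = maps[0].mask
    for m in maps:
        sig = [fwhm_mm / _FWHM_TO_SIGMA / v for v in m.grid.voxel_size]
        sm = ndimage.gaussian_filter(m.values, sig, mode="nearest")
        out.append(sm[mask])
    return np.stack(out)


def t_map(X: np.ndarray, y: np.ndarray, direction: str = "less") -> np.ndarray:
    """Voxelwise pooled-variance two-sample t (vectorized over voxels)."""
    y = np.asarray(y).astype(int)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    m0 = X[y == 0].mean(axis=0)
    m1 = X[y == 1].mean(axis=0)
    ss = ((X[y == 0] - m0) ** 2).sum(axis=0) + ((X[y == 1] - m1) ** 2).sum(axis=0)
    pooled = ss / (n0 + n1 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m0 - m1) / np.sqrt(pooled * (1.0 / n0 + 1.0 / n1))
    t[~np.isfinite(t)] = 0.0
    return t if direction == "less" else -t


def smoothed_t_pvalues(maps, labels, fwhm_mm: float,
                       scheme: PermutationScheme | None = None) -> PValueMap:
    """Permutation voxel p-values for the smoothed voxelwise t baseline."""
    scheme = scheme or PermutationScheme()
    maps = list(maps)
    y = np.asarray(labels).astype(np.int8)
    X = smooth_maps(maps, fwhm_mm)
    obs = t_map(X, y)
    rng = np.random.default_rng(scheme.seed)
    perm = np.stack([t_map(X, rng.permutation(y)) for _ in range(scheme.n_perm)])
    pooled = np.vstack([obs[None, :], perm])
    p_flat = _pooled_pvalues(pooled, pooled.shape[0])[0]
    mask = maps[0].mask
    p3 = np.ones(mask.shape)
    p3[mask] = p_flat
    return PValueMap(grid=maps[0].grid, p=p3, n_perm=scheme.n_perm, mask=mask)
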