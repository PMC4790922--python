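"""Permutation significance and cluster-wise family-wise-error correction.

Under the null hypothesis of no group difference, the labels are
exchangeable: group assignments are randomly permuted (preserving group
sizes) and the full discriminative map is recomputed per permutation —
including re-learning every neighborhood's weights, since freezing weights
learned on the true labels would break exchangeability.  The voxel p-value
is the add-one Monte-Carlo estimator

    p_i = (1 + #{permutations with phi*_i >= phi_i}) / (n_perm + 1),

equivalently the rank of the observed value within the pool of observed +
permuted maps.  The same pooled rank rule thresholds every permuted map at
the primary (cluster-forming) level, and the permutation distribution of
the maximum suprathreshold cluster size yields cluster-wise FWE-corrected
p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import GridGeometry, stack_cohort, unstack_values
from .odvba import ODVBA, OdvbaParams, StatMap

__all__ = [
    "PermutationScheme",
    "PValueMap",
    "Cluster",
    "PermutationTest",
    "permutation_pvalues",
    "find_clusters",
    "cluster_fwe",
    "threshold_map",
]


@dataclass
class PermutationScheme:
    n_perm: int = 2000
    seed: int = 0
    relearn: bool = True
    exhaustive: bool = False
    alpha_primary: float = 0.05
    connectivity: int = 26

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 0 < self.alpha_primary < 1:
            raise ValueError("alpha_primary must be in (0, 1)")


@dataclass
class PValueMap:
    grid: GridGeometry
    p: np.ndarray  # 3D, = 1 outside mask by convention
    n_perm: int
    mask: np.ndarray


@dataclass
class Cluster:
    id: int
    voxels: np.ndarray  # (N, 3) index triples
    size: int
    corrected_p: float = np.nan


def _structure(connectivity: int):
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def find_clusters(binary: np.ndarray, connectivity: int = 26):
    """Connected components of a binary field, sorted by size descending.

    Ties are broken by the smallest flat voxel index, so cluster ids are
    deterministic.
    """
    binary = np.asarray(binary, dtype=bool)
    lab, n = ndimage.label(binary, structure=_structure(connectivity))
    clusters = []
    for k in range(1, n + 1):
        vox = np.argwhere(lab == k)
        clusters.append((len(vox), int(np.ravel_multi_index(vox[0], binary.shape)), vox))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    return [Cluster(id=i + 1, voxels=vox, size=size) for i, (size, _, vox) in enumerate(clusters)]


def cluster_fwe(observed_clusters, null_max_cluster_sizes, denominator: int | None = None):
    """Attach FWE-corrected p-values from the null max-cluster-size record.

    corrected_p = (1 + #{null max sizes >= N}) / (n_perm + 1); monotone in N.
    """
    null = np.asarray(null_max_cluster_sizes)
    if null.size == 0:
        raise ValueError("empty null distribution")
    denom = denominator if denominator is not None else len(null) + 1
    out = []
    for c in observed_clusters:
        cp = (1 + int((null >= c.size).sum())) / denom
        out.append(Cluster(id=c.id, voxels=c.voxels, size=c.size, corrected_p=min(cp, 1.0)))
    return out


def threshold_map(pmap: PValueMap, alpha: float) -> np.ndarray:
    """In-mask voxels with p strictly below alpha."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return pmap.mask & (pmap.p < alpha)


def _pooled_pvalues(pooled: np.ndarray, denom: int) -> np.ndarray:
    """Rank every entry of pooled (rows = maps) within its column.

    Returns p[j, i] = #{rows k: pooled[k, i] >= pooled[j, i]} / denom, so
    larger statistics get smaller p.  Ties count toward exceedance
    (conservative).
    """
    R, V = pooled.shape
    p = np.empty_like(pooled)
    for i in range(V):
        col = pooled[:, i]
        order = np.sort(col)
        # count >= x  ==  R - (number strictly below x)
        p[:, i] = (R - np.searchsorted(order, col, side="left")) / denom
    return p


def _all_assignments(y: np.ndarray) -> np.ndarray:
    n = len(y)
    n1 = int(y.sum())
    combos = list(itertools.combinations(range(n), n1))
    out = np.zeros((len(combos), n), dtype=np.int8)
    for r, c in enumerate(combos):
        out[r, list(c)] = 1
    return out


class PermutationTest:
    """Permutation voxel p-values and cluster-FWE for a discriminative map.

    Parameters
    ----------
    estimator : ODVBA
        Configured (unfitted is fine) map estimator; its neighborhoods and
        parameters define the statistic being permuted.
    scheme : PermutationScheme
        ``exhaustive=True`` enumerates all distinct label assignments (which
        include the observed one) and divides ranks by their count — exact
        for tiny designs.  ``relearn=False`` freezes the weights learned on
        the observed labels and only re-scores projections per permutation;
        it is an approximate fast path for smoke testing, not inference.

    Attributes (after fit)
    ----------------------
    p_map_ : PValueMap            voxel p-values (1 outside mask)
    stat_map_ : StatMap           observed tallied map
    clusters_ : list of Cluster   suprathreshold clusters with corrected_p
    null_max_sizes_ : ndarray     per-permutation max cluster size
    """

    def __init__(self, estimator: ODVBA, scheme: PermutationScheme | None = None):
        self.estimator = estimator
        self.scheme = scheme or PermutationScheme()

    def _perm_labels(self, y: np.ndarray) -> np.ndarray:
        if self.scheme.exhaustive:
            return _all_assignments(y)
        rng = np.random.default_rng(self.scheme.seed)
        P = self.scheme.n_perm
        out = np.empty((P, len(y)), dtype=np.int8)
        for p in range(P):
            out[p] = rng.permutation(y)
        return out

    def _frozen_maps(self, X: np.ndarray, perm_labels: np.ndarray) -> np.ndarray:
        """relearn=False: rescore fixed learned weights under permuted labels."""
        from scipy import sparse

        est = self.estimator
        nbs = est.neighborhoods_
        proj = np.empty((X.shape[0], len(nbs)))
        rows, cols, vals = [], [], []
        for k, nb in enumerate(nbs):
            w = self._weights[k]
            proj[:, k] = X[:, nb.member_cols] @ w
            rows.extend(nb.member_cols.tolist())
            cols.extend([k] * len(nb.member_cols))
            vals.extend(w.tolist())
        M = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(X.shape[1], len(nbs))
        )
        sign = est.params_.sign
        out = np.empty((perm_labels.shape[0], X.shape[1]))
        for p in range(perm_labels.shape[0]):
            y = perm_labels[p]
            n0, n1 = int((y == 0).sum()), int((y == 1).sum())
            m0 = proj[y == 0].mean(axis=0)
            m1 = proj[y == 1].mean(axis=0)
            ss = ((proj[y == 0] - m0) ** 2).sum(axis=0) + ((proj[y == 1] - m1) ** 2).sum(axis=0)
            pooled = ss / (n0 + n1 - 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (m0 - m1) / np.sqrt(pooled * (1.0 / n0 + 1.0 / n1))
            t[~np.isfinite(t)] = 0.0
            out[p] = M @ (sign * t)
        return out

    def fit(self, X, y):
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y).astype(np.int8)
        est = self.estimator
        est.fit(X, y)
        phi = est.phi_
        perm_labels = self._perm_labels(y)
        if self.scheme.relearn:
            perm_phi = est.permuted_maps(X, perm_labels)
        else:
            self._weights = self._learned_weights(X, y)
            perm_phi = self._frozen_maps(X, perm_labels)

        if self.scheme.exhaustive:
            pooled = perm_phi  # the observed assignment is one of the rows
            denom = pooled.shape[0]
            obs_rank = (pooled >= phi[None, :]).sum(axis=0)
            p_flat = obs_rank / denom
            pooled_p = _pooled_pvalues(pooled, denom)
            null_rows = range(pooled.shape[0])
        else:
            pooled = np.vstack([phi[None, :], perm_phi])
            denom = pooled.shape[0]  # n_perm + 1
            pooled_p = _pooled_pvalues(pooled, denom)
            p_flat = pooled_p[0]
            null_rows = range(1, pooled.shape[0])

        mask, grid = est.mask, est.grid
        p3 = np.ones(mask.shape)
        p3[mask] = p_flat
        self.p_map_ = PValueMap(grid=grid, p=p3, n_perm=perm_phi.shape[0], mask=mask)
        self.stat_map_ = est.stat_map_
        self.phi_ = phi

        alpha = self.scheme.alpha_primary
        null_max = []
        for r in null_rows:
            binary = unstack_values(pooled_p[r] < alpha, mask) > 0
            if binary.any():
                lab, n = ndimage.label(binary, structure=_structure(self.scheme.connectivity))
                sizes = ndimage.sum_labels(binary, lab, index=range(1, n + 1))
                null_max.append(int(sizes.max()))
            else:
                null_max.append(0)
        self.null_max_sizes_ = np.asarray(null_max, dtype=np.int64)

        obs_binary = threshold_map(self.p_map_, alpha)
        clusters = find_clusters(obs_binary, self.scheme.connectivity)
        self.clusters_ = cluster_fwe(clusters, self.null_max_sizes_, denominator=denom)
        return self

    def _learned_weights(self, X, y):
        from .odvba import scatter_matrices, solve_ndp

        est = self.estimator
        ws = []
        for nb in est.neighborhoods_:
            sc = scatter_matrices(X[:, nb.member_cols], y)
            ws.append(solve_ndp(sc, est.params_).weights)
        return ws

    def significant_mask(self, alpha_cluster: float = 0.05) -> np.ndarray:
        """Union of clusters with FWE-corrected p below alpha_cluster."""
        out = np.zeros(self.p_map_.mask.shape, dtype=bool)
        for c in self.clusters_:
            if c.corrected_p < alpha_cluster:
                out[tuple(c.voxels.T)] = True
        return out


def permutation_pvalues(maps, labels, params: OdvbaParams | None = None,
                        scheme: PermutationScheme | None = None):
    """Functional wrapper: cohort -> (PValueMap, null max cluster sizes)."""
    params = params or OdvbaParams()
    maps = list(maps)
    X = stack_cohort(maps)
    est = ODVBA(
        mask=maps[0].mask, grid=maps[0].grid, radius_mm=params.radius_mm,
        stride=params.stride, lam=params.lam, max_iter=params.max_iter,
        tol=params.tol, direction=params.direction,
    )
    test = PermutationTest(est, scheme).fit(X, np.asarray(labels))
    return test.p_map_, test.null_max_sizes_
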