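"""Optimally-discriminative voxel-based analysis: the statistic map.

Instead of smoothing with a fixed Gaussian kernel and running a univariate
test per voxel, the map is built from overlapping local neighborhoods.  In
each neighborhood a non-negative discriminative direction w is learned —
the unit vector w >= 0 maximizing the Fisher-style criterion

    f(w) = w' S_b w  -  lambda * w' S_w w

with rank-one between-class scatter S_b = (m0 - m1)(m0 - m1)' and pooled
within-class scatter S_w — acting as an optimal anisotropic filter that
sharpens the group difference.  A pooled-variance two-sample t statistic of
the projected values X w scores the neighborhood, and the whole-brain map
phi tallies each voxel's contribution over every neighborhood containing
it: phi_i = sum_k w_{k,i} * s_k.

The non-negativity constraint makes the learned filter a local averaging
weight (never a contrast), so high |phi| stays spatially faithful to the
group difference rather than ringing around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .grid import GridGeometry, stack_cohort, unstack_values

__all__ = [
    "OdvbaParams",
    "Neighborhood",
    "ScatterPair",
    "NDPResult",
    "StatMap",
    "ODVBA",
    "build_neighborhoods",
    "scatter_matrices",
    "solve_ndp",
    "neighborhood_statistic",
    "tally_map",
    "odvba_map",
]

_EPS = 1e-12


@dataclass
class OdvbaParams:
    """Tunables of the discriminative map.

    radius_mm : neighborhood radius (Euclidean, mm); default 2 voxels at 1 mm.
    stride : voxels between neighborhood centers along each axis.
    lam : within-class trade-off weight, or "auto" for the scale-free
        heuristic lam = trace(S_b) / max(trace(S_w), eps) per neighborhood.
    direction : "less" tests group1 < group0 (positive statistic = deficit
        in the group of interest); "greater" tests group1 > group0.
    """

    radius_mm: float = 2.0
    stride: int = 1
    lam: object = "auto"
    max_iter: int = 100
    tol: float = 1e-6
    direction: str = "less"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.direction not in ("less", "greater"):
            raise ValueError("direction must be 'less' or 'greater'")
        if self.lam != "auto" and float(self.lam) < 0:
            raise ValueError("lam must be >= 0 or 'auto'")

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "less" else -1.0


@dataclass
class Neighborhood:
    """A local voxel set: center triple plus member triples (center first)."""

    center: tuple
    members: np.ndarray  # (m, 3) voxel index triples
    member_cols: np.ndarray  # (m,) flat in-mask column indices


@dataclass
class ScatterPair:
    S_b: np.ndarray
    S_w: np.ndarray

    def __post_init__(self):
        self.S_b = np.asarray(self.S_b, dtype=float)
        self.S_w = np.asarray(self.S_w, dtype=float)
        for M in (self.S_b, self.S_w):
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError("scatter matrices must be square")
            if not np.allclose(M, M.T, atol=1e-8):
                raise ValueError("scatter matrices must be symmetric")


@dataclass
class NDPResult:
    weights: np.ndarray
    statistic: float
    objective: float
    converged: bool
    iterations: int
    degenerate: bool = False


@dataclass
class StatMap:
    grid: GridGeometry
    phi: np.ndarray
    mask: np.ndarray


def build_neighborhoods(mask: np.ndarray, grid: GridGeometry, params: OdvbaParams):
    """Euclidean-ball neighborhoods on a stride lattice of in-mask centers.

    Every in-mask voxel must be covered by at least one neighborhood and
    every neighborhood must have >= 2 members; otherwise a coverage error is
    raised (radius too small or stride too large).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vs = np.asarray(grid.voxel_size)
    # integer offsets within the mm ball
    max_off = np.floor(params.radius_mm / vs).astype(int)
    ranges = [np.arange(-m, m + 1) for m in max_off]
    oi, oj, ok = np.meshgrid(*ranges, indexing="ij")
    offs = np.stack([oi.ravel(), oj.ravel(), ok.ravel()], axis=1)
    dist = np.sqrt(((offs * vs) ** 2).sum(axis=1))
    offs = offs[dist <= params.radius_mm + 1e-9]
    if len(offs) < 2:
        raise ValueError(
            "coverage error: radius smaller than voxel size gives single-member neighborhoods"
        )

    col_of = -np.ones(mask.shape, dtype=np.int64)
    col_of[mask] = np.arange(int(mask.sum()))
    centers = np.argwhere(mask)
    if params.stride > 1:
        keep = np.all(centers % params.stride == 0, axis=1)
        centers = centers[keep]
        if len(centers) == 0:
            raise ValueError("coverage error: stride lattice misses the mask entirely")

    shape = np.asarray(mask.shape)
    covered = np.zeros(int(mask.sum()), dtype=bool)
    neighborhoods = []
    for c in centers:
        pts = c + offs
        ok_b = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok_b]
        cols = col_of[pts[:, 0], pts[:, 1], pts[:, 2]]
        inm = cols >= 0
        pts, cols = pts[inm], cols[inm]
        if len(pts) < 2:
            raise ValueError(
                "coverage error: a neighborhood has fewer than 2 in-mask members"
            )
        # center first, then scan order
        is_center = np.all(pts == c, axis=1)
        order = np.argsort(~is_center, kind="stable")
        pts, cols = pts[order], cols[order]
        covered[cols] = True
        neighborhoods.append(
            Neighborhood(center=tuple(int(x) for x in c), members=pts, member_cols=cols)
        )
    if not covered.all():
        raise ValueError(
            "coverage error: stride too large, some in-mask voxels belong to no neighborhood"
        )
    return neighborhoods


def scatter_matrices(X: np.ndarray, labels: np.ndarray) -> ScatterPair:
    """Rank-one between-class and pooled within-class scatter.

    S_b = (m0 - m1)(m0 - m1)';  S_w = sum over classes and subjects of the
    centered outer products, divided by n - 2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).astype(int)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs >= 2 subjects")
    m0 = X[y == 0].mean(axis=0)
    m1 = X[y == 1].mean(axis=0)
    d = m0 - m1
    S_b = np.outer(d, d)
    C = X.copy()
    C[y == 0] -= m0
    C[y == 1] -= m1
    S_w = C.T @ C / (len(y) - 2)
    return ScatterPair(S_b=S_b, S_w=S_w)


def _objective(A: np.ndarray, w: np.ndarray) -> float:
    return float(w @ A @ w)


def _pg_ascent(A: np.ndarray, w0: np.ndarray, max_iter: int, tol: float, step0: float):
    """Projected gradient ascent with backtracking from one start.

    Returns (w, objective, iterations, converged); the objective is
    non-decreasing over accepted iterations.
    """
    w = w0.copy()
    f_old = _objective(A, w)
    step = step0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = 2.0 * (A @ w)
        accepted = False
        f_new = f_old
        for _ in range(40):
            wt = np.clip(w + step * g, 0.0, None)
            nrm = np.linalg.norm(wt)
            if nrm < _EPS:
                break  # all-negative gradient directions: stay at w
            wt /= nrm
            f_try = _objective(A, wt)
            if f_try >= f_old:
                moved = np.abs(wt - w).sum() > 0.0
                w = wt
                f_new = f_try
                step *= 1.5
                accepted = moved
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        if f_new - f_old <= tol * max(1.0, abs(f_old)):
            f_old = f_new
            converged = True
            break
        f_old = f_new
    return w, f_old, it, converged


def solve_ndp(scatter: ScatterPair, params: OdvbaParams, lam: float | None = None) -> NDPResult:
    """Maximize w' (S_b - lam S_w) w over {w >= 0, ||w|| = 1}.

    The objective is an indefinite quadratic on the non-negative unit
    sphere, so a single ascent path can stall on an inferior face.
    Projected gradient ascent with backtracking is therefore run from a
    small deterministic set of starts — the clipped leading between-class
    direction (both signs) and the best single coordinate argmax_i f(e_i)
    — and the best stationary point is returned.  This is
    the reference implementation; the compiled kernel in ``_kernels`` runs
    the same algorithm through the centered data matrix.
    """
    S_b, S_w = scatter.S_b, scatter.S_w
    m = S_b.shape[0]
    if m < 2:
        raise ValueError("need >= 2 members")
    if lam is None:
        lam = (
            np.trace(S_b) / max(np.trace(S_w), _EPS)
            if params.lam == "auto"
            else float(params.lam)
        )
    if np.trace(S_b) < _EPS:
        # identical class means: no discriminative direction exists
        w = np.full(m, 1.0 / np.sqrt(m))
        return NDPResult(
            weights=w, statistic=0.0, objective=_objective(S_b - lam * S_w, w),
            converged=True, iterations=0, degenerate=True,
        )
    A = S_b - lam * S_w
    step0 = 0.5 / max(np.trace(S_b) + lam * np.trace(S_w), _EPS)

    starts = []
    evals, evecs = np.linalg.eigh(S_b)
    v = evecs[:, -1]
    for sgn in (1.0, -1.0):
        vc = np.clip(sgn * v, 0.0, None)
        nrm = np.linalg.norm(vc)
        if nrm > _EPS:
            starts.append(vc / nrm)
    e_best = np.zeros(m)
    e_best[int(np.argmax(np.diag(A)))] = 1.0
    starts.append(e_best)

    best = None
    total_it = 0
    for w0 in starts:
        w, f, it, conv = _pg_ascent(A, w0, params.max_iter, params.tol, step0)
        total_it += it
        if best is None or f > best[1]:
            best = (w, f, conv)
    w, f, conv = best
    return NDPResult(
        weights=w, statistic=np.nan, objective=f, converged=conv, iterations=total_it
    )


def neighborhood_statistic(X: np.ndarray, labels: np.ndarray, w: np.ndarray,
                           direction: str = "less") -> float:
    """Pooled-variance two-sample t of the projected values y = X w.

    Signed so that a positive value means the group of interest (label 1)
    has the hypothesized deficit: for direction "less" the statistic is
    t(mean0 - mean1).  Zero pooled variance maps to 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).astype(int)
    w = np.asarray(w, dtype=float)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs >= 2 subjects")
    proj = X @ w
    d = proj[y == 0].mean() - proj[y == 1].mean()
    ss = ((proj[y == 0] - proj[y == 0].mean()) ** 2).sum() + (
        (proj[y == 1] - proj[y == 1].mean()) ** 2
    ).sum()
    pooled = ss / (n0 + n1 - 2)
    if pooled < _EPS:
        return 0.0
    t = d / np.sqrt(pooled * (1.0 / n0 + 1.0 / n1))
    return float(t if direction == "less" else -t)


def tally_map(neighborhoods, ndp_results, grid: GridGeometry, mask: np.ndarray) -> StatMap:
    """phi_i = sum over neighborhoods k containing i of w_{k,i} * s_k."""
    if len(neighborhoods) != len(ndp_results):
        raise ValueError("one NDPResult per Neighborhood required")
    mask = np.asarray(mask, dtype=bool)
    flat = np.zeros(int(mask.sum()))
    for nb, res in zip(neighborhoods, ndp_results):
        np.add.at(flat, nb.member_cols, res.weights * res.statistic)
    return StatMap(grid=grid, phi=unstack_values(flat, mask), mask=mask)


class ODVBA:
    """Spatially adaptive discriminative group-comparison map (estimator).

    Parameters mirror :class:`OdvbaParams`.  ``fit(X, y)`` takes a
    subjects-by-in-mask-voxels matrix (see :func:`odvbm.grid.stack_cohort`)
    and binary labels (1 = group of interest) and exposes:

    stat_map_ : StatMap          the tallied whole-brain statistic
    phi_ : ndarray (n_voxels,)   the flat in-mask statistic vector
    neighborhoods_ : list        the neighborhood decomposition
    """

    def __init__(self, mask, grid: GridGeometry, radius_mm: float = 2.0,
                 stride: int = 1, lam="auto", max_iter: int = 100,
                 tol: float = 1e-6, direction: str = "less"):
        self.mask = np.asarray(mask, dtype=bool)
        self.grid = grid
        self.radius_mm = radius_mm
        self.stride = stride
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol
        self.direction = direction

    def get_params(self, deep=True):
        return {
            "mask": self.mask, "grid": self.grid, "radius_mm": self.radius_mm,
            "stride": self.stride, "lam": self.lam, "max_iter": self.max_iter,
            "tol": self.tol, "direction": self.direction,
        }

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    @property
    def params_(self) -> OdvbaParams:
        return OdvbaParams(
            radius_mm=self.radius_mm, stride=self.stride, lam=self.lam,
            max_iter=self.max_iter, tol=self.tol, direction=self.direction,
        )

    def _packed(self):
        if not hasattr(self, "neighborhoods_"):
            self.neighborhoods_ = build_neighborhoods(self.mask, self.grid, self.params_)
            counts = np.array([len(nb.member_cols) for nb in self.neighborhoods_],
                              dtype=np.int64)
            mmax = int(counts.max())
            members = np.zeros((len(counts), mmax), dtype=np.int64)
            for i, nb in enumerate(self.neighborhoods_):
                members[i, : counts[i]] = nb.member_cols
            self._members, self._counts = members, counts
        return self._members, self._counts

    def _kernel_args(self):
        p = self.params_
        lam_fixed = 0.0 if p.lam == "auto" else float(p.lam)
        return lam_fixed, p.lam == "auto", p.max_iter, p.tol, p.sign

    def fit(self, X, y):
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y).astype(np.int8)
        if X.shape[1] != int(self.mask.sum()):
            raise ValueError("X columns must equal in-mask voxel count")
        if int((y == 0).sum()) < 2 or int((y == 1).sum()) < 2:
            raise ValueError("each class needs >= 2 subjects")
        members, counts = self._packed()
        self.phi_ = _kernels.stat_map(X, y, members, counts, *self._kernel_args())
        self.stat_map_ = StatMap(
            grid=self.grid, phi=unstack_values(self.phi_, self.mask), mask=self.mask
        )
        return self

    def permuted_maps(self, X, perm_labels) -> np.ndarray:
        """Tallied maps for many labelings at once (rows of perm_labels)."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        perm_labels = np.ascontiguousarray(perm_labels, dtype=np.int8)
        members, counts = self._packed()
        return _kernels.perm_stat_maps(X, perm_labels, members, counts, *self._kernel_args())


def odvba_map(maps, labels, params: OdvbaParams | None = None) -> StatMap:
    """Functional wrapper: cohort of VolumeMaps + labels -> StatMap."""
    params = params or OdvbaParams()
    maps = list(maps)
    X = stack_cohort(maps)
    est = ODVBA(
        mask=maps[0].mask, grid=maps[0].grid, radius_mm=params.radius_mm,
        stride=params.stride, lam=params.lam, max_iter=params.max_iter,
        tol=params.tol, direction=params.direction,
    )
    est.fit(X, np.asarray(labels))
    return est.stat_map_
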