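"""Compiled inner loops for the discriminative map.

The whole-brain statistic requires one small non-negative quadratic
maximization per neighborhood, and permutation inference repeats the whole
map once per relabeling, so these loops are JIT-compiled with numba.  The
within-class scatter is never materialized: its quadratic form and gradient
act through the class-centered data matrix C (w' S_w w = ||C w||^2 / (n-2)),
which keeps the per-iteration cost at O(n_subjects * n_members).

The maximization is non-convex (the objective is an indefinite quadratic on
the non-negative unit sphere), so projected gradient ascent is run from a
small set of deterministic starts — the clipped between-class direction
(both signs) and the best single coordinate — and the best stationary
point is kept.  The algorithm is identical to the pure-numpy
reference solver in ``odvba.solve_ndp``; tests check the two paths against
each other and against brute force.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True, fastmath=False)
def _objective(d, C, lamn, w, m, n):
    dw = 0.0
    for j in range(m):
        dw += d[j] * w[j]
    cw2 = 0.0
    for s in range(n):
        acc = 0.0
        for j in range(m):
            acc += C[s, j] * w[j]
        acc2 = acc
        cw2 += acc2 * acc2
    return dw * dw - lamn * cw2


@njit(cache=True, fastmath=False)
def _pg_ascent(d, C, lamn, w, m, n, max_iter, tol, step0, wt, g, Cw):
    """Projected gradient ascent in place on w; returns final objective."""
    dw = 0.0
    for j in range(m):
        dw += d[j] * w[j]
    cw2 = 0.0
    for s in range(n):
        acc = 0.0
        for j in range(m):
            acc += C[s, j] * w[j]
        Cw[s] = acc
        cw2 += acc * acc
    f_old = dw * dw - lamn * cw2
    step = step0
    for _ in range(max_iter):
        for j in range(m):
            acc = 0.0
            for s in range(n):
                acc += C[s, j] * Cw[s]
            g[j] = 2.0 * (dw * d[j] - lamn * acc)
        accepted = False
        f_new = f_old
        for _bt in range(40):
            nrm2 = 0.0
            for j in range(m):
                val = w[j] + step * g[j]
                if val < 0.0:
                    val = 0.0
                wt[j] = val
                nrm2 += val * val
            if nrm2 < _EPS:
                break  # all-negative gradient directions: stay at w
            nrm = np.sqrt(nrm2)
            dw_t = 0.0
            for j in range(m):
                wt[j] /= nrm
                dw_t += d[j] * wt[j]
            cw2_t = 0.0
            for s in range(n):
                acc = 0.0
                for j in range(m):
                    acc += C[s, j] * wt[j]
                cw2_t += acc * acc
            f_try = dw_t * dw_t - lamn * cw2_t
            if f_try >= f_old:
                moved = 0.0
                for j in range(m):
                    moved += abs(wt[j] - w[j])
                    w[j] = wt[j]
                dw = dw_t
                f_new = f_try
                step *= 1.5
                accepted = moved > 0.0
                break
            step *= 0.5
        if not accepted:
            break  # stationary: no ascent step found
        # refresh Cw for the accepted iterate
        for s in range(n):
            acc = 0.0
            for j in range(m):
                acc += C[s, j] * w[j]
            Cw[s] = acc
        if f_new - f_old <= tol * max(1.0, abs(f_old)):
            f_old = f_new
            break
        f_old = f_new
    return f_old


@njit(cache=True, fastmath=False)
def _solve_best(d, C, lamn, m, n, max_iter, tol, w, wb, wt, g, Cw):
    """Multi-start NDP solve; best weights left in w, objective returned."""
    dd = 0.0
    trC2 = 0.0
    for j in range(m):
        dd += d[j] * d[j]
        for s in range(n):
            trC2 += C[s, j] * C[s, j]
    step0 = 0.5 / max(dd + lamn * trC2, _EPS)
    best_f = -1.0e300
    # starts 1-2: clipped between-class direction, both signs
    for sgn in (1.0, -1.0):
        nrm2 = 0.0
        for j in range(m):
            val = sgn * d[j]
            if val < 0.0:
                val = 0.0
            wb[j] = val
            nrm2 += val * val
        if nrm2 < _EPS:
            continue
        nrm = np.sqrt(nrm2)
        for j in range(m):
            wb[j] /= nrm
        f = _pg_ascent(d, C, lamn, wb, m, n, max_iter, tol, step0, wt, g, Cw)
        if f > best_f:
            best_f = f
            for j in range(m):
                w[j] = wb[j]
    # start 3: best single coordinate
    best_j = 0
    best_fj = -1.0e300
    for j in range(m):
        c2 = 0.0
        for s in range(n):
            c2 += C[s, j] * C[s, j]
        fj = d[j] * d[j] - lamn * c2
        if fj > best_fj:
            best_fj = fj
            best_j = j
    for j in range(m):
        wb[j] = 0.0
    wb[best_j] = 1.0
    f = _pg_ascent(d, C, lamn, wb, m, n, max_iter, tol, step0, wt, g, Cw)
    if f > best_f:
        best_f = f
        for j in range(m):
            w[j] = wb[j]
    return best_f


@njit(cache=True, fastmath=False)
def _stat_map_once(X, y, members, counts, lam_fixed, auto_lam, max_iter, tol, sign, phi):
    """Accumulate the tallied statistic map for one labeling into ``phi``."""
    n, n_vox = X.shape
    K, mmax = members.shape
    n1 = 0
    for s in range(n):
        n1 += y[s]
    n0 = n - n1
    inv_n0 = 1.0 / n0
    inv_n1 = 1.0 / n1
    dof = n - 2
    se_fac = inv_n0 + inv_n1

    C = np.empty((n, mmax))
    d = np.empty(mmax)
    w = np.empty(mmax)
    wb = np.empty(mmax)
    wt = np.empty(mmax)
    g = np.empty(mmax)
    Cw = np.empty(n)

    for v in range(n_vox):
        phi[v] = 0.0

    for k in range(K):
        m = counts[k]
        # class means and class-centered data over the member columns
        for j in range(m):
            col = members[k, j]
            m0 = 0.0
            m1 = 0.0
            for s in range(n):
                if y[s] == 1:
                    m1 += X[s, col]
                else:
                    m0 += X[s, col]
            m0 *= inv_n0
            m1 *= inv_n1
            d[j] = m0 - m1
            for s in range(n):
                if y[s] == 1:
                    C[s, j] = X[s, col] - m1
                else:
                    C[s, j] = X[s, col] - m0
        dd = 0.0
        trC2 = 0.0
        for j in range(m):
            dd += d[j] * d[j]
            for s in range(n):
                trC2 += C[s, j] * C[s, j]
        if dd < _EPS:
            continue  # identical class means: no discriminative direction, s = 0
        if auto_lam:
            lam = dd / max(trC2 / dof, _EPS)
        else:
            lam = lam_fixed
        lamn = lam / dof

        _solve_best(d, C, lamn, m, n, max_iter, tol, w, wb, wt, g, Cw)

        dw = 0.0
        for j in range(m):
            dw += d[j] * w[j]
        cw2 = 0.0
        for s in range(n):
            acc = 0.0
            for j in range(m):
                acc += C[s, j] * w[j]
            cw2 += acc * acc
        pooled = cw2 / dof
        if pooled < _EPS:
            continue  # degenerate zero-variance projection: s = 0
        t = dw / np.sqrt(pooled * se_fac)
        s_k = sign * t
        for j in range(m):
            phi[members[k, j]] += w[j] * s_k


@njit(cache=True)
def stat_map(X, y, members, counts, lam_fixed, auto_lam, max_iter, tol, sign):
    n_vox = X.shape[1]
    phi = np.empty(n_vox)
    _stat_map_once(X, y, members, counts, lam_fixed, auto_lam, max_iter, tol, sign, phi)
    return phi


@njit(cache=True)
def perm_stat_maps(X, perm_labels, members, counts, lam_fixed, auto_lam, max_iter, tol, sign):
    """One tallied map per row of ``perm_labels``; rows are label vectors."""
    P = perm_labels.shape[0]
    n_vox = X.shape[1]
    out = np.empty((P, n_vox))
    for p in range(P):
        _stat_map_once(
            X, perm_labels[p], members, counts, lam_fixed, auto_lam, max_iter, tol, sign, out[p]
        )
    return out
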