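"""Compiled Nelder-Mead kernel and grid scans for the curve objectives.

The bootstrap refits every resampled curve to all three models; a study-size
run touches ~10^5 optimizations, so the simplex search and the t(4)
objective live in numba-compiled kernels. The algorithm is the standard
Nelder-Mead simplex (reflection 1, expansion 2, contraction 0.5, shrink
0.5) with a scipy-style initial simplex; scipy.optimize's own Nelder-Mead
serves as an independent cross-check in the test suite.

Constraint boxes are enforced by penalty: outside the box (or violating the
gnls gap la - ga > 0.25) the objective returns 1e10 plus the distance to
the feasible set, so the best simplex vertex is always feasible while
estimates are free to land on the boundary itself.

Parameter vector layouts (model codes): 0 = cnst ``[er]``; 1 = hill
``[tp, ga, gw, er]``; 2 = gnls ``[tp, ga, gw, la, lw, er]``. ``er`` is the
log error scale.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG_T4_NORM = math.log(0.375)
PENALTY = 1e10
EXP_CAP = 300.0

CNST, HILL, GNLS = 0, 1, 2


@njit(cache=True)
def _mu_at(model, p, xi):
    if model == CNST:
        return 0.0
    tp = p[0]
    eg = (p[1] - xi) * p[2]
    if eg > EXP_CAP:
        eg = EXP_CAP
    elif eg < -EXP_CAP:
        eg = -EXP_CAP
    val = tp / (1.0 + 10.0 ** eg)
    if model == GNLS:
        el = (xi - p[3]) * p[4]
        if el > EXP_CAP:
            el = EXP_CAP
        elif el < -EXP_CAP:
            el = -EXP_CAP
        val = val / (1.0 + 10.0 ** el)
    return val


@njit(cache=True)
def neg_loglik(model, p, x, y):
    """Negative t(4) log-likelihood of the model at parameters p."""
    er = p[p.shape[0] - 1]
    s = math.exp(er)
    total = 0.0
    for i in range(x.shape[0]):
        z = (y[i] - _mu_at(model, p, x[i])) / s
        total += LOG_T4_NORM - 2.5 * math.log1p(0.25 * z * z) - er
    return -total


@njit(cache=True)
def penalized_objective(model, p, x, y, lb, ub):
    """neg_loglik inside the box; PENALTY + distance-to-box outside."""
    pen = 0.0
    for j in range(p.shape[0]):
        if p[j] < lb[j]:
            pen += lb[j] - p[j]
        elif p[j] > ub[j]:
            pen += p[j] - ub[j]
    if model == GNLS:
        gap = p[3] - p[1]
        if gap <= 0.25:
            pen += 0.25 - gap + 1e-12
    if pen > 0.0:
        return PENALTY + pen
    f = neg_loglik(model, p, x, y)
    if not math.isfinite(f):
        return PENALTY
    return f


@njit(cache=True)
def group_medians(resp, inverse, n_groups):
    """Median replicate response per concentration group.

    ``inverse`` maps each measurement to its (sorted) group index.
    """
    counts = np.zeros(n_groups, dtype=np.int64)
    for i in range(inverse.shape[0]):
        counts[inverse[i]] += 1
    offs = np.zeros(n_groups + 1, dtype=np.int64)
    for g in range(n_groups):
        offs[g + 1] = offs[g] + counts[g]
    buf = np.empty(inverse.shape[0])
    fill = offs[:-1].copy()
    for i in range(inverse.shape[0]):
        g = inverse[i]
        buf[fill[g]] = resp[i]
        fill[g] += 1
    out = np.empty(n_groups)
    for g in range(n_groups):
        seg = np.sort(buf[offs[g]:offs[g + 1]])
        m = seg.shape[0]
        if m % 2 == 1:
            out[g] = seg[m // 2]
        else:
            out[g] = 0.5 * (seg[m // 2 - 1] + seg[m // 2])
    return out


@njit(cache=True)
def _sort_simplex(sim, fsim, n):
    # insertion sort by fsim with row swaps; simplex is nearly sorted
    for k in range(1, n + 1):
        fk = fsim[k]
        m = k
        while m > 0 and fsim[m - 1] > fk:
            m -= 1
        if m != k:
            for j in range(n):
                tmp = sim[k, j]
                for i in range(k, m, -1):
                    sim[i, j] = sim[i - 1, j]
                sim[m, j] = tmp
            for i in range(k, m, -1):
                fsim[i] = fsim[i - 1]
            fsim[m] = fk


@njit(cache=True)
def nelder_mead(model, x0, x, y, lb, ub, maxfev, xatol, fatol):
    """Minimize the penalized objective from x0; returns (p, f, nfev, conv)."""
    n = x0.shape[0]
    sim = np.empty((n + 1, n))
    fsim = np.empty(n + 1)
    sim[0, :] = x0
    for k in range(n):
        for j in range(n):
            sim[k + 1, j] = x0[j]
        step = 0.05 * abs(x0[k])
        if step == 0.0:
            step = 0.00025
        if x0[k] + step > ub[k] and x0[k] - step >= lb[k]:
            step = -step
        sim[k + 1, k] = x0[k] + step
    nfev = 0
    for k in range(n + 1):
        fsim[k] = penalized_objective(model, sim[k], x, y, lb, ub)
        nfev += 1
    _sort_simplex(sim, fsim, n)

    centroid = np.empty(n)
    cand = np.empty(n)
    converged = False
    while nfev < maxfev:
        # termination: simplex collapsed in x and f
        xspread = 0.0
        fspread = 0.0
        for k in range(1, n + 1):
            d = abs(fsim[k] - fsim[0])
            if d > fspread:
                fspread = d
            for j in range(n):
                d = abs(sim[k, j] - sim[0, j])
                if d > xspread:
                    xspread = d
        if xspread <= xatol and fspread <= fatol:
            converged = True
            break

        for j in range(n):
            c = 0.0
            for k in range(n):
                c += sim[k, j]
            centroid[j] = c / n

        # reflection
        for j in range(n):
            cand[j] = 2.0 * centroid[j] - sim[n, j]
        fr = penalized_objective(model, cand, x, y, lb, ub)
        nfev += 1
        accepted = False
        if fr < fsim[0]:
            fnew = fr
            for j in range(n):
                sim[n, j] = cand[j]
            # expansion: step twice as far as the accepted reflection
            for j in range(n):
                cand[j] = centroid[j] + 2.0 * (sim[n, j] - centroid[j])
            fe = penalized_objective(model, cand, x, y, lb, ub)
            nfev += 1
            if fe < fr:
                fnew = fe
                for j in range(n):
                    sim[n, j] = cand[j]
            fsim[n] = fnew
            accepted = True
        elif fr < fsim[n - 1]:
            for j in range(n):
                sim[n, j] = cand[j]
            fsim[n] = fr
            accepted = True
        else:
            # contraction (outside toward xr if it improved on the worst)
            if fr < fsim[n]:
                for j in range(n):
                    cand[j] = centroid[j] + 0.5 * (cand[j] - centroid[j])
            else:
                for j in range(n):
                    cand[j] = centroid[j] + 0.5 * (sim[n, j] - centroid[j])
            fc = penalized_objective(model, cand, x, y, lb, ub)
            nfev += 1
            if fc < min(fr, fsim[n]):
                for j in range(n):
                    sim[n, j] = cand[j]
                fsim[n] = fc
                accepted = True
        if accepted:
            _sort_simplex(sim, fsim, n)
        else:
            # shrink toward the best vertex
            for k in range(1, n + 1):
                for j in range(n):
                    sim[k, j] = sim[0, j] + 0.5 * (sim[k, j] - sim[0, j])
                fsim[k] = penalized_objective(model, sim[k], x, y, lb, ub)
                nfev += 1
            _sort_simplex(sim, fsim, n)

    return sim[0].copy(), fsim[0], nfev, converged


@njit(cache=True)
def grid_best(model, x, y, grids_flat, grid_sizes):
    """Best (lowest) feasible neg_loglik over a full factorial grid.

    ``grids_flat`` concatenates the per-dimension grids; ``grid_sizes``
    gives each dimension's length, in parameter-vector order. Infeasible
    gnls combinations (la - ga <= 0.25) are skipped.
    """
    d = grid_sizes.shape[0]
    offs = np.zeros(d, dtype=np.int64)
    for j in range(1, d):
        offs[j] = offs[j - 1] + grid_sizes[j - 1]
    total = 1
    for j in range(d):
        total *= grid_sizes[j]
    p = np.empty(d)
    best = np.inf
    best_p = np.empty(d)
    for flat in range(total):
        rem = flat
        for j in range(d - 1, -1, -1):
            idx = rem % grid_sizes[j]
            rem //= grid_sizes[j]
            p[j] = grids_flat[offs[j] + idx]
        if model == GNLS and p[3] - p[1] <= 0.25:
            continue
        f = neg_loglik(model, p, x, y)
        if f < best:
            best = f
            for j in range(d):
                best_p[j] = p[j]
    return best, best_p
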