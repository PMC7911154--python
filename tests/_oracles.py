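"""Independent brute-force oracles for the test suite.

Everything here is written with plain nested loops (no vectorization, no
reuse of package internals) so that agreement with the package is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import math

import numpy as np

DIRS13 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
]


def _in(shape, x):
    return all(0 <= xi < si for xi, si in zip(x, shape))


# -- GLCM --------------------------------------------------------------------

def oracle_glcm(levels, mask, g, distance=1, directions=DIRS13):
    """Symmetric normalized co-occurrence matrix by exhaustive voxel loops."""
    shape = levels.shape
    counts = np.zeros((g, g))
    for x in np.ndindex(shape):
        if not mask[x]:
            continue
        for d in directions:
            for sgn in (1, -1):
                y = tuple(xi + sgn * distance * di for xi, di in zip(x, d))
                if _in(shape, y) and mask[y]:
                    counts[levels[x] - 1, levels[y] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def oracle_glcm_features(p):
    g = p.shape[0]
    mu = 0.0
    for i in range(g):
        for j in range(g):
            mu += (i + 1) * p[i, j]
    var = 0.0
    for i in range(g):
        for j in range(g):
            var += (i + 1 - mu) ** 2 * p[i, j]
    homog = energy = contrast = entropy = dissim = cov = 0.0
    for i in range(g):
        for j in range(g):
            v = p[i, j]
            homog += v / (1 + abs(i - j))
            energy += v * v
            contrast += v * (i - j) ** 2
            dissim += v * abs(i - j)
            cov += (i + 1 - mu) * (j + 1 - mu) * v
            if v > 0:
                entropy -= v * math.log2(v)
    return {
        "glcm_homogeneity": homog,
        "glcm_energy": energy,
        "glcm_contrast": contrast,
        "glcm_correlation": cov / var if var > 0 else 0.0,
        "glcm_entropy": entropy,
        "glcm_dissimilarity": dissim,
        "glcm_variance": var,
    }


# -- GLRLM -------------------------------------------------------------------

def oracle_glrlm(levels, mask, g, directions=DIRS13):
    """Run counts by walking every voxel along every direction."""
    shape = levels.shape
    runs = {}
    maxlen = 1
    for d in directions:
        for x in np.ndindex(shape):
            if not mask[x]:
                continue
            prev = tuple(xi - di for xi, di in zip(x, d))
            if _in(shape, prev) and mask[prev] and levels[prev] == levels[x]:
                continue  # not a run start
            length = 1
            y = tuple(xi + di for xi, di in zip(x, d))
            while _in(shape, y) and mask[y] and levels[y] == levels[x]:
                length += 1
                y = tuple(yi + di for yi, di in zip(y, d))
            runs[(levels[x], length)] = runs.get((levels[x], length), 0) + 1
            maxlen = max(maxlen, length)
    m = np.zeros((g, maxlen))
    for (lev, length), c in runs.items():
        m[lev - 1, length - 1] = c
    return m


def oracle_rl_features(m, n_runs, n_voxels, n_dirs):
    g, lmax = m.shape
    sre = lre = lgre = hgre = srlge = srhge = lrlge = lrhge = 0.0
    for i in range(g):
        for l in range(lmax):
            v = m[i, l]
            ii, ll = (i + 1) ** 2, (l + 1) ** 2
            sre += v / ll
            lre += v * ll
            lgre += v / ii
            hgre += v * ii
            srlge += v / (ii * ll)
            srhge += v * ii / ll
            lrlge += v * ll / ii
            lrhge += v * ii * ll
    glnu = sum(m[i, :].sum() ** 2 for i in range(g))
    rlnu = sum(m[:, l].sum() ** 2 for l in range(lmax))
    n = n_runs
    return {
        "glrlm_sre": sre / n,
        "glrlm_lre": lre / n,
        "glrlm_lgre": lgre / n,
        "glrlm_hgre": hgre / n,
        "glrlm_srlge": srlge / n,
        "glrlm_srhge": srhge / n,
        "glrlm_lrlge": lrlge / n,
        "glrlm_lrhge": lrhge / n,
        "glrlm_glnur": glnu / n,
        "glrlm_rlnu": rlnu / n,
        "glrlm_rp": n / (n_voxels * n_dirs),
    }


# -- NGLDM -------------------------------------------------------------------

def oracle_ngldm_features(levels, mask, g):
    shape = levels.shape
    n_i = [0.0] * g
    s_i = [0.0] * g
    for x in np.ndindex(shape):
        if not mask[x]:
            continue
        nbrs = []
        for d in DIRS13:
            for sgn in (1, -1):
                y = tuple(xi + sgn * di for xi, di in zip(x, d))
                if _in(shape, y) and mask[y]:
                    nbrs.append(levels[y])
        if not nbrs:
            continue
        a = sum(nbrs) / len(nbrs)
        i = levels[x]
        n_i[i - 1] += 1
        s_i[i - 1] += abs(i - a)
    n_total = sum(n_i)
    p_i = [ni / n_total for ni in n_i]
    ps = sum(p * s for p, s in zip(p_i, s_i))
    coarseness = 1.0 / ps if ps > 0 else 0.0
    occupied = [i for i in range(g) if p_i[i] > 0]
    ng = len(occupied)
    if ng > 1:
        acc = 0.0
        for i in range(g):
            for j in range(g):
                acc += p_i[i] * p_i[j] * (i - j) ** 2
        contrast = acc / (ng * (ng - 1)) * (sum(s_i) / n_total)
    else:
        contrast = 0.0
    denom = 0.0
    for i in occupied:
        for j in occupied:
            denom += abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
    busyness = ps / denom if denom > 0 else 0.0
    return {
        "ngldm_coarseness": coarseness,
        "ngldm_contrast": contrast,
        "ngldm_busyness": busyness,
    }


# -- GLZLM -------------------------------------------------------------------

def oracle_glzlm(levels, mask, g):
    """Zone counts by explicit flood fill over the 26-neighborhood."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = {}
    zmax = 1
    for x in np.ndindex(shape):
        if not mask[x] or seen[x]:
            continue
        lev = levels[x]
        stack = [x]
        seen[x] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in DIRS13:
                for sgn in (1, -1):
                    y = tuple(ci + sgn * di for ci, di in zip(cur, d))
                    if _in(shape, y) and mask[y] and not seen[y] and levels[y] == lev:
                        seen[y] = True
                        stack.append(y)
        zones[(lev, size)] = zones.get((lev, size), 0) + 1
        zmax = max(zmax, size)
    m = np.zeros((g, zmax))
    for (lev, size), c in zones.items():
        m[lev - 1, size - 1] = c
    return m


def oracle_zone_features(m, n_zones, n_voxels):
    rl = oracle_rl_features(m, n_zones, 1, 1)  # reuse the emphasis sums
    return {
        "glzlm_sze": rl["glrlm_sre"],
        "glzlm_lze": rl["glrlm_lre"],
        "glzlm_lgze": rl["glrlm_lgre"],
        "glzlm_hgze": rl["glrlm_hgre"],
        "glzlm_szlge": rl["glrlm_srlge"],
        "glzlm_szhge": rl["glrlm_srhge"],
        "glzlm_lzlge": rl["glrlm_lrlge"],
        "glzlm_lzhge": rl["glrlm_lrhge"],
        "glzlm_glnuz": rl["glrlm_glnur"],
        "glzlm_zlnu": rl["glrlm_rlnu"],
        "glzlm_zp": n_zones / n_voxels,
    }


# -- histogram ---------------------------------------------------------------

def oracle_histogram_features(levels, mask, g):
    vals = [levels[x] for x in np.ndindex(levels.shape) if mask[x]]
    n = len(vals)
    mu = sum(vals) / n
    m2 = sum((v - mu) ** 2 for v in vals) / n
    if m2 > 0:
        skew = sum((v - mu) ** 3 for v in vals) / n / m2**1.5
        kurt = sum((v - mu) ** 4 for v in vals) / n / m2**2
    else:
        skew = kurt = 0.0
    p = [0.0] * g
    for v in vals:
        p[v - 1] += 1 / n
    entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0)
    energy = sum(pi * pi for pi in p)
    return {
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_entropy": entropy,
        "hist_energy": energy,
    }


# -- survival ----------------------------------------------------------------

def product_limit(times, events):
    """Hand Kaplan–Meier: returns dict event_time -> S(t)."""
    order = sorted(set(t for t, e in zip(times, events) if e))
    s = 1.0
    out = {}
    for t in order:
        at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ei and ti == t)
        s *= 1 - d / at_risk
        out[t] = s
    return out


def cox_partial_loglik(beta, times, events, x):
    """Efron partial log-likelihood for one covariate (ties by Efron)."""
    ll = 0.0
    for t in sorted(set(t for t, e in zip(times, events) if e)):
        dead = [i for i, (ti, ei) in enumerate(zip(times, events)) if ei and ti == t]
        risk_sum = sum(math.exp(beta * xj) for tj, xj in zip(times, x) if tj >= t)
        tied_sum = sum(math.exp(beta * x[i]) for i in dead)
        d = len(dead)
        for i in dead:
            ll += beta * x[i]
        for l in range(d):
            ll -= math.log(risk_sum - (l / d) * tied_sum)
    return ll


def cox_grid_mle(times, events, x, lo=-4.0, hi=4.0, step=1e-4):
    """Grid-search maximizer of the hand-written partial likelihood."""
    grid = np.arange(lo, hi + step, step)
    lls = [cox_partial_loglik(b, times, events, x) for b in grid]
    return float(grid[int(np.argmax(lls))])


def logrank_chi2_two_group(times, events, group):
    """Hand log-rank: observed minus expected in group 1, variance-normalized."""
    event_times = sorted(set(t for t, e in zip(times, events) if e))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n = sum(1 for ti in times if ti >= t)
        n1 = sum(1 for ti, gi in zip(times, group) if ti >= t and gi == 1)
        d = sum(1 for ti, ei in zip(times, events) if ei and ti == t)
        d1 = sum(1 for ti, ei, gi in zip(times, events, group) if ei and ti == t and gi == 1)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
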