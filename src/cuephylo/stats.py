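"""Auxiliary statistics: repeated-measures correlation and Hartigan's dip test.

Both are self-contained implementations.

*Repeated-measures correlation* measures the common within-subject
association between two repeatedly measured variables: an ANCOVA with a
subject factor and a common slope, equivalent to the Pearson correlation of
within-subject-centred values with N - k - 1 degrees of freedom (k
subjects).

*Hartigan's dip* is the smallest sup-norm distance between the empirical
CDF and the class of unimodal CDFs (convex up to a mode, concave after).
The implementation computes, for every candidate placement of the mode, the
minimal distance at which a convex prefix fit, a concave suffix fit, and a
monotone junction between them coexist, and binary-searches that distance;
p-values come from Monte-Carlo simulation of the uniform null.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps

try:  # numba makes the dip O(n^2) inner loops fast; plain Python still works
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "rmcorr",
    "RmcorrResult",
    "dip_statistic",
    "hartigan_dip",
    "null_dip_distribution",
    "dip_pvalue",
    "DipResult",
]


# ---------------------------------------------------------------------------
# Repeated-measures correlation

@dataclasses.dataclass
class RmcorrResult:
    r: float
    df: int
    p: float
    n_subjects: int
    n_obs: int


def rmcorr(x, y, subject_labels) -> RmcorrResult:
    """Repeated-measures correlation of paired observations within subjects.

    Centres x and y within each subject (removing between-subject
    differences) and correlates the residual within-subject variation with
    a common slope.  With a single subject this reduces exactly to the
    Pearson correlation with N - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subj = np.asarray(subject_labels)
    if not (len(x) == len(y) == len(subj)):
        raise ValueError("x, y and subject_labels must have equal length")
    uniq, inv = np.unique(subj, return_inverse=True)
    k = len(uniq)
    n = len(x)
    counts = np.bincount(inv)
    if np.any(counts < 2):
        raise ValueError("every subject needs >= 2 paired observations")
    xm = np.bincount(inv, weights=x) / counts
    ym = np.bincount(inv, weights=y) / counts
    xc = x - xm[inv]
    yc = y - ym[inv]
    ssx = float(xc @ xc)
    if ssx <= 0:
        raise ValueError("x is constant within every subject")
    ssy = float(yc @ yc)
    if ssy <= 0:
        raise ValueError("y is constant within every subject")
    r = float(xc @ yc) / np.sqrt(ssx * ssy)
    df = n - 2 if k == 1 else n - k - 1
    if df < 1:
        raise ValueError("not enough observations for the residual df")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return RmcorrResult(r=r, df=df, p=p, n_subjects=k, n_obs=n)


# ---------------------------------------------------------------------------
# Hartigan's dip
#
# Working representation: unique sorted values u_1..u_m with ECDF levels
# L_j (left limit, below the jump at u_j) and U_j (value at u_j).  A
# unimodal CDF G within sup-distance d of the ECDF must satisfy, at every
# data point, U_j - d <= G(u_j) and G(u_j) <= L_j + d (a jump of G is
# allowed only at the mode).  G is convex before the mode and concave
# after.  For a fixed assignment of points to the convex/concave regions,
# feasibility at distance d decomposes into:
#   * convex-side feasibility: the greatest convex minorant of the lower
#     corners (u_j, L_j) must stay within 2d below the upper corners;
#   * the mirrored condition on the concave side;
#   * a junction condition: some feasible convex branch value at the last
#     convex point must not exceed some feasible concave branch value at
#     the first concave point (G is nondecreasing).
# The dip is the smallest d for which any mode placement is feasible,
# located by bisection (feasibility is monotone in d).


@njit(cache=False)
def _prefix_devs(u, L, Uv):
    """Max deviation of upper corners above the GCM of lower corners, for
    every prefix.

    Returns (A, Aex): A[j] is the deviation for prefix 0..j; Aex[j]
    excludes point j's own upper-corner requirement (used when a jump of G
    at u_j absorbs it).  Convex-side feasibility at distance d is A <= 2d.
    """
    m = len(u)
    A = np.zeros(m)
    Aex = np.zeros(m)
    stack = np.zeros(m, dtype=np.int64)
    top = -1
    running = 0.0
    for j in range(m):
        while top >= 1:
            i1 = stack[top - 1]
            i2 = stack[top]
            if (L[i2] - L[i1]) * (u[j] - u[i2]) >= (L[j] - L[i2]) * (u[i2] - u[i1]):
                top -= 1
            else:
                break
        if top >= 0:
            s = stack[top]
            denom = u[j] - u[s]
            for i in range(s + 1, j):
                gi = L[s] + (L[j] - L[s]) * (u[i] - u[s]) / denom
                dv = Uv[i] - gi
                if dv > running:
                    running = dv
        Aex[j] = running
        dj = Uv[j] - L[j]
        if dj > running:
            running = dj
        A[j] = running
        top += 1
        stack[top] = j
    return A, Aex


@njit(cache=False)
def _gmin(u, L, Uv, k, d, point_mode):
    """Smallest value at u_k attainable by a feasible convex branch.

    The branch must stay above U_j - d (or L_k - d at a jump mode) and
    below L_j + d at every prefix point; convexity propagates any forced
    rise between an upper anchor (u_i, L_i + d) and a lower requirement
    (u_j, lo_j) out to u_k.
    """
    if point_mode:
        best = L[k] - d
    else:
        best = Uv[k] - d
    for j in range(k + 1):
        if point_mode and j == k:
            lo_j = L[j] - d
        else:
            lo_j = Uv[j] - d
        s = 0.0
        for i in range(j):
            sl = (lo_j - (L[i] + d)) / (u[j] - u[i])
            if sl > s:
                s = sl
        val = lo_j + s * (u[k] - u[j])
        if val > best:
            best = val
    return best


@njit(cache=False)
def _feasible(u, L, Uv, um, Lm, Um, A, Aex, B, Bex, d):
    """Can some unimodal CDF stay within sup-distance d of the ECDF?

    (um, Lm, Um, B, Bex) are the mirrored arrays encoding the concave
    (suffix) side as a convex problem.
    """
    m = len(u)
    two_d = 2.0 * d
    # Mode in the open gap after index k (k = -1: everything concave;
    # k = m-1: everything convex).
    for k in range(-1, m):
        if k >= 0 and A[k] > two_d:
            continue
        if k < m - 1 and B[m - 2 - k] > two_d:
            continue
        if k < 0 or k == m - 1:
            return True
        if Uv[k + 1] - L[k] >= two_d:
            return True
        gmin = _gmin(u, L, Uv, k, d, False)
        hmax = 1.0 - _gmin(um, Lm, Um, m - 2 - k, d, False)
        if gmin <= hmax:
            return True
    # Mode at a data point, with a jump of G allowed there.
    for j in range(m):
        if Aex[j] > two_d or Bex[m - 1 - j] > two_d:
            continue
        gmin = _gmin(u, L, Uv, j, d, True)
        hmax = 1.0 - _gmin(um, Lm, Um, m - 1 - j, d, True)
        if gmin <= hmax:
            return True
    return False


@njit(cache=False)
def _dip_from_levels(u, L, Uv):
    m = len(u)
    if m == 1:
        return 0.0
    um = -u[::-1].copy()
    Lm = 1.0 - Uv[::-1].copy()
    Um = 1.0 - L[::-1].copy()
    A, Aex = _prefix_devs(u, L, Uv)
    B, Bex = _prefix_devs(um, Lm, Um)
    lo = 0.0
    hi = 0.5
    while not _feasible(u, L, Uv, um, Lm, Um, A, Aex, B, Bex, hi):
        hi *= 2.0  # pragma: no cover - 0.5 is always feasible
        if hi > 2.0:
            return np.nan
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _feasible(u, L, Uv, um, Lm, Um, A, Aex, B, Bex, mid):
            hi = mid
        else:
            lo = mid
    return hi


def dip_statistic(sample) -> float:
    """Hartigan's dip: sup-distance from the ECDF to the nearest unimodal CDF.

    For n distinct observations the dip is at least 1/(2n); large values
    indicate the ECDF cannot be matched by any distribution with a single
    mode.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("dip test needs a 1-d sample with n >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in sample")
    u, counts = np.unique(x, return_counts=True)
    n = len(x)
    cum = np.cumsum(counts)
    Uv = cum / n
    L = (cum - counts) / n
    return float(_dip_from_levels(u, L, Uv))


def null_dip_distribution(
    n: int, n_null: int = 2000, seed: int | None = None
) -> np.ndarray:
    """Dip statistics of ``n_null`` uniform(0, 1) samples of size ``n``.

    The uniform distribution is the conventional (asymptotically least
    favourable) unimodal null; the returned array can be shared across
    tests of the same sample size.
    """
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_null)])


def dip_pvalue(dip: float, null_dips: np.ndarray) -> float:
    """Fraction of null samples with dip >= the observed dip."""
    null_dips = np.asarray(null_dips)
    return float(np.mean(null_dips >= dip - 1e-12))


@dataclasses.dataclass
class DipResult:
    dip: float
    p: float
    n_null: int


def hartigan_dip(sample, n_null: int = 2000, seed: int | None = None) -> DipResult:
    """Dip statistic with a Monte-Carlo p-value against the uniform null."""
    d = dip_statistic(sample)
    null = null_dip_distribution(len(np.asarray(sample)), n_null=n_null, seed=seed)
    return DipResult(dip=d, p=dip_pvalue(d, null), n_null=n_null)
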