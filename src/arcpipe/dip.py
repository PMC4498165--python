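"""Hartigan's dip statistic of unimodality, with bootstrap p-values.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (convex below the mode, concave above, with an
optional jump at the mode).  It is computed here directly from that
definition: for a candidate distance ``d``, a unimodal CDF within ``d`` of
the ECDF everywhere exists iff, for some mode position, a convex
nondecreasing function threads the per-point bands left of the mode and a
concave one threads them right of it.  Band feasibility for the convex side
is an exact hull condition (the lower convex hull of the band upper bounds
must clear every band lower bound), checked in a single left-to-right pass;
the concave side is its mirror image.  Feasibility is monotone in ``d``, so
the dip is found by bisection to near machine precision.

p-values come from a bootstrap against the uniform reference distribution
(the asymptotically least-favorable unimodal null), as is standard for this
test.  The feasibility kernel is JIT-compiled when numba is importable;
the pure-Python path computes identical results.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

_BISECT_TOL = 1e-10
_EPS = 1e-15


def _prefix_flags(x: np.ndarray, upper: np.ndarray, lower: np.ndarray,
                  flags: np.ndarray) -> None:
    """Convex-side feasibility flags (written into ``flags``).

    flags[k] is True iff a convex nondecreasing function exists passing
    <= upper[i] at every x[i], i <= k, and >= lower[i] at every *interior*
    point i < k (the point at k itself is the prospective mode, whose
    lower band is relaxed).  The maximal such function is the lower convex
    hull of the points (x[i], upper[i]); feasibility fails the first time
    an interior band is empty or a hull chord dips below an interior lower
    bound, and stays failed (the hull only moves down while constraints
    accumulate), so one monotone-chain pass suffices.
    """
    n = x.size
    hull = np.empty(n, dtype=np.int64)
    top = 0
    ok = True
    for j in range(n):
        if ok and j >= 1:
            # point j-1 is now interior: its band must be nonempty (if it
            # is still a hull vertex the hull sits exactly at upper[j-1])
            ok = lower[j - 1] <= upper[j - 1] + _EPS
        if ok:
            while top >= 2:
                a = hull[top - 2]
                b = hull[top - 1]
                # slope(a,b) >= slope(b,j)  ->  b is not a hull vertex
                if ((upper[b] - upper[a]) * (x[j] - x[b])
                        >= (upper[j] - upper[b]) * (x[b] - x[a])):
                    top -= 1
                else:
                    break
            if top >= 1:
                s = hull[top - 1]
                # the chord s -> j replaces the hull over (s, j): every
                # interior lower bound must stay below it
                if j - s > 1:
                    slope = (upper[j] - upper[s]) / (x[j] - x[s])
                    for i in range(s + 1, j):
                        if lower[i] > upper[s] + slope * (x[i] - x[s]) + _EPS:
                            ok = False
                            break
            hull[top] = j
            top += 1
        flags[j] = ok


def _feasible(x: np.ndarray, c0: np.ndarray, c1: np.ndarray,
              n: float, d: float) -> bool:
    """Does a unimodal CDF exist within sup-distance d of the ECDF?

    x holds the unique sample values; c0[i]/n and c1[i]/n are the ECDF
    left and right limits at x[i].  Continuity at a non-mode point x[i]
    confines the CDF there to [c1[i]/n - d, c0[i]/n + d]; a jump at the
    mode decouples the convex and concave sides.
    """
    m = x.size
    upper = c0 / n + d
    lower = c1 / n - d
    conv = np.empty(m, dtype=np.bool_)
    conc = np.empty(m, dtype=np.bool_)
    _prefix_flags(x, upper, lower, conv)
    # concave side: reflect the axis; concave-above-lowers becomes
    # convex-below-uppers for the reflected points
    _prefix_flags(-x[::-1], (-lower)[::-1].copy(), (-upper)[::-1].copy(), conc)
    conc = conc[::-1]
    # mode at a sample point: convex side through k (relaxed lower there),
    # concave side from k (relaxed upper there)
    for k in range(m):
        if conv[k] and conc[k]:
            return True
    # mode strictly between x[k] and x[k+1]: standard bands at both ends,
    # which additionally requires those bands to be nonempty
    for k in range(m - 1):
        if (conv[k] and conc[k + 1]
                and lower[k] <= upper[k] + _EPS
                and lower[k + 1] <= upper[k + 1] + _EPS):
            return True
    return False


try:  # optional JIT; semantics identical on the pure-Python path
    from numba import njit

    _prefix_flags = njit(cache=True)(_prefix_flags)
    _feasible = njit(cache=True)(_feasible)
except ImportError:  # pragma: no cover
    pass


def dip_statistic(sample: np.ndarray) -> float:
    """Hartigan's dip of a 1-d sample (0 for degenerate samples)."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2 or x[-1] == x[0]:
        return 0.0
    ux, counts = np.unique(x, return_counts=True)
    c1 = np.cumsum(counts).astype(float)       # ECDF right counts
    c0 = c1 - counts                           # ECDF left counts
    lo, hi = 0.0, 0.25
    if _feasible(ux, c0, c1, float(n), lo):
        return 0.0
    while hi - lo > _BISECT_TOL:
        mid = 0.5 * (lo + hi)
        if _feasible(ux, c0, c1, float(n), mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


_NULL_CACHE: dict = {}


def dip_null_distribution(n: int, n_boot: int = 2000,
                          seed: int = 0) -> np.ndarray:
    """Bootstrap dips of uniform samples of size n (cached per (n, B, seed)).

    The uniform is the asymptotically least-favorable unimodal null, so its
    dip distribution (which depends only on n) is the standard reference.
    """
    key = (n, n_boot, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        _NULL_CACHE[key] = np.sort(
            [dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)]
        )
    return _NULL_CACHE[key]


def dip_test(sample: np.ndarray, n_boot: int = 2000,
             seed: int = 0) -> Tuple[float, float]:
    """Dip statistic and bootstrap p-value against the uniform reference.

    Small p rejects unimodality.
    """
    sample = np.asarray(sample, dtype=float)
    stat = dip_statistic(sample)
    null = dip_null_distribution(sample.size, n_boot, seed)
    n_ge = null.size - np.searchsorted(null, stat, side="left")
    p = (n_ge + 1) / (null.size + 1)
    return stat, float(p)
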