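"""Exact small-sample oracle for the dip statistic via linear programming.

The dip is the smallest t for which some unimodal CDF G stays within t of
the empirical CDF.  For each candidate mode position (at a data point, with
a possible atom there, or strictly between two points) the constraint set on
G's values at the data points is linear: convex second differences left of
the mode, concave right of it, monotonicity, and the sup-norm band
|G(x_i) - i/n| <= t, |G(x_i^-) - (i-1)/n| <= t.  Minimising t per candidate
and taking the overall minimum gives the dip exactly.  O(n) LPs of O(n)
variables: usable for n up to ~15, entirely independent of the hull-based
production algorithm.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _solve_mode_candidate(xu, cu, cl, n, mode_at_point, j):
    """Min t for one mode candidate.

    xu: unique sorted values; cu[i]/n = F(xu[i]); cl[i]/n = F(xu[i]^-).
    mode_at_point: if True, mode sits at xu[j] with a possible atom there
    (an extra variable h = G(xu[j]^-)); otherwise the mode lies strictly
    between xu[j] and xu[j+1] (j = -1: before all points; j = m-1: after).
    """
    m = len(xu)
    # variables: g_0..g_{m-1}, [h], t
    nh = 1 if mode_at_point else 0
    nv = m + nh + 1
    it = nv - 1
    ih = m  # index of h when present
    A, b = [], []

    def ineq(coeffs, rhs=0.0):
        row = np.zeros(nv)
        for k, v in coeffs:
            row[k] += v
        A.append(row)
        b.append(rhs)

    # band constraints: |g_i - cu_i/n| <= t and |g_i - cl_i/n| <= t
    for i in range(m):
        hi_t, lo_t = cu[i] / n, cl[i] / n
        if mode_at_point and i == j:
            # left limit handled by h; g_j compared to the upper value only
            ineq([(i, 1.0), (it, -1.0)], hi_t)
            ineq([(i, -1.0), (it, -1.0)], -hi_t)
            ineq([(ih, 1.0), (it, -1.0)], lo_t)
            ineq([(ih, -1.0), (it, -1.0)], -lo_t)
        else:
            ineq([(i, 1.0), (it, -1.0)], hi_t)
            ineq([(i, -1.0), (it, -1.0)], -hi_t)
            ineq([(i, 1.0), (it, -1.0)], lo_t)
            ineq([(i, -1.0), (it, -1.0)], -lo_t)

    # monotone nondecreasing (h slots between g_{j-1} and g_j)
    for i in range(m - 1):
        ineq([(i, 1.0), (i + 1, -1.0)])
    if mode_at_point:
        if j >= 1:
            ineq([(j - 1, 1.0), (ih, -1.0)])
        ineq([(ih, 1.0), (j, -1.0)])

    # convexity left of the mode / concavity right of it, cross-multiplied
    if mode_at_point:
        left = [(xu[i], i) for i in range(j)] + [(xu[j], ih)]
        right = [(xu[i], i) for i in range(j, m)]
    else:
        left = [(xu[i], i) for i in range(j + 1)]
        right = [(xu[i], i) for i in range(j + 1, m)]
    for pts, sign in ((left, 1.0), (right, -1.0)):
        for k in range(1, len(pts) - 1):
            (x0, i0), (x1, i1), (x2, i2) = pts[k - 1], pts[k], pts[k + 1]
            d01, d12 = x1 - x0, x2 - x1
            # sign * [ (g2 - g1) * d01 - (g1 - g0) * d12 ] >= 0
            ineq(
                [(i2, -sign * d01), (i1, sign * (d01 + d12)), (i0, -sign * d12)]
            )

    bounds = [(0.0, 1.0)] * (m + nh) + [(0.0, None)]
    c = np.zeros(nv)
    c[it] = 1.0
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds, method="highs")
    return res.fun if res.success else np.inf


def dip_lp(scores) -> float:
    """Exact dip of a small sample by LP over all mode candidates."""
    x = np.sort(np.asarray(scores, dtype=float))
    n = x.size
    if n <= 1 or x[0] == x[-1]:
        return 0.0
    xu, first = np.unique(x, return_index=True)
    m = len(xu)
    counts = np.diff(np.append(first, n))
    cu = np.cumsum(counts)  # F * n at each unique point
    cl = cu - counts  # left limits * n
    best = np.inf
    for j in range(m):
        best = min(best, _solve_mode_candidate(xu, cu, cl, n, True, j))
    for j in range(-1, m):
        best = min(best, _solve_mode_candidate(xu, cu, cl, n, False, j))
    return float(best)
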