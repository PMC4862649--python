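"""Brute-force reference for the dip statistic.

Computes the exact dip by linear programming over piecewise-linear
unimodal CDFs: the candidate CDF has knots at the data points, one
possible jump at the mode, nondecreasing values and a slope sequence that
rises then falls (convex-then-concave).  Minimising the sup-distance to
the empirical CDF over all mode positions gives the dip exactly.

Deliberately independent of the fast greatest-convex-minorant /
least-concave-majorant implementation in :mod:`scaaverage.ensemble`; this
module exists so the fast path can be validated against first principles.
Complexity is O(m) linear programs of O(m) variables for m distinct
values — fine for validation, far too slow for bootstrap use.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

__all__ = ["dip_lp_oracle"]


def dip_lp_oracle(sample: np.ndarray) -> float:
    """Exact dip statistic by exhaustive LP (no 1/(2n) floor applied)."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    v, counts = np.unique(x, return_counts=True)
    c = np.cumsum(counts) / n
    m = v.size
    if m == 1:
        return 0.0  # a point mass is itself unimodal
    cprev = np.r_[0.0, c[:-1]]
    best = np.inf
    for j in range(m):  # mode (and possible CDF jump) at knot j
        # variables: [y_0..y_{m-1}, yl, d]; y_j is the value just after the
        # jump, yl the left limit just before it
        nv = m + 2
        yl, d = m, m + 1
        A, b = [], []

        def row():
            return np.zeros(nv)

        for i in range(m):
            r = row(); r[i] = -1; r[d] = -1          # y_i >= c_i - d
            A.append(r); b.append(-c[i])
            if i != j:
                r = row(); r[i] = 1; r[d] = -1       # y_i <= cprev_i + d
                A.append(r); b.append(cprev[i])
        r = row(); r[yl] = 1; r[d] = -1              # yl <= cprev_j + d
        A.append(r); b.append(cprev[j])
        r = row(); r[yl] = -1; r[d] = -1             # yl >= cprev_j - d
        A.append(r); b.append(-cprev[j])

        order = list(range(j)) + [yl, j] + list(range(j + 1, m))
        for a_i, b_i in zip(order[:-1], order[1:]):  # monotone
            r = row(); r[a_i] = 1; r[b_i] = -1
            A.append(r); b.append(0.0)

        pre_vals = list(range(j)) + [yl]             # convex up to the mode
        pre_x = v[: j + 1]
        for t in range(len(pre_vals) - 2):
            h1 = pre_x[t + 1] - pre_x[t]
            h2 = pre_x[t + 2] - pre_x[t + 1]
            r = row()
            r[pre_vals[t]] = -1.0 / h1
            r[pre_vals[t + 1]] = 1.0 / h1 + 1.0 / h2
            r[pre_vals[t + 2]] = -1.0 / h2
            A.append(r); b.append(0.0)
        post_vals = [j] + list(range(j + 1, m))      # concave after it
        post_x = v[j:]
        for t in range(len(post_vals) - 2):
            h1 = post_x[t + 1] - post_x[t]
            h2 = post_x[t + 2] - post_x[t + 1]
            r = row()
            r[post_vals[t]] = 1.0 / h1
            r[post_vals[t + 1]] = -1.0 / h1 - 1.0 / h2
            r[post_vals[t + 2]] = 1.0 / h2
            A.append(r); b.append(0.0)

        cost = np.zeros(nv); cost[d] = 1.0
        res = linprog(cost, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0, 1)] * (m + 1) + [(0, None)], method="highs")
        if res.success:
            best = min(best, float(res.fun))
    return best
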