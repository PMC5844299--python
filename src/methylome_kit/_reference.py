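"""Exact, slow reference computations used to validate the fast paths.

These are deliberately independent of the production implementations:
the dip oracle searches the space of unimodal CDFs directly (small
linear programs over piecewise-linear candidates, with the mode swept
over a refined grid), the binomial tail is summed term by term, and the
BH reference applies the step-up rule literally.  They exist for
verification on small inputs only and are not part of the analysis API.
"""

from __future__ import annotations

from itertools import groupby
from math import comb

import numpy as np
from scipy.optimize import linprog, minimize_scalar

__all__ = [
    "dip_oracle",
    "binom_upper_tail",
    "bh_stepup_reference",
    "hypergeom_upper_tail",
]


def dip_oracle(values, grid: int = 13) -> float:
    """Dip by direct minimisation of sup |F_n - U| over unimodal CDFs U.

    A unimodal CDF is convex up to its mode and concave after it; an atom
    (jump) is permitted at the mode.  For a sample with unique sorted
    values v_1 < ... < v_G the minimising U can be taken piecewise linear
    with knots at the v's plus the mode itself, so the problem "minimise
    d subject to U within d of F_n everywhere, monotone, convex then
    concave" becomes a linear program once the mode position is fixed:

    * mode at a data value (with jump): knot values on each branch are
      the only variables;
    * mode strictly inside a gap: two extra variables carry the CDF
      value just before and just after the mode, coupled to the adjacent
      branch slopes (the convex branch must reach the mode with a slope
      no smaller than its last inter-knot slope, and the concave branch
      must leave it with a slope no smaller than its next one).

    The mode position inside each gap is swept over a grid and refined
    with bounded scalar minimisation.  The dip is the smallest optimum
    over all configurations, floored at 1/(2n) by convention.  Intended
    for small n; the validation suites use n <= 8.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        return 0.0
    groups = []
    idx = 1
    for val, run in groupby(x):
        k = len(list(run))
        groups.append((float(val), idx, idx + k - 1))
        idx += k
    G = len(groups)
    floor = 1.0 / (2.0 * n)
    if G == 1:
        return floor

    best = np.inf
    # mode exactly at each data value, with a jump allowed there
    for t in range(G):
        d = _knot_mode_lp(groups, n, t)
        if d is not None and d < best:
            best = d
    # all-convex / all-concave candidates (mode beyond the data range)
    for left in (0, G):
        d = _knot_mode_lp(groups, n, None, left=left)
        if d is not None and d < best:
            best = d
    # mode strictly inside each interior gap
    for g in range(1, G):
        x_l, x_r = groups[g - 1][0], groups[g][0]
        span = x_r - x_l
        eps = span * 1e-9

        def dval(m, _g=g):
            d = _gap_mode_lp(groups, n, _g, m)
            return np.inf if d is None else d

        ms = np.linspace(x_l + eps, x_r - eps, grid)
        vals = np.array([dval(m) for m in ms])
        order = np.argsort(vals)
        for k in order[:2]:
            lo = ms[max(k - 1, 0)]
            hi = ms[min(k + 1, grid - 1)]
            res = minimize_scalar(
                dval, bounds=(lo, hi), method="bounded",
                options={"xatol": span * 1e-12},
            )
            cand = min(vals[k], float(res.fun))
            if cand < best:
                best = cand
    return max(best, floor)


class _LP:
    """Tiny helper collecting sum(c_j x_j) <= rhs rows."""

    def __init__(self, nv):
        self.nv = nv
        self.rows = []
        self.rhs = []

    def le(self, coefs, rhs):
        row = np.zeros(self.nv)
        for j, c in coefs.items():
            row[j] = c
        self.rows.append(row)
        self.rhs.append(rhs)

    def solve(self, i_d, value_bounds):
        c = np.zeros(self.nv)
        c[i_d] = 1.0
        bounds = [value_bounds] * (self.nv - 1) + [(0.0, 0.5)]
        res = linprog(
            c, A_ub=np.array(self.rows), b_ub=np.array(self.rhs),
            bounds=bounds, method="highs",
            options={
                "primal_feasibility_tolerance": 1e-10,
                "dual_feasibility_tolerance": 1e-10,
            },
        )
        return float(res.x[i_d]) if res.success else None


def _band(lp, var, i_d, n, group, side):
    """Band constraints tying one knot value to the ECDF within d."""
    _, i1, j1 = group
    if side in ("both", "upper"):
        lp.le({var: 1.0, i_d: -1.0}, (i1 - 1) / n)   # <= left plateau + d
    if side in ("both", "lower"):
        lp.le({var: -1.0, i_d: -1.0}, -j1 / n)       # >= right plateau - d


def _shape(lp, vars_, xs, convex):
    """Monotonicity and slope ordering along one branch."""
    for r in range(len(vars_) - 1):
        lp.le({vars_[r]: 1.0, vars_[r + 1]: -1.0}, 0.0)
    for r in range(len(vars_) - 2):
        h1 = xs[r + 1] - xs[r]
        h2 = xs[r + 2] - xs[r + 1]
        if convex:  # slopes nondecreasing
            lp.le({vars_[r]: -h2, vars_[r + 1]: h2 + h1, vars_[r + 2]: -h1}, 0.0)
        else:       # slopes nonincreasing
            lp.le({vars_[r]: h2, vars_[r + 1]: -(h2 + h1), vars_[r + 2]: h1}, 0.0)


def _knot_mode_lp(groups, n, at_value, left=None):
    """Mode at data value ``at_value`` (jump allowed), or pure one-branch fit."""
    G = len(groups)
    if at_value is not None:
        conv = list(range(at_value + 1))
        conc = list(range(at_value, G))
    else:
        conv = list(range(left))
        conc = list(range(left, G))
    p, q = len(conv), len(conc)
    nv = p + q + 1
    i_d = nv - 1
    lp = _LP(nv)
    for r, gi in enumerate(conv):
        shared = at_value is not None and gi == at_value
        _band(lp, r, i_d, n, groups[gi], "upper" if shared else "both")
    for r, gi in enumerate(conc):
        shared = at_value is not None and gi == at_value
        _band(lp, p + r, i_d, n, groups[gi], "lower" if shared else "both")
    _shape(lp, list(range(p)), [groups[gi][0] for gi in conv], convex=True)
    _shape(lp, [p + r for r in range(q)], [groups[gi][0] for gi in conc], convex=False)
    if p and q:
        lp.le({p - 1: 1.0, p: -1.0}, 0.0)  # junction: left limit <= right value
    return lp.solve(i_d, (0.0, 1.0))


def _gap_mode_lp(groups, n, g, m):
    """Mode at position m strictly inside the gap between groups g-1 and g."""
    G = len(groups)
    conv = list(range(g))      # knot variables 0..p-1
    conc = list(range(g, G))   # knot variables p..p+q-1
    p, q = len(conv), len(conc)
    i_a, i_b = p + q, p + q + 1   # U(m^-), U(m)
    nv = p + q + 3
    i_d = nv - 1
    lp = _LP(nv)
    for r, gi in enumerate(conv):
        _band(lp, r, i_d, n, groups[gi], "both")
    for r, gi in enumerate(conc):
        _band(lp, p + r, i_d, n, groups[gi], "both")
    _shape(lp, list(range(p)), [groups[gi][0] for gi in conv], convex=True)
    _shape(lp, [p + r for r in range(q)], [groups[gi][0] for gi in conc], convex=False)

    c_flat = groups[g - 1][2] / n      # ECDF plateau inside the gap
    x_l = groups[g - 1][0]
    x_r = groups[g][0]
    lp.le({i_a: 1.0, i_d: -1.0}, c_flat)       # a <= c + d
    lp.le({i_b: -1.0, i_d: -1.0}, -c_flat)     # b >= c - d
    lp.le({i_a: 1.0, i_b: -1.0}, 0.0)          # a <= b (jump up only)
    # convex branch reaches the mode with slope >= its last inter-knot slope
    lp.le({i_a: -1.0, p - 1: 1.0}, 0.0)        # a >= A_L
    if p >= 2:
        x_prev = groups[g - 2][0]
        h_last = x_l - x_prev
        h_mode = m - x_l
        # (a - A_L)/h_mode >= (A_L - A_prev)/h_last
        lp.le({i_a: -h_last, p - 1: h_last + h_mode, p - 2: -h_mode}, 0.0)
    # concave branch leaves the mode with slope >= its next inter-knot slope
    lp.le({i_b: 1.0, p: -1.0}, 0.0)            # b <= B_R
    if q >= 2:
        x_next = groups[g + 1][0]
        h_next = x_next - x_r
        h_mode = x_r - m
        # (B_R - b)/h_mode >= (B_next - B_R)/h_next
        lp.le({i_b: h_next, p: -(h_next + h_mode), p + 1: h_mode}, 0.0)
    return lp.solve(i_d, (0.0, 1.0))


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P[X >= k] for X ~ Binomial(n, p), by literal summation."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    total = 0.0
    for j in range(k, n + 1):
        total += comb(n, j) * p**j * (1.0 - p) ** (n - j)
    return min(total, 1.0)


def bh_stepup_reference(pvalues) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up, for cross-checking bh_adjust."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        val = p[order[rank - 1]] * m / rank
        running = min(running, val)
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def hypergeom_upper_tail(a: int, row1: int, col1: int, total: int) -> float:
    """P[X >= a] for X ~ Hypergeom(total, col1, row1), by summation.

    Matches the one-sided ('greater') Fisher exact p for the 2x2 table
    with first-row total row1, first-column total col1 and grand total.
    """
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    denom = comb(total, col1)
    tail = 0.0
    for k in range(max(a, lo), hi + 1):
        tail += comb(row1, k) * comb(total - row1, col1 - k) / denom
    return min(tail, 1.0)
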