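"""Independent reference implementations used as test oracles.

These are deliberately simple, list-and-loop implementations kept separate
from the package code paths they validate.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Optional, Tuple

import numpy as np


class _RefSeg:
    """One split hypothesis: straight-line fit, optionally through a point."""

    def __init__(self, split: int, constraint: Optional[Tuple[float, float, float]],
                 base: float, parent_chain: Tuple[int, ...]):
        self.split = split
        self.constraint = constraint
        self.base = base
        self.chain = parent_chain
        self.ts: List[float] = []
        self.xs: List[float] = []
        self.ys: List[float] = []

    def add(self, t, x, y):
        self.ts.append(t)
        self.xs.append(x)
        self.ys.append(y)

    def _axis_fit(self, vals, t0, v0):
        u = [t - t0 for t in self.ts]
        v = [w - v0 for w in vals]
        suu = sum(a * a for a in u)
        suv = sum(a * b for a, b in zip(u, v))
        svv = sum(b * b for b in v)
        if self.constraint is None:
            n = len(u)
            su = sum(u)
            sv = sum(v)
            sxx = suu - su * su / n
            sxy = suv - su * sv / n
            syy = svv - sv * sv / n
            if sxx <= 0:
                return 0.0, syy, sv / n, su / n
            b = sxy / sxx
            return b, max(syy - b * sxy, 0.0), sv / n, su / n
        if suu <= 0:
            return 0.0, svv, None, None
        b = suv / suu
        return b, max(svv - b * suv, 0.0), None, None

    def sse(self):
        if self.constraint is None:
            t0, x0, y0 = self.ts[0], self.xs[0], self.ys[0]
        else:
            t0, x0, y0 = self.constraint
        _, sx, _, _ = self._axis_fit(self.xs, t0, x0)
        _, sy, _, _ = self._axis_fit(self.ys, t0, y0)
        return sx + sy

    def objective(self, sigma):
        return self.base - self.sse() / (2.0 * sigma * sigma)

    def predict(self, tq):
        if self.constraint is None:
            t0, x0, y0 = self.ts[0], self.xs[0], self.ys[0]
            out = []
            for vals, v0 in ((self.xs, x0), (self.ys, y0)):
                b, _, vbar, ubar = self._axis_fit(vals, t0, v0)
                out.append(v0 + vbar + b * ((tq - t0) - ubar))
            return out[0], out[1]
        t0, x0, y0 = self.constraint
        bx, _, _, _ = self._axis_fit(self.xs, t0, x0)
        by, _, _, _ = self._axis_fit(self.ys, t0, y0)
        return x0 + bx * (tq - t0), y0 + by * (tq - t0)


def unpruned_greedy_dp(t, x, y, sigma, penalty, min_seg=2):
    """Unpruned O(n²) greedy-continuity dynamic program.

    Same likelihood and spawn rule as the package's forward pass, but every
    hypothesis is kept alive.  Returns (breakpoints, objective).
    """
    n = len(t)
    hyps = [_RefSeg(0, None, 0.0, (0,))]
    for i in range(n):
        if i > 0:
            best = None
            best_obj = -math.inf
            for h in hyps:
                if i - h.split >= min_seg:
                    o = h.objective(sigma)
                    if o > best_obj or (o == best_obj and best is not None and h.split > best.split):
                        best_obj = o
                        best = h
            if best is not None:
                px, py = best.predict(t[i])
                hyps.append(_RefSeg(i, (t[i], px, py), best_obj - penalty,
                                    best.chain + (i,)))
        for h in hyps:
            h.add(t[i], x[i], y[i])
    eligible = [h for h in hyps if n - h.split >= min_seg] or hyps
    best = None
    best_obj = -math.inf
    for h in eligible:
        o = h.objective(sigma)
        if o > best_obj or (o == best_obj and best is not None and h.split > best.split):
            best_obj = o
            best = h
    return np.array(best.chain, dtype=np.int64), best_obj


def constrained_ls_piecewise(t, vals, node_times):
    """Continuous piecewise-linear least squares via a dense KKT system.

    Parameterizes each segment as (intercept at the left knot, slope) and
    imposes equality of adjacent segments at interior knots with Lagrange
    multipliers.  Independent of the package's hat-basis banded solver.
    Returns the fitted node values.
    """
    t = np.asarray(t, float)
    vals = np.asarray(vals, float)
    m = len(node_times) - 1
    # design: columns [c_0, b_0, c_1, b_1, ...]
    seg = np.clip(np.searchsorted(node_times, t, side="right") - 1, 0, m - 1)
    A = np.zeros((len(t), 2 * m))
    for i, (ti, j) in enumerate(zip(t, seg)):
        A[i, 2 * j] = 1.0
        A[i, 2 * j + 1] = ti - node_times[j]
    # constraints: c_j + b_j (tau_{j+1} - tau_j) = c_{j+1}
    C = np.zeros((m - 1, 2 * m))
    for j in range(m - 1):
        C[j, 2 * j] = 1.0
        C[j, 2 * j + 1] = node_times[j + 1] - node_times[j]
        C[j, 2 * (j + 1)] = -1.0
    K = np.zeros((2 * m + m - 1, 2 * m + m - 1))
    K[: 2 * m, : 2 * m] = 2 * A.T @ A
    K[: 2 * m, 2 * m:] = C.T
    K[2 * m:, : 2 * m] = C
    rhs = np.zeros(2 * m + m - 1)
    rhs[: 2 * m] = 2 * A.T @ vals
    sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
    node_vals = np.empty(m + 1)
    for j in range(m):
        node_vals[j] = sol[2 * j]
    node_vals[m] = sol[2 * (m - 1)] + sol[2 * (m - 1) + 1] * (node_times[m] - node_times[m - 1])
    return node_vals


def brute_force_viterbi(features, model):
    """Exhaustive max-likelihood state sequence over all k^m paths."""
    logB = model.emission_logpdf(np.asarray(features, float))
    with np.errstate(divide="ignore"):
        logT = np.log(model.transitions)
        logpi = np.log(model.initial)
    m, k = logB.shape
    best_path, best_score = None, -math.inf
    for path in itertools.product(range(k), repeat=m):
        s = logpi[path[0]] + logB[0, path[0]]
        for i in range(1, m):
            s += logT[path[i - 1], path[i]] + logB[i, path[i]]
        if s > best_score:
            best_score = s
            best_path = path
    return [model.classes[i] for i in best_path], best_score
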