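"""Piecewise-linear gaze denoising and segmentation.

The signal model: gaze position is a continuous piecewise-linear function
of time, observed under i.i.d. per-axis Gaussian noise of standard
deviation σ.  Events (fixations, saccades, pursuits, post-saccadic
oscillations) correspond to the linear pieces.

The search is a forward dynamic program over split hypotheses in the style
of pruned exact changepoint search (PELT).  Each live hypothesis holds the
start index of its current segment, the point the segment is forced to pass
through, O(1)-updatable regression sufficient statistics per axis, and a
cumulative objective

    objective = −Σ SSE_axis / (2σ²) − penalty × (number of splits),

i.e. the Gaussian log-likelihood up to constants shared by all hypotheses
at equal sample count.  Continuity is enforced *greedily*: a new segment is
constrained to start at the current best hypothesis's predicted value at
the split time, which keeps the subproblems independent (optimal
substructure).  Hypotheses whose objective falls more than a fixed slack
(``PRUNE_MARGIN``) below the newly spawned hypothesis's are pruned.  The
slack is needed because the continuity constraint breaks the cost
subadditivity that makes slack-free pruning exact for unconstrained
segment costs: a trailing hypothesis whose line the future data rejoins
can recover a bounded amount of objective.  With the default slack the
pruned pass reproduces the unpruned dynamic program exactly on extensive
randomized checks while staying empirically linear in n.
After the forward pass, the breakpoints are kept and the node values are
re-estimated by an exact continuous least-squares fit (linear spline / hat
basis, banded normal equations), which removes the greedy approximation
from the reconstruction.

σ can be estimated automatically by fixed-point iteration: start from the
signal's own standard deviation, segment, use the residual standard
deviation as the next estimate, stop when an estimate repeats.  A constant
"structural error" (default 0.1°) is added to the final estimate to absorb
correlated noise and micro-movements irrelevant to macro events.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy.linalg import solveh_banded

from .io import GazeTrace

try:  # pragma: no cover
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

#: default structural error added to the automatic noise estimate [deg]
DEFAULT_STRUCTURAL_ERROR = 0.1
#: pruning slack in log-likelihood units (see module docstring)
PRUNE_MARGIN = 100.0
#: bounded-memory cap on live hypotheses; binds only when a grossly
#: over-estimated sigma flattens the objective so the slack stops pruning
MAX_HYPOTHESES = 500
#: scenario assumed when no hint is available for automatic penalty lookup
DEFAULT_SCENARIO = (10.0, 1.0, 5.0)  # a* [deg], d* [s], v* [deg/s]


@dataclass
class SegmentationConfig:
    """Parameters of the segmentation.

    sigma : float or "auto"
        Assumed per-axis noise std [deg]; "auto" estimates it iteratively.
    structural_error : float
        Constant added to the automatic noise estimate [deg].  Ignored when
        ``sigma`` is numeric (a numeric sigma is taken as the total).
    structural_combine : "add" or "quadrature"
        How the structural error combines with the estimate.
    penalty : float or "auto"
        Split penalty in log-likelihood units; "auto" looks it up from the
        shipped calibration table using ``scenario_hint`` (or the default
        scenario) and the trace's sampling rate.
    scenario_hint : (a_star, d_star, v_star) or None
        Eye-movement scenario characteristics for the penalty lookup.
    min_segment_samples : int
        Minimum samples per segment, >= 2.
    """

    sigma: Union[float, str] = "auto"
    structural_error: float = DEFAULT_STRUCTURAL_ERROR
    structural_combine: str = "add"
    penalty: Union[float, str] = "auto"
    scenario_hint: Optional[Tuple[float, float, float]] = None
    min_segment_samples: int = 2
    noise_max_iter: int = 50
    noise_round_decimals: int = 6

    def __post_init__(self) -> None:
        if isinstance(self.sigma, str):
            if self.sigma != "auto":
                raise ValueError("sigma must be a positive number or 'auto'")
        elif self.sigma <= 0:
            raise ValueError("numeric sigma must be > 0")
        if isinstance(self.penalty, str):
            if self.penalty != "auto":
                raise ValueError("penalty must be a positive number or 'auto'")
        elif self.penalty <= 0:
            raise ValueError("numeric penalty must be > 0")
        if self.min_segment_samples < 2:
            raise ValueError("min_segment_samples must be >= 2")
        if self.structural_combine not in ("add", "quadrature"):
            raise ValueError("structural_combine must be 'add' or 'quadrature'")


@dataclass
class Segmentation:
    """A continuous piecewise-linear reconstruction of a gaze trace.

    Segments are half-open sample ranges ``[breakpoints[j], breakpoints[j+1])``
    (the breakpoint sample belongs to the following segment); the last
    segment ends at ``n_samples``.  ``node_times``/``node_values`` are the
    knots of the continuous reconstruction: node ``j`` is shared exactly by
    segments ``j-1`` and ``j``.
    """

    breakpoints: np.ndarray          # segment start indices, breakpoints[0] == 0
    node_times: np.ndarray           # shape (m+1,)
    node_values: np.ndarray          # shape (m+1, 2)
    n_samples: int
    sigma_used: float = math.nan
    penalty_used: float = math.nan
    objective: float = math.nan

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints)

    def reconstruct(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the reconstruction at times ``t``; returns (n, 2)."""
        t = np.asarray(t, dtype=float)
        out = np.empty((len(t), 2))
        for a in range(2):
            out[:, a] = np.interp(t, self.node_times, self.node_values[:, a])
        return out

    def segment_of_samples(self) -> np.ndarray:
        """Segment index of every sample (half-open convention)."""
        idx = np.searchsorted(self.breakpoints, np.arange(self.n_samples), side="right") - 1
        return idx

    def segment_displacements(self) -> np.ndarray:
        """(m, 2) displacement vector of each segment [deg]."""
        return np.diff(self.node_values, axis=0)

    def segment_durations(self) -> np.ndarray:
        return np.diff(self.node_times)

    def segment_speeds(self) -> np.ndarray:
        """Mean speed of each segment [deg/s]."""
        disp = self.segment_displacements()
        return np.hypot(disp[:, 0], disp[:, 1]) / self.segment_durations()


# ---------------------------------------------------------------------------
# regression through a fixed point: O(1) sufficient statistics
# ---------------------------------------------------------------------------


class ConstrainedFit:
    """Incremental straight-line regression through a fixed point.

    Model per axis: ``v(t) = v0 + b (t − t0)`` with ``(t0, v0)`` the
    constraint.  Internally accumulates the shifted sums Σu², Σuv, Σv²
    (u = t − t0, v = value − v0), from which the optimal slope
    ``b = Σuv/Σu²`` and the minimized ``SSE = Σv² − b Σuv`` follow in
    closed form.  Used directly by tests and small-scale callers; the
    forward pass uses the same arithmetic inside a compiled kernel.
    """

    __slots__ = ("t0", "v0", "suu", "suv", "svv", "n")

    def __init__(self, t0: float, v0: float):
        self.t0 = float(t0)
        self.v0 = float(v0)
        self.suu = self.suv = self.svv = 0.0
        self.n = 0

    def update(self, t: float, v: float) -> None:
        u = t - self.t0
        w = v - self.v0
        self.suu += u * u
        self.suv += u * w
        self.svv += w * w
        self.n += 1

    def eval(self) -> Tuple[float, float]:
        """Return ``(slope, SSE)``; slope 0 by convention if all t == t0."""
        if self.n < 1:
            raise ValueError("no samples appended")
        if self.suu <= 0.0:
            return 0.0, self.svv
        b = self.suv / self.suu
        return b, max(self.svv - b * self.suv, 0.0)

    def predict(self, t: float) -> float:
        b, _ = self.eval()
        return self.v0 + b * (t - self.t0)


# ---------------------------------------------------------------------------
# forward pass (compiled kernel)
# ---------------------------------------------------------------------------

# hypothesis state columns
_BASE, _TR, _XR, _YR, _N, _SU, _SUU, _SVX, _SUVX, _SVVX, _SVY, _SUVY, _SVVY, _CON = range(14)
_NF = 14


@njit(cache=True)
def _hyp_sse(H, k):  # pragma: no cover - compiled
    """Total (x+y) SSE of hypothesis k's current segment."""
    n = H[k, _N]
    if n <= 0.0:
        return 0.0
    sse = 0.0
    if H[k, _CON] > 0.5:
        suu = H[k, _SUU]
        for c0, c1 in ((_SUVX, _SVVX), (_SUVY, _SVVY)):
            suv = H[k, c0]
            svv = H[k, c1]
            if suu > 0.0:
                s = svv - (suv / suu) * suv
            else:
                s = svv
            sse += max(s, 0.0)
    else:
        su = H[k, _SU]
        suu = H[k, _SUU]
        sxx = suu - su * su / n
        for c0, c1, c2 in ((_SVX, _SUVX, _SVVX), (_SVY, _SUVY, _SVVY)):
            sv = H[k, c0]
            suv = H[k, c1]
            svv = H[k, c2]
            sxy = suv - su * sv / n
            syy = svv - sv * sv / n
            if sxx > 0.0:
                s = syy - (sxy / sxx) * sxy
            else:
                s = syy
            sse += max(s, 0.0)
    return sse


@njit(cache=True)
def _hyp_obj(H, k, inv2s2):  # pragma: no cover - compiled
    return H[k, _BASE] - _hyp_sse(H, k) * inv2s2


@njit(cache=True)
def _hyp_predict(H, k, tq):  # pragma: no cover - compiled
    """Predicted (x, y) of hypothesis k's segment line at time tq."""
    n = H[k, _N]
    u = tq - H[k, _TR]
    if H[k, _CON] > 0.5:
        suu = H[k, _SUU]
        bx = H[k, _SUVX] / suu if suu > 0.0 else 0.0
        by = H[k, _SUVY] / suu if suu > 0.0 else 0.0
        return H[k, _XR] + bx * u, H[k, _YR] + by * u
    su = H[k, _SU]
    suu = H[k, _SUU]
    sxx = suu - su * su / n
    ubar = su / n
    out = np.empty(2)
    for a in range(2):
        sv = H[k, _SVX + 3 * a]
        suv = H[k, _SUVX + 3 * a]
        sxy = suv - su * sv / n
        b = sxy / sxx if sxx > 0.0 else 0.0
        out[a] = H[k, _XR + a] + sv / n + b * (u - ubar)
    return out[0], out[1]


@njit(cache=True)
def _forward_pass(t, x, y, sigma, penalty, min_seg, prune, margin, max_hyps):  # pragma: no cover
    """Greedy-continuity pruned DP.  Returns (segment start indices, objective)."""
    n = t.shape[0]
    cap = n + 2
    H = np.zeros((cap, _NF))
    h_split = np.zeros(cap, dtype=np.int64)
    h_rec = np.zeros(cap, dtype=np.int64)
    r_split = np.zeros(cap, dtype=np.int64)
    r_parent = np.zeros(cap, dtype=np.int64)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)

    # hypothesis 0: first segment, unconstrained 2-parameter fit,
    # reference point (coordinate shift only) at the first sample
    H[0, _TR] = t[0]
    H[0, _XR] = x[0]
    H[0, _YR] = y[0]
    H[0, _CON] = 0.0
    h_split[0] = 0
    h_rec[0] = 0
    r_split[0] = 0
    r_parent[0] = -1
    nh = 1
    nrec = 1

    for i in range(n):
        new_k = -1
        if i > 0:
            # spawn a new hypothesis from the best eligible parent,
            # evaluated on samples < i; ties go to the later split index
            best = -1
            best_obj = -np.inf
            for k in range(nh):
                if i - h_split[k] >= min_seg:
                    o = _hyp_obj(H, k, inv2s2)
                    if o > best_obj or (o == best_obj and best >= 0 and h_split[k] > h_split[best]):
                        best_obj = o
                        best = k
            if best >= 0:
                px, py = _hyp_predict(H, best, t[i])
                new_k = nh
                for c in range(_NF):
                    H[new_k, c] = 0.0
                H[new_k, _BASE] = best_obj - penalty
                H[new_k, _TR] = t[i]
                H[new_k, _XR] = px
                H[new_k, _YR] = py
                H[new_k, _CON] = 1.0
                h_split[new_k] = i
                r_split[nrec] = i
                r_parent[nrec] = h_rec[best]
                h_rec[new_k] = nrec
                nrec += 1
                nh += 1
        # append sample i to every live hypothesis
        for k in range(nh):
            u = t[i] - H[k, _TR]
            vx = x[i] - H[k, _XR]
            vy = y[i] - H[k, _YR]
            H[k, _N] += 1.0
            H[k, _SU] += u
            H[k, _SUU] += u * u
            H[k, _SVX] += vx
            H[k, _SUVX] += u * vx
            H[k, _SVVX] += vx * vx
            H[k, _SVY] += vy
            H[k, _SUVY] += u * vy
            H[k, _SVVY] += vy * vy
        # prune hypotheses that fell too far below the newly spawned one;
        # the slack scales with the observed per-sample misfit of the best
        # hypothesis (>=1), since the amount a trailing hypothesis can
        # later recover grows with the noise/sigma misspecification
        if prune and new_k >= 0:
            objs = np.empty(nh)
            for k in range(nh):
                objs[k] = _hyp_obj(H, k, inv2s2)
            best_k = 0
            best_o = -np.inf
            for k in range(nh):
                if objs[k] > best_o:
                    best_o = objs[k]
                    best_k = k
            misfit = _hyp_sse(H, best_k) * inv2s2 / H[best_k, _N]
            thresh = objs[new_k] - margin * max(1.0, misfit)
            if nh > max_hyps:
                # bounded memory: raise the threshold to keep the best max_hyps
                cut = np.sort(objs)[nh - max_hyps]
                if cut > thresh:
                    thresh = cut
            w = 0
            for k in range(nh):
                if k == new_k or objs[k] >= thresh:
                    if w != k:
                        for c in range(_NF):
                            H[w, c] = H[k, c]
                        h_split[w] = h_split[k]
                        h_rec[w] = h_rec[k]
                    w += 1
            nh = w

    # final selection: prefer hypotheses whose last segment is long enough
    best = -1
    best_obj = -np.inf
    for k in range(nh):
        if n - h_split[k] >= min_seg:
            o = _hyp_obj(H, k, inv2s2)
            if o > best_obj or (o == best_obj and best >= 0 and h_split[k] > h_split[best]):
                best_obj = o
                best = k
    if best < 0:
        for k in range(nh):
            o = _hyp_obj(H, k, inv2s2)
            if o > best_obj:
                best_obj = o
                best = k

    # backtrack the record chain
    count = 0
    r = h_rec[best]
    while r >= 0:
        count += 1
        r = r_parent[r]
    bps = np.empty(count, dtype=np.int64)
    r = h_rec[best]
    j = count - 1
    while r >= 0:
        bps[j] = r_split[r]
        j -= 1
        r = r_parent[r]
    return bps, best_obj


# ---------------------------------------------------------------------------
# continuous refit
# ---------------------------------------------------------------------------


def refit_continuous(trace: GazeTrace, breakpoints: np.ndarray) -> Segmentation:
    """Exact least-squares fit of a continuous piecewise-linear function.

    Given the breakpoints from the forward pass, solves per axis for the
    node values of a linear spline with knots at the breakpoint times (hat
    basis; the normal equations are tridiagonal and solved with a banded
    Cholesky).  This removes the greedy-continuity approximation from the
    final reconstruction.
    """
    n = len(trace)
    bps = np.asarray(breakpoints, dtype=np.int64)
    if len(bps) == 0 or bps[0] != 0:
        raise ValueError("breakpoints must start at 0")
    m = len(bps)
    node_t = np.empty(m + 1)
    node_t[:m] = trace.t[bps]
    node_t[m] = trace.t[n - 1]
    if np.any(np.diff(node_t) <= 0):
        raise ValueError("degenerate segment: repeated node times")

    seg_idx = np.searchsorted(bps, np.arange(n), side="right") - 1
    u = (trace.t - node_t[seg_idx]) / (node_t[seg_idx + 1] - node_t[seg_idx])
    w0 = 1.0 - u
    w1 = u
    nn = m + 1
    diag = np.zeros(nn)
    off = np.zeros(nn - 1)
    np.add.at(diag, seg_idx, w0 * w0)
    np.add.at(diag, seg_idx + 1, w1 * w1)
    np.add.at(off, seg_idx, w0 * w1)
    ab = np.zeros((2, nn))
    ab[0, 1:] = off
    ab[1, :] = diag
    node_values = np.empty((nn, 2))
    for a, vals in enumerate((trace.x, trace.y)):
        b = np.zeros(nn)
        np.add.at(b, seg_idx, w0 * vals)
        np.add.at(b, seg_idx + 1, w1 * vals)
        try:
            node_values[:, a] = solveh_banded(ab, b)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate geometry
            ab_r = ab.copy()
            ab_r[1, :] += 1e-12 * max(diag.max(), 1.0)
            node_values[:, a] = solveh_banded(ab_r, b)
    return Segmentation(bps, node_t, node_values, n)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def segment_signal(trace: GazeTrace, config: SegmentationConfig) -> Segmentation:
    """Segment a trace at a *numeric* sigma and penalty.

    Runs the pruned forward pass followed by the continuous refit.  Traces
    shorter than ``2 * min_segment_samples`` yield a single segment.  For
    automatic noise estimation use :func:`segment_gaze` or
    :func:`estimate_noise`.
    """
    if not isinstance(config.sigma, (int, float)):
        raise ValueError("segment_signal requires a numeric sigma (use segment_gaze for 'auto')")
    if not isinstance(config.penalty, (int, float)):
        raise ValueError("segment_signal requires a numeric penalty")
    if len(trace) < 2:
        raise ValueError("trace too short to segment")
    t = np.ascontiguousarray(trace.t, dtype=np.float64)
    x = np.ascontiguousarray(trace.x, dtype=np.float64)
    y = np.ascontiguousarray(trace.y, dtype=np.float64)
    bps, obj = _forward_pass(
        t, x, y, float(config.sigma), float(config.penalty),
        int(config.min_segment_samples), True, PRUNE_MARGIN, MAX_HYPOTHESES,
    )
    seg = refit_continuous(trace, bps)
    seg.sigma_used = float(config.sigma)
    seg.penalty_used = float(config.penalty)
    seg.objective = float(obj)
    return seg


def _pooled_residual_std(trace: GazeTrace, seg: Segmentation) -> float:
    rec = seg.reconstruct(trace.t)
    r = np.concatenate([trace.x - rec[:, 0], trace.y - rec[:, 1]])
    return float(np.sqrt(np.mean(r * r)))


def estimate_noise(
    trace: GazeTrace, config: SegmentationConfig, penalty: float
) -> Tuple[float, Segmentation]:
    """Automatic noise estimation by fixed-point iteration.

    σ₀ is the pooled per-axis standard deviation of the signal itself;
    σ_{k+1} is the pooled standard deviation of the residual between the
    signal and its reconstruction under σ_k.  Iteration stops when an
    estimate recurs (values compared after rounding, since exact recurrence
    is a measure-zero event in floating point) or at the iteration cap, in
    which case the lowest-residual iterate is kept with a warning.

    Returns ``(sigma_total, segmentation)`` where ``sigma_total`` is the
    converged estimate combined with the structural error, and the
    segmentation is recomputed at ``sigma_total``.
    """
    sx = float(np.std(trace.x))
    sy = float(np.std(trace.y))
    sigma = math.sqrt((sx * sx + sy * sy) / 2.0)
    if sigma <= 0:
        sigma = 1e-6
    seen = set()
    best_sigma = sigma
    best_gap = math.inf
    converged = False
    for _ in range(config.noise_max_iter):
        key = round(sigma, config.noise_round_decimals)
        if key in seen:
            converged = True
            break
        seen.add(key)
        cfg_k = SegmentationConfig(
            sigma=max(sigma, 1e-6), penalty=penalty,
            min_segment_samples=config.min_segment_samples,
        )
        seg_k = segment_signal(trace, cfg_k)
        new_sigma = _pooled_residual_std(trace, seg_k)
        if new_sigma <= 0:
            new_sigma = 1e-6
        gap = abs(new_sigma - sigma)
        if gap < best_gap:
            best_gap = gap
            best_sigma = new_sigma
        sigma = new_sigma
    if not converged:
        warnings.warn(
            "noise estimation did not converge within the iteration cap; "
            "using the lowest-residual iterate",
            RuntimeWarning,
        )
        sigma = best_sigma
    if config.structural_combine == "add":
        total = sigma + config.structural_error
    else:
        total = math.sqrt(sigma * sigma + config.structural_error ** 2)
    cfg_final = SegmentationConfig(
        sigma=max(total, 1e-6), penalty=penalty,
        min_segment_samples=config.min_segment_samples,
    )
    seg = segment_signal(trace, cfg_final)
    return total, seg


def resolve_penalty(trace: GazeTrace, config: SegmentationConfig) -> float:
    """Resolve the split penalty: numeric value, or table lookup.

    The automatic lookup uses the shipped calibration table at the
    configured scenario hint (default: a*=10°, d*=1 s, v*=5°/s); the
    sampling rate comes from the hint's optional fourth element, else from
    the trace's median sampling interval.
    """
    if isinstance(config.penalty, (int, float)):
        return float(config.penalty)
    from .calibrate import load_default_penalty_table, penalty_from_scenario

    hint = tuple(config.scenario_hint or DEFAULT_SCENARIO)
    if len(hint) == 3:
        hint = (*hint, trace.median_rate)
    table = load_default_penalty_table()
    return penalty_from_scenario(hint, table)


def segment_gaze(trace: GazeTrace, config: Optional[SegmentationConfig] = None) -> Segmentation:
    """High-level entry point: resolve sigma/penalty, segment, refit.

    With the default configuration (sigma="auto", penalty="auto") no manual
    parameters are required: the penalty comes from the shipped calibration
    table and the noise level is estimated from the data.
    """
    if config is None:
        config = SegmentationConfig()
    penalty = resolve_penalty(trace, config)
    if config.sigma == "auto":
        _, seg = estimate_noise(trace, config, penalty)
        return seg
    cfg = SegmentationConfig(
        sigma=config.sigma, penalty=penalty,
        min_segment_samples=config.min_segment_samples,
    )
    return segment_signal(trace, cfg)
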