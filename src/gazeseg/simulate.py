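"""Synthetic gaze recordings with ground truth.

The simulator emulates a participant tracking a target that alternates
between instantaneous jumps (producing saccade-like fast phases of the eye)
and constant-velocity slow phases (producing fixations or smooth pursuit).
The eye itself is a damped harmonic oscillator driven by the positional
error to the target, integrated independently per axis:

    p̈ = K (target − p) − D ṗ

with stiffness ``K`` (1/s²) and damping ``D`` (1/s).  With the default
K=6000, D=90 the step response is underdamped and approximates saccadic
dynamics: peak velocity and acceleration are linear in step amplitude and
the response duration is amplitude-independent (a deliberate simplification
of the empirical main sequence).

The noiseless eye trajectory is generated on a dense grid (default 1009 Hz),
downsampled by linear interpolation to the requested tracker rate, and
contaminated with i.i.d. per-axis Gaussian noise.  All randomness flows from
a single integer seed through ``numpy.random.SeedSequence`` (PCG64 streams),
so recordings are bit-reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .io import GazeTrace

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

FAST = "fast"
SLOW = "slow"


@dataclass
class ScenarioParams:
    """Parameters of a simulated eye-movement scenario.

    a_star : maximum fast-phase (jump) amplitude [deg]
    d_star : maximum slow-phase duration [s]
    v_star : maximum slow-phase speed [deg/s]
    K, D   : oscillator stiffness [1/s²] and damping [1/s]
    gen_rate : dense generation rate [Hz]
    out_rate : output (tracker) rate [Hz], must not exceed gen_rate
    duration : scenario length [s]
    sigma  : per-axis measurement noise std [deg]
    seed   : integer RNG seed (mandatory for reproducibility)
    """

    a_star: float = 10.0
    d_star: float = 1.0
    v_star: float = 5.0
    K: float = 6000.0
    D: float = 90.0
    gen_rate: float = 1009.0
    out_rate: float = 500.0
    duration: float = 120.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.a_star, self.d_star, self.v_star, self.sigma) < 0:
            raise ValueError("a_star, d_star, v_star, sigma must be >= 0")
        if min(self.K, self.D, self.gen_rate, self.out_rate, self.duration) <= 0:
            raise ValueError("K, D, rates and duration must be > 0")
        if self.out_rate > self.gen_rate:
            raise ValueError("out_rate must not exceed gen_rate")
        if self.d_star == 0:
            raise ValueError("d_star must be > 0 (scenario needs slow phases)")


@dataclass
class TargetEvents:
    """Event-level description of the target process."""

    #: jump times [s]
    jump_times: np.ndarray
    #: jump amplitudes [deg]
    jump_amplitudes: np.ndarray
    #: slow-phase speeds [deg/s], one per phase (first phase included)
    slow_speeds: np.ndarray
    #: vertices (t, x, y) of the piecewise-linear target path; jumps appear
    #: as two vertices at the same time (pre- and post-jump position)
    vertices: np.ndarray


def generate_target_events(params: ScenarioParams, rng: np.random.Generator) -> TargetEvents:
    """Draw the alternating slow-phase / jump event sequence.

    Per slow phase, duration ~ U(0, d*), speed ~ U(0, v*) and direction
    uniform on the circle; per jump, amplitude ~ U(0, a*) and direction
    uniform on the circle.  The first slow phase starts at the origin.
    """
    t = 0.0
    pos = np.zeros(2)
    verts: List[Tuple[float, float, float]] = [(0.0, 0.0, 0.0)]
    jt: List[float] = []
    ja: List[float] = []
    speeds: List[float] = []
    while t < params.duration:
        dur = rng.uniform(0.0, params.d_star)
        speed = rng.uniform(0.0, params.v_star)
        ang = rng.uniform(0.0, 2.0 * math.pi)
        vel = speed * np.array([math.cos(ang), math.sin(ang)])
        t = t + dur
        pos = pos + vel * dur
        verts.append((t, pos[0], pos[1]))
        speeds.append(speed)
        if t >= params.duration:
            break
        amp = rng.uniform(0.0, params.a_star)
        ang = rng.uniform(0.0, 2.0 * math.pi)
        pos = pos + amp * np.array([math.cos(ang), math.sin(ang)])
        verts.append((t, pos[0], pos[1]))
        jt.append(t)
        ja.append(amp)
    return TargetEvents(
        jump_times=np.asarray(jt),
        jump_amplitudes=np.asarray(ja),
        slow_speeds=np.asarray(speeds),
        vertices=np.asarray(verts),
    )


def sample_target(events: TargetEvents, t: np.ndarray) -> np.ndarray:
    """Evaluate the target path at times ``t`` (right-continuous at jumps).

    Returns an (n, 2) position array.
    """
    vt = events.vertices[:, 0]
    # right-continuity: at a jump time the post-jump vertex (the later of
    # the two equal-time vertices) wins
    idx = np.searchsorted(vt, t, side="right") - 1
    idx = np.clip(idx, 0, len(vt) - 1)
    out = np.empty((len(t), 2))
    for a in range(2):
        va = events.vertices[:, 1 + a]
        nxt = np.minimum(idx + 1, len(vt) - 1)
        dt_seg = vt[nxt] - vt[idx]
        frac = np.where(dt_seg > 0, (t - vt[idx]) / np.where(dt_seg > 0, dt_seg, 1.0), 0.0)
        out[:, a] = va[idx] + frac * (va[nxt] - va[idx])
    return out


def generate_target(params: ScenarioParams, rng: Optional[np.random.Generator] = None):
    """Sample the target process on the dense generation grid.

    Returns ``(trace, events)`` where ``trace`` is the target as a
    :class:`GazeTrace` at ``gen_rate`` and ``events`` the underlying jump /
    slow-phase description (the ground truth for phase labelling).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    events = generate_target_events(params, rng)
    n = int(math.floor(params.duration * params.gen_rate)) + 1
    t = np.arange(n) / params.gen_rate
    pos = sample_target(events, t)
    return GazeTrace(t, pos[:, 0], pos[:, 1]), events


@njit(cache=True)
def _rk4_oscillator(tx, ty, dt, K, D, p0x, p0y):  # pragma: no cover - compiled
    n = tx.shape[0]
    out = np.empty((n, 2))
    px, py = p0x, p0y
    vx, vy = 0.0, 0.0
    out[0, 0] = px
    out[0, 1] = py
    for i in range(n - 1):
        for a in range(2):
            if a == 0:
                u0, u1, p, v = tx[i], tx[i + 1], px, vx
            else:
                u0, u1, p, v = ty[i], ty[i + 1], py, vy
            uh = 0.5 * (u0 + u1)
            # k1
            k1p = v
            k1v = K * (u0 - p) - D * v
            # k2
            p2 = p + 0.5 * dt * k1p
            v2 = v + 0.5 * dt * k1v
            k2p = v2
            k2v = K * (uh - p2) - D * v2
            # k3
            p3 = p + 0.5 * dt * k2p
            v3 = v + 0.5 * dt * k2v
            k3p = v3
            k3v = K * (uh - p3) - D * v3
            # k4
            p4 = p + dt * k3p
            v4 = v + dt * k3v
            k4p = v4
            k4v = K * (u1 - p4) - D * v4
            p = p + dt / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
            v = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            if a == 0:
                px, vx = p, v
            else:
                py, vy = p, v
        out[i + 1, 0] = px
        out[i + 1, 1] = py
    return out


def simulate_eye(
    target: GazeTrace,
    K: float = 6000.0,
    D: float = 90.0,
    initial: Optional[Tuple[float, float]] = None,
) -> GazeTrace:
    """Integrate the damped-oscillator eye model along a target trace.

    The eye starts at rest at ``initial`` (default: the target's first
    position).  Classical fixed-step RK4 on the uniform generation grid;
    the target is linearly interpolated at half steps.  Raises if the step
    size is too large for the oscillator's eigenvalues (RK4 stability).
    """
    dt = float(np.median(np.diff(target.t)))
    # complex eigenvalue magnitude is sqrt(K) in the underdamped regime
    if dt * math.sqrt(K) > 2.0:
        raise ValueError(
            "integration step too large for K, D: increase gen_rate "
            f"(dt*sqrt(K) = {dt * math.sqrt(K):.2f} > 2)"
        )
    if initial is None:
        initial = (float(target.x[0]), float(target.y[0]))
    pos = _rk4_oscillator(
        np.ascontiguousarray(target.x),
        np.ascontiguousarray(target.y),
        dt,
        float(K),
        float(D),
        float(initial[0]),
        float(initial[1]),
    )
    return GazeTrace(target.t.copy(), pos[:, 0], pos[:, 1])


def step_response(t: np.ndarray, amplitude: float, K: float = 6000.0, D: float = 90.0) -> np.ndarray:
    """Closed-form unit-step response of the oscillator, scaled by amplitude.

    For the underdamped case (D² < 4K):
    ``x(t) = A [1 − e^{−ζω t}(cos ω_d t + ζω/ω_d · sin ω_d t)]`` with
    ω = √K, ζ = D/(2√K), ω_d = ω√(1−ζ²).
    """
    w = math.sqrt(K)
    zeta = D / (2.0 * w)
    if zeta >= 1.0:
        raise ValueError("closed form implemented for the underdamped case only")
    wd = w * math.sqrt(1.0 - zeta * zeta)
    e = np.exp(-zeta * w * t)
    return amplitude * (1.0 - e * (np.cos(wd * t) + (zeta * w / wd) * np.sin(wd * t)))


def resample_and_noise(
    eye: GazeTrace,
    out_rate: float,
    sigma: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> GazeTrace:
    """Downsample by linear interpolation and add per-axis Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(seed)
    span = eye.t[-1] - eye.t[0]
    n_out = int(math.floor(span * out_rate + 1e-9)) + 1
    t_out = eye.t[0] + np.arange(n_out) / out_rate
    x = np.interp(t_out, eye.t, eye.x)
    y = np.interp(t_out, eye.t, eye.y)
    if sigma > 0:
        x = x + rng.normal(0.0, sigma, n_out)
        y = y + rng.normal(0.0, sigma, n_out)
    return GazeTrace(t_out, x, y)


@dataclass
class SimulatedRecording:
    """A simulated recording with full ground truth.

    All four series share identical timestamps (the output grid).
    ``phase_labels`` holds ``"fast"`` during the eye's response to a target
    jump and ``"slow"`` elsewhere.
    """

    measured: GazeTrace
    truth: GazeTrace
    target: GazeTrace
    phase_labels: np.ndarray
    events: TargetEvents
    params: ScenarioParams


# fraction of the jump amplitude below which the eye is considered settled
FAST_SETTLE_FRACTION = 0.1
# a fast phase is labelled on at least this many output samples
FAST_MIN_SAMPLES = 2


def _fast_phase_windows(
    events: TargetEvents, eye: GazeTrace, target_pos: np.ndarray, out_rate: float
) -> List[Tuple[float, float]]:
    """Time windows of the eye's fast response to each jump.

    A window runs from jump onset until the eye-to-target distance first
    falls below ``FAST_SETTLE_FRACTION`` of the jump amplitude *on top of*
    the pre-jump tracking error (the oscillator lags a moving target, so a
    purely amplitude-relative threshold would never be reached after small
    jumps).  The search is bounded by the next jump; windows are extended
    if necessary to span ``FAST_MIN_SAMPLES`` output samples.
    """
    d = np.hypot(eye.x - target_pos[:, 0], eye.y - target_pos[:, 1])
    n_jumps = len(events.jump_times)
    windows = []
    for j, (tj, amp) in enumerate(zip(events.jump_times, events.jump_amplitudes)):
        i0 = int(np.searchsorted(eye.t, tj, side="left"))
        t_next = events.jump_times[j + 1] if j + 1 < n_jumps else eye.t[-1]
        i1 = int(np.searchsorted(eye.t, t_next, side="left"))
        pre_err = d[i0 - 1] if i0 > 0 else 0.0
        thresh = FAST_SETTLE_FRACTION * amp + pre_err
        rel = np.nonzero(d[i0:i1] < thresh)[0]
        t_end = eye.t[i0 + rel[0]] if len(rel) else t_next
        t_end = max(t_end, tj + FAST_MIN_SAMPLES / out_rate)
        windows.append((tj, t_end))
    return windows


def simulate_recording(params: ScenarioParams) -> SimulatedRecording:
    """Run the full pipeline: target → oscillator eye → resample → noise.

    Deterministic in ``params`` (including ``seed``); the target draw and
    the measurement noise use independent child streams of the seed.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_target, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    target, events = generate_target(params, rng_target)
    eye = simulate_eye(target, params.K, params.D)
    truth = resample_and_noise(eye, params.out_rate, 0.0)
    measured = GazeTrace(
        truth.t.copy(),
        truth.x + (rng_noise.normal(0.0, params.sigma, len(truth)) if params.sigma > 0 else 0.0),
        truth.y + (rng_noise.normal(0.0, params.sigma, len(truth)) if params.sigma > 0 else 0.0),
    )
    target_out = resample_and_noise(target, params.out_rate, 0.0)

    target_pos_gen = sample_target(events, target.t)
    windows = _fast_phase_windows(events, eye, target_pos_gen, params.out_rate)
    labels = np.full(len(truth), SLOW, dtype=object)
    for t0, t1 in windows:
        labels[(truth.t >= t0) & (truth.t < t1)] = FAST
    return SimulatedRecording(measured, truth, target_out, labels, events, params)
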