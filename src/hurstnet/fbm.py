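"""Exact fractional Brownian motion simulation and fixtures.

Fractional Brownian motion (fBm) is the zero-mean Gaussian process with
covariance ``<B_H(t) B_H(s)> ~ t^2H + s^2H - |t-s|^2H``; its increment
process, fractional Gaussian noise (fGn), is stationary with autocovariance

    gamma(k) = (sigma^2 / 2) * (|k+1|^2H - 2|k|^2H + |k-1|^2H).

Trajectories are generated by the Hosking method: the Durbin-Levinson
recursion samples each fGn value from its exact conditional distribution
given the past, so the output has the target covariance exactly (not
asymptotically).  The recursion is O(N^2) per track and is jit-compiled;
ensembles with per-track Hurst exponents are drawn in one batched call.

The module also builds the synthetic fixtures used throughout: regime-
switching trajectories whose Hurst exponent jumps between an anti-persistent
and a persistent state with exponential or heavy-tailed (Pareto) residence
times, measurement-noise corruption, and random temporal subsampling.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .errors import ParameterError
from .trajectory import LabeledTrajectory, Trajectory

__all__ = [
    "FbmParams",
    "DwellLaw",
    "SwitchingSpec",
    "fgn_autocovariance",
    "sample_fgn",
    "simulate_fbm",
    "simulate_fbm_ensemble",
    "simulate_switching_fbm",
    "add_noise",
    "subsample_random",
]

ANTI_PERSISTENT = "anti_persistent"
PERSISTENT = "persistent"

# rows per batched Hosking call; bounds peak memory at ~3 * CHUNK * N doubles
_CHUNK = 20_000


def fgn_autocovariance(hurst: float, n_lags: int) -> np.ndarray:
    """Closed-form autocovariance of unit-variance fGn at lags ``0..n_lags-1``."""
    if not 0.0 < hurst < 1.0:
        raise ParameterError(f"hurst must be in (0, 1), got {hurst}")
    k = np.arange(n_lags, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


@njit(cache=True)
def _hosking_batch(gam: np.ndarray, z: np.ndarray) -> np.ndarray:  # pragma: no cover
    """Durbin-Levinson conditional sampling, one row per track.

    gam[m] is the fGn autocovariance for track m (gam[m, 0] == 1), z is a
    matrix of i.i.d. standard normals; returns fGn with that covariance.
    """
    m_tracks, n = z.shape
    out = np.empty((m_tracks, n))
    phi = np.empty(n)
    phi_prev = np.empty(n)
    for m in range(m_tracks):
        g = gam[m]
        x = out[m]
        v = g[0]
        x[0] = np.sqrt(v) * z[m, 0]
        for i in range(n):
            phi_prev[i] = 0.0
        for t in range(1, n):
            acc = g[t]
            for k in range(1, t):
                acc -= phi_prev[k] * g[t - k]
            pt = acc / v
            for k in range(1, t):
                phi[k] = phi_prev[k] - pt * phi_prev[t - k]
            phi[t] = pt
            v *= 1.0 - pt * pt
            if v < 1e-14:  # numerical floor near H -> 1
                v = 1e-14
            mean = 0.0
            for k in range(1, t + 1):
                mean += phi[k] * x[t - k]
            x[t] = mean + np.sqrt(v) * z[m, t]
            for k in range(1, t + 1):
                phi_prev[k] = phi[k]
    return out


def sample_fgn(hurst: np.ndarray | float, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Sample unit-variance fGn rows, one per entry of ``hurst``.

    Returns an array of shape ``(len(hurst), n_steps)``.  Scalar ``hurst``
    yields a single row.
    """
    h = np.atleast_1d(np.asarray(hurst, dtype=float))
    if np.any((h <= 0.0) | (h >= 1.0)):
        raise ParameterError("hurst values must be in (0, 1)")
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    out = np.empty((h.size, n_steps))
    k = np.arange(n_steps, dtype=float)
    for lo in range(0, h.size, _CHUNK):
        hi = min(lo + _CHUNK, h.size)
        h2 = (2.0 * h[lo:hi])[:, None]
        gam = 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)
        z = rng.standard_normal((hi - lo, n_steps))
        out[lo:hi] = _hosking_batch(gam, z)
    return out


@dataclass
class FbmParams:
    """Parameters of a constant-H fBm track.

    ``diffusion_scale`` multiplies the increments; with unit scale the track
    is exactly self-similar, ``Var[x(k dt)] = (k dt)^(2H)``.
    """

    hurst: float
    n_points: int
    dt: float = 1.0
    diffusion_scale: float = 1.0
    seed: Optional[int] = None
    n_dim: int = 1
    track_id: object = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ParameterError(f"hurst must be in (0, 1), got {self.hurst}")
        if self.n_points < 2:
            raise ParameterError("n_points must be >= 2")
        if self.dt <= 0 or self.diffusion_scale <= 0:
            raise ParameterError("dt and diffusion_scale must be positive")
        if self.n_dim not in (1, 2):
            raise ParameterError("n_dim must be 1 or 2")


def simulate_fbm(params: FbmParams, rng: Optional[np.random.Generator] = None) -> Trajectory:
    """Generate one exact fBm trajectory (Hosking method).

    2D tracks use two independent fGn components sharing the same H
    (isotropic convention).  Reproducible given ``params.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_inc = params.n_points - 1
    step_scale = params.diffusion_scale * params.dt**params.hurst
    fgn = sample_fgn(np.full(params.n_dim, params.hurst), n_inc, rng) * step_scale
    pos = np.zeros((params.n_points, params.n_dim))
    pos[1:] = np.cumsum(fgn.T, axis=0)
    return Trajectory(params.track_id, params.dt, pos)


def simulate_fbm_ensemble(
    hurst: np.ndarray,
    n_points: int,
    dt: float = 1.0,
    diffusion_scale: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Batch 1D fBm: returns positions of shape ``(len(hurst), n_points)``.

    Row ``m`` is a track with Hurst exponent ``hurst[m]`` starting at 0.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    h = np.asarray(hurst, dtype=float)
    fgn = sample_fgn(h, n_points - 1, rng)
    fgn *= (diffusion_scale * dt**h)[:, None] if h.ndim else diffusion_scale * dt**h
    pos = np.zeros((h.size, n_points))
    np.cumsum(fgn, axis=1, out=pos[:, 1:])
    return pos


@dataclass
class DwellLaw:
    """Residence-time distribution for one motile state, in points.

    family ``"exponential"`` uses ``mean``; family ``"pareto"`` draws from
    the heavy-tailed density psi(t) ~ t^(-mu-1) (survival ~ t^-mu) with
    scale ``minimum``.  ``cap`` truncates the largest dwells, mimicking the
    finite observation window of real tracks ("truncated heavy tails").
    """

    family: str
    mean: Optional[float] = None
    mu: Optional[float] = None
    minimum: int = 1
    cap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "pareto"):
            raise ParameterError(f"unknown dwell family {self.family!r}")
        if self.family == "exponential" and (self.mean is None or self.mean <= 0):
            raise ParameterError("exponential dwell law needs mean > 0")
        if self.family == "pareto" and (self.mu is None or self.mu <= 0):
            raise ParameterError("pareto dwell law needs mu > 0")
        if self.minimum < 1:
            raise ParameterError("minimum dwell must be >= 1 point")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "exponential":
            raw = self.minimum + rng.exponential(self.mean, size=size)
        else:
            u = rng.random(size)
            raw = self.minimum * u ** (-1.0 / self.mu)
        lengths = np.maximum(np.rint(raw).astype(int), self.minimum)
        if self.cap is not None:
            lengths = np.minimum(lengths, self.cap)
        return lengths


@dataclass
class SwitchingSpec:
    """Regime-switching fBm: H(t) jumps between an anti-persistent state
    (interval inside (0, 0.5)) and a persistent state (inside (0.5, 1)).

    Each dwell draws its duration from the state's :class:`DwellLaw` and its
    Hurst exponent uniformly from the state's interval; increments are
    generated per dwell as independent fBm segments joined continuously.
    """

    anti_hurst: Tuple[float, float] = (0.2, 0.3)
    pers_hurst: Tuple[float, float] = (0.75, 0.85)
    anti_dwell: DwellLaw = field(default_factory=lambda: DwellLaw("exponential", mean=100.0))
    pers_dwell: DwellLaw = field(default_factory=lambda: DwellLaw("exponential", mean=100.0))
    n_points: int = 1000
    dt: float = 1.0
    diffusion_scale: float = 1.0
    seed: Optional[int] = None
    start_state: Optional[str] = None  # None: random
    n_dim: int = 1
    track_id: object = 0

    def __post_init__(self) -> None:
        a_lo, a_hi = self.anti_hurst
        p_lo, p_hi = self.pers_hurst
        if not (0.0 < a_lo <= a_hi < 0.5):
            raise ParameterError("anti_hurst interval must lie within (0, 0.5)")
        if not (0.5 < p_lo <= p_hi < 1.0):
            raise ParameterError("pers_hurst interval must lie within (0.5, 1)")
        if self.n_points < 2:
            raise ParameterError("n_points must be >= 2")
        if self.n_dim not in (1, 2):
            raise ParameterError("n_dim must be 1 or 2")


def _draw_state_hurst(interval: Tuple[float, float], rng: np.random.Generator) -> float:
    lo, hi = interval
    return lo if lo == hi else rng.uniform(lo, hi)


def simulate_switching_fbm(
    spec: SwitchingSpec, rng: Optional[np.random.Generator] = None
) -> LabeledTrajectory:
    """Generate a piecewise-fBm trajectory with per-point H labels.

    Dwells alternate between the two states; the trajectory is truncated at
    ``n_points`` (the final dwell is cut short).  No correlation is carried
    across state boundaries: each dwell is an independent fBm segment
    translated to start at the previous endpoint.  2D tracks use
    independent components sharing the same H(t).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_points
    state = spec.start_state or rng.choice([ANTI_PERSISTENT, PERSISTENT])
    if state not in (ANTI_PERSISTENT, PERSISTENT):
        raise ParameterError(f"unknown start_state {state!r}")

    # plan dwells until the label series is full
    dwells = []  # (state, hurst, start_index, length)
    labels = np.empty(n)
    pos_filled = 0
    while pos_filled < n:
        law = spec.anti_dwell if state == ANTI_PERSISTENT else spec.pers_dwell
        interval = spec.anti_hurst if state == ANTI_PERSISTENT else spec.pers_hurst
        length = int(law.draw(rng, 1)[0])
        length = min(length, n - pos_filled)
        h = _draw_state_hurst(interval, rng)
        labels[pos_filled : pos_filled + length] = h
        dwells.append((state, h, pos_filled, length))
        pos_filled += length
        state = PERSISTENT if state == ANTI_PERSISTENT else ANTI_PERSISTENT

    # increment i (between points i-1 and i) inherits the label of point i
    inc_h = labels[1:]
    increments = np.empty((n - 1, spec.n_dim))
    start = 0
    while start < n - 1:
        stop = start
        while stop < n - 1 and inc_h[stop] == inc_h[start]:
            stop += 1
        h = inc_h[start]
        seg = sample_fgn(np.full(spec.n_dim, h), stop - start, rng)
        increments[start:stop] = seg.T * spec.diffusion_scale * spec.dt**h
        start = stop

    pos = np.zeros((n, spec.n_dim))
    pos[1:] = np.cumsum(increments, axis=0)
    traj = Trajectory(spec.track_id, spec.dt, pos)
    return LabeledTrajectory(traj, labels, dwells=dwells)


def add_noise(traj: Trajectory, nsr: float, seed: Optional[int] = None) -> Trajectory:
    """Add Gaussian measurement noise of strength ``nsr`` (noise/signal).

    The noise standard deviation is ``nsr`` times the sample standard
    deviation of the coordinate values, per spatial component; every point
    is corrupted independently.  ``nsr=0`` returns an identical copy.
    """
    if nsr < 0:
        raise ParameterError("nsr must be >= 0")
    pos = traj.positions.copy()
    if nsr > 0:
        rng = np.random.default_rng(seed)
        sigma = nsr * pos.std(axis=0)
        pos += rng.standard_normal(pos.shape) * sigma
    return Trajectory(traj.track_id, traj.dt, pos, None if traj.times is None else traj.times.copy())


def subsample_random(traj: Trajectory, n_rand: int, seed: Optional[int] = None) -> Trajectory:
    """Keep ``n_rand`` uniformly random time points (sorted, original stamps).

    Models intermittent detection: the retained points keep their original
    times, so the output is non-uniformly sampled.
    """
    n = traj.n_points
    if not 2 <= n_rand <= n:
        raise ParameterError(f"n_rand must be in [2, {n}], got {n_rand}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=n_rand, replace=False))
    return Trajectory(traj.track_id, traj.dt, traj.positions[idx], traj.time_stamps()[idx])


def subsample_indices(n: int, n_rand: int, rng: np.random.Generator, m: int = 1) -> np.ndarray:
    """Batch helper: ``m`` sorted index sets of size ``n_rand`` out of ``n``."""
    if not 2 <= n_rand <= n:
        raise ParameterError(f"n_rand must be in [2, {n}], got {n_rand}")
    keys = rng.random((m, n))
    return np.sort(np.argsort(keys, axis=1)[:, :n_rand], axis=1)
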