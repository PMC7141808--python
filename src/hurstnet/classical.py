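"""Conventional Hurst-exponent estimators used as baselines.

Three single-track estimators, each reducing a scalar position series to a
power-law fit:

* time-averaged MSD  ``<x^2(n dt)> ~ t^(2H)``
* rescaled range     ``[R/S](n dt) ~ (n dt)^H``
* sequential range   ``M(n dt) = (n dt)^H M(dt)``

2D tracks are handled per coordinate and the two H estimates averaged
(except the TAMSD curve itself, where squared displacements sum over
components as usual).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateInputError, ParameterError, UndefinedFitError
from .trajectory import Trajectory

__all__ = [
    "ClassicalCurve",
    "tamsd_curve",
    "fit_hurst_tamsd",
    "tamsd_hurst",
    "rescaled_range_hurst",
    "sequential_range_hurst",
]


@dataclass
class ClassicalCurve:
    """A lag-time statistic ready for a power-law fit."""

    lag_times: np.ndarray
    statistic_values: np.ndarray
    statistic_kind: str

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.statistic_values = np.asarray(self.statistic_values, dtype=float)
        if self.lag_times.shape != self.statistic_values.shape:
            raise ParameterError("lag_times and statistic_values must have equal length")
        if np.any(np.diff(self.lag_times) <= 0):
            raise ParameterError("lag_times must be strictly increasing")


def _require_uniform(traj: Trajectory) -> None:
    if not traj.is_uniform:
        raise ParameterError("classical estimators require uniform sampling")


def tamsd_curve(traj: Trajectory) -> ClassicalCurve:
    """Time-averaged MSD at every available lag ``n = 1..N-1``.

    ``<x^2(n dt)> = (1/(N-n)) sum_m |x((m+n)dt) - x(m dt)|^2`` with the sum
    over all N-n window placements; squared displacements sum over spatial
    components for 2D tracks.
    """
    _require_uniform(traj)
    n = traj.n_points
    if n < 3:
        raise ParameterError("TAMSD needs at least 3 points")
    pos = traj.positions
    vals = np.empty(n - 1)
    for lag in range(1, n):
        d = pos[lag:] - pos[:-lag]
        vals[lag - 1] = np.mean(np.sum(d * d, axis=1))
    lags = np.arange(1, n) * traj.dt
    return ClassicalCurve(lags, vals, "tamsd")


def fit_hurst_tamsd(curve: ClassicalCurve) -> float:
    """Nonlinear least-squares fit ``A * t^(2H)`` over all lags; returns H."""
    t = curve.lag_times
    y = curve.statistic_values
    if t.size < 3:
        raise ParameterError("need at least 3 lag points")
    if np.all(y == 0):
        raise UndefinedFitError("all-zero curve has no power-law exponent")
    # log-log slope as starting point, guarded against zeros
    mask = y > 0
    slope, logc = np.polyfit(np.log(t[mask]), np.log(y[mask]), 1)
    try:
        popt, _ = curve_fit(
            lambda tt, a, h: a * tt ** (2.0 * h),
            t,
            y,
            p0=[np.exp(logc), np.clip(slope / 2.0, 0.01, 1.49)],
            maxfev=2000,
        )
    except RuntimeError as exc:  # no convergence
        raise UndefinedFitError("power-law fit did not converge") from exc
    return float(popt[1])


def _tamsd_hurst_1d(x: np.ndarray, dt: float) -> float:
    traj = Trajectory("_", dt, x)
    return fit_hurst_tamsd(tamsd_curve(traj))


def tamsd_hurst(traj: Trajectory) -> float:
    """TAMSD power-law estimate of H for a track (coordinates averaged)."""
    _require_uniform(traj)
    return float(
        np.mean([_tamsd_hurst_1d(traj.coordinate(a), traj.dt) for a in range(traj.n_dim)])
    )


def _rs_window_sizes(n: int, minimum: int = 10, factor: float = 1.25) -> np.ndarray:
    """Geometric schedule of R/S window sizes from ``minimum`` to ``n``."""
    sizes = [minimum]
    while sizes[-1] < n:
        nxt = max(int(round(sizes[-1] * factor)), sizes[-1] + 1)
        sizes.append(min(nxt, n))
    return np.unique(sizes)


def _rs_statistic(x: np.ndarray) -> float:
    """Rescaled range of one block: range of the mean-adjusted cumulative
    deviate series over the population standard deviation."""
    dev = x - x.mean()
    z = np.cumsum(dev)
    s = np.sqrt(np.mean(dev * dev))
    if s == 0:
        return np.nan
    return (z.max() - z.min()) / s


def _rescaled_range_hurst_1d(pos: np.ndarray, dt: float) -> float:
    if pos.size < 21:
        raise ParameterError("rescaled-range estimate needs at least 21 points")
    if np.all(pos == pos[0]):
        raise DegenerateInputError("zero-variance series")
    # R/S analysis addresses a stationary sequence: the track's step
    # displacements (fGn), not the positions themselves
    x = np.diff(pos)
    n = x.size
    sizes = _rs_window_sizes(n)
    log_w, log_rs = [], []
    for w in sizes:
        n_blocks = n // w
        vals = [_rs_statistic(x[b * w : (b + 1) * w]) for b in range(n_blocks)]
        vals = [v for v in vals if np.isfinite(v) and v > 0]
        if vals:
            log_w.append(np.log(w * dt))
            log_rs.append(np.log(np.mean(vals)))
    if len(log_w) < 3:
        raise UndefinedFitError("too few usable window sizes for R/S fit")
    slope = np.polyfit(log_w, log_rs, 1)[0]
    return float(slope)


def rescaled_range_hurst(traj: Trajectory) -> float:
    """Rescaled-range (R/S) estimate of H.

    The track is differenced to its step displacements, then block-averaged
    R/S statistics on a geometric window schedule (10 .. N-1, factor 1.25)
    are fitted as ``[R/S] ~ (n dt)^H`` in log-log.  Scale- and
    shift-invariant by construction.
    """
    _require_uniform(traj)
    return float(
        np.mean(
            [_rescaled_range_hurst_1d(traj.coordinate(a), traj.dt) for a in range(traj.n_dim)]
        )
    )


def _sequential_range_hurst_1d(x: np.ndarray, dt: float) -> float:
    n = x.size
    if n < 10:
        raise ParameterError("sequential-range estimate needs at least 10 points")
    d = x - x[0]
    run_max = np.maximum.accumulate(d)
    run_min = np.minimum.accumulate(d)
    m = (run_max - run_min)[1:]  # M(n dt), n = 1..N-1
    if m[0] == 0:
        raise UndefinedFitError("M(dt) = 0: sequential-range fit undefined")
    # M(n dt) = (n dt)^H M(dt)  =>  log(M(n)/M(1)) = H log(n),
    # regression through the origin with M(dt) as the anchor
    log_n = np.log(np.arange(1, n))
    ratio = m / m[0]
    good = ratio > 0
    log_r = np.log(ratio[good])
    log_n = log_n[good]
    denom = np.dot(log_n, log_n)
    if denom == 0:
        raise UndefinedFitError("degenerate lag axis")
    return float(np.dot(log_n, log_r) / denom)


def sequential_range_hurst(traj: Trajectory) -> float:
    """Sequential-range estimate of H.

    ``M(n dt)`` is the running max-minus-min of displacements from the
    origin; H is the through-origin slope of ``log(M(n dt)/M(dt))`` on
    ``log n``.
    """
    _require_uniform(traj)
    return float(
        np.mean(
            [_sequential_range_hurst_1d(traj.coordinate(a), traj.dt) for a in range(traj.n_dim)]
        )
    )
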