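"""Particle-track containers.

A :class:`Trajectory` is a uniformly sampled track of 1D or 2D positions
(micrometres) at spacing ``dt`` (seconds).  Randomly subsampled tracks keep
their original (now non-uniform) time stamps in ``times``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError

__all__ = ["Trajectory", "LabeledTrajectory"]


@dataclass
class Trajectory:
    """A single particle track.

    Parameters
    ----------
    track_id
        Opaque identifier.
    dt
        Nominal sampling interval in seconds (spacing of the *original*
        uniform grid, also for subsampled tracks).
    positions
        Array of shape ``(N,)`` for 1D or ``(N, 2)`` for 2D, in micrometres.
    times
        Optional explicit time stamps in seconds.  ``None`` means the track
        is uniformly sampled at ``k * dt``.
    """

    track_id: object
    dt: float
    positions: np.ndarray
    times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim == 1:
            self.positions = self.positions[:, None]
        if self.positions.ndim != 2 or self.positions.shape[1] not in (1, 2):
            raise ParameterError("positions must be (N,), (N,1) or (N,2)")
        if self.n_points < 2:
            raise ParameterError("a trajectory needs at least 2 points")
        if not np.all(np.isfinite(self.positions)):
            raise ParameterError("positions must be finite")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_points,):
                raise ParameterError("times length must match positions")
            if np.any(np.diff(self.times) <= 0):
                raise ParameterError("times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dim(self) -> int:
        return self.positions.shape[1]

    @property
    def is_uniform(self) -> bool:
        """True when sampled on the regular ``k * dt`` grid (1% tolerance)."""
        if self.times is None:
            return True
        steps = np.diff(self.times)
        return bool(np.all(np.abs(steps - self.dt) <= 0.01 * self.dt))

    def time_stamps(self) -> np.ndarray:
        if self.times is not None:
            return self.times
        return np.arange(self.n_points) * self.dt

    def coordinate(self, axis: int) -> np.ndarray:
        """Scalar series of one spatial component."""
        return self.positions[:, axis]


@dataclass
class LabeledTrajectory:
    """A trajectory with the ground-truth Hurst exponent at every point."""

    trajectory: Trajectory
    true_hurst_series: np.ndarray
    # (state, hurst, start_index, length) per dwell, bookkeeping for
    # residence-time oracles; populated by the switching simulator.
    dwells: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.true_hurst_series = np.asarray(self.true_hurst_series, dtype=float)
        if self.true_hurst_series.shape[0] != self.trajectory.n_points:
            raise ParameterError("label length must equal n_points")
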