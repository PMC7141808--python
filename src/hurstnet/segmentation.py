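"""Moving-window local Hurst estimation and state segmentation.

A symmetric window of ``Nw`` points (odd) slides along a track one point at
a time; the network's estimate for each window is assigned to the window's
center, index ``j = i + (Nw - 1) / 2`` for window start ``i``.  The local
estimates are then cut into maximal runs of persistence (``H > 0.55``) and
anti-persistence (``H < 0.45``); the band in between absorbs the
estimator's own error (sigma_H ~ 0.05) and is left unclassified, and runs
shorter than ``Nw`` are discarded as spurious.

Persistent segments of 2D tracks can be further subdivided by direction
relative to a user-supplied centrosome position: the cosine of the angle
between the radial vector (centrosome -> particle) and the step vector,
smoothed over the same window, classifies motion as anterograde (outward,
``cos > 0.3``) or retrograde (inward, ``cos < -0.3``).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ParameterError
from .network import TrainedModel, estimate_hurst_many
from .trajectory import Trajectory

__all__ = [
    "HurstSeries",
    "Segment",
    "CellGeometry",
    "windowed_hurst",
    "segment_states",
    "classify_direction",
    "count_switches",
    "filter_tracks_for_direction",
    "segment_stats",
]

PERSISTENT = "persistent"
ANTI_PERSISTENT = "anti_persistent"
UNCLASSIFIED = "unclassified"
ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"


@dataclass
class HurstSeries:
    """Local H estimates aligned to trajectory center indices."""

    window_size: int
    center_indices: np.ndarray
    h_values: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.center_indices = np.asarray(self.center_indices, dtype=int)
        self.h_values = np.asarray(self.h_values, dtype=float)
        if self.center_indices.shape != self.h_values.shape:
            raise ParameterError("center_indices and h_values must align")


@dataclass
class Segment:
    """A contiguous stretch of one motile state on a trajectory.

    Indices are inclusive trajectory indices (window centers); duration is
    the index span times dt, displacement the straight-line distance between
    the segment's endpoint positions.
    """

    state: str
    start_index: int
    end_index: int
    duration: float
    displacement: float
    mean_speed: float
    mean_h: float
    direction: Optional[str] = None
    track_id: object = None


@dataclass
class CellGeometry:
    """User-supplied reference geometry for directional analysis."""

    centrosome: Tuple[float, float]
    boundary: Optional[np.ndarray] = None


def windowed_hurst(model: TrainedModel, traj: Trajectory, window: int = 15) -> HurstSeries:
    """Local H estimates from a symmetric moving window.

    2D tracks are estimated per coordinate and the two estimates averaged.
    Windows with zero range on a coordinate give NaN there; the average
    ignores NaN components and is NaN only if both fail.
    """
    if window % 2 == 0:
        raise ParameterError("window must be odd")
    if window > traj.n_points:
        raise ParameterError("window exceeds trajectory length")
    if model.n_input != window:
        raise ParameterError(
            f"model input size {model.n_input} does not match window {window}"
        )
    half = (window - 1) // 2
    n_win = traj.n_points - window + 1
    ests = np.full((traj.n_dim, n_win), np.nan)
    for axis in range(traj.n_dim):
        x = traj.coordinate(axis)
        wins = np.lib.stride_tricks.sliding_window_view(x, window)
        ests[axis] = estimate_hurst_many(model, wins)
    with np.errstate(invalid="ignore"):
        h = np.nanmean(ests, axis=0)
    centers = np.arange(n_win) + half
    return HurstSeries(window, centers, h, dt=traj.dt)


def _runs(labels: np.ndarray) -> List[Tuple[int, int, int]]:
    """Maximal runs of equal label: (label, start, stop_exclusive)."""
    out = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            out.append((int(labels[start]), start, i))
            start = i
    return out


def _make_segment(
    state: str, lo: int, hi: int, hs: HurstSeries, traj: Optional[Trajectory]
) -> Segment:
    """Segment over h-series slots [lo, hi) mapped to trajectory indices."""
    idx = hs.center_indices
    start, end = int(idx[lo]), int(idx[hi - 1])
    duration = (end - start) * hs.dt
    mean_h = float(np.nanmean(hs.h_values[lo:hi]))
    if traj is not None:
        disp = float(np.linalg.norm(traj.positions[end] - traj.positions[start]))
        speed = disp / duration if duration > 0 else 0.0
        track_id = traj.track_id
    else:
        disp, speed, track_id = np.nan, np.nan, None
    return Segment(state, start, end, duration, disp, speed, mean_h, track_id=track_id)


def segment_states(
    hs: HurstSeries,
    lower: float = 0.45,
    upper: float = 0.55,
    min_len: Optional[int] = None,
    traj: Optional[Trajectory] = None,
    bridge_gaps: bool = False,
) -> List[Segment]:
    """Cut a local-H series into persistent / anti-persistent / unclassified
    segments.

    Classified runs shorter than ``min_len`` (default: the window size) are
    demoted to unclassified.  With ``bridge_gaps`` enabled, unclassified
    gaps shorter than ``min_len`` that are flanked by the *same* state on
    both sides are absorbed into that state: the unclassified band exists
    to soak up estimator error, so a brief excursion into it that never
    establishes the opposite state is noise, not a state change.  Bridging
    is essential for unbiased residence-time statistics (without it, long
    dwells are fragmented at a constant rate, which multiplies the dwell
    survival function by a spurious exponential factor).  Every h-series
    slot belongs to exactly one returned segment.
    """
    if lower >= upper:
        raise ParameterError("lower bound must be below upper bound")
    if min_len is None:
        min_len = hs.window_size
    h = hs.h_values
    code = np.zeros(h.size, dtype=int)  # 0 unclassified, 1 anti, 2 persistent
    with np.errstate(invalid="ignore"):
        code[h < lower] = 1
        code[h > upper] = 2
    # demote short classified runs, then merge
    for label, lo, hi in _runs(code):
        if label != 0 and hi - lo < min_len:
            code[lo:hi] = 0
    if bridge_gaps:
        changed = True
        while changed:
            changed = False
            runs = _runs(code)
            for k, (label, lo, hi) in enumerate(runs):
                if (
                    label == 0
                    and hi - lo < min_len
                    and 0 < k < len(runs) - 1
                    and runs[k - 1][0] == runs[k + 1][0] != 0
                ):
                    code[lo:hi] = runs[k - 1][0]
                    changed = True
    names = {0: UNCLASSIFIED, 1: ANTI_PERSISTENT, 2: PERSISTENT}
    return [_make_segment(names[label], lo, hi, hs, traj) for label, lo, hi in _runs(code)]


def _cos_theta(traj: Trajectory, geom: CellGeometry) -> np.ndarray:
    """cos(theta_i) between centrosome->x_i and the step x_i->x_{i+1}.

    Length N-1; NaN where either vector has zero length.
    """
    if traj.n_dim != 2:
        raise ParameterError("directional analysis needs 2D tracks")
    pos = traj.positions
    radial = pos[:-1] - np.asarray(geom.centrosome, dtype=float)
    step = pos[1:] - pos[:-1]
    num = np.sum(radial * step, axis=1)
    denom = np.linalg.norm(radial, axis=1) * np.linalg.norm(step, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = num / denom
    cos[denom == 0] = np.nan
    return cos


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered NaN-aware moving average with shrinking edges."""
    half = (window - 1) // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        seg = x[lo:hi]
        good = ~np.isnan(seg)
        out[i] = seg[good].mean() if good.any() else np.nan
    return out


def classify_direction(
    traj: Trajectory,
    segments: Sequence[Segment],
    geom: CellGeometry,
    threshold: float = 0.3,
    window: int = 15,
) -> List[Segment]:
    """Subdivide persistent segments into anterograde/retrograde runs.

    The per-step cosine is smoothed with a centered window of the same size
    as the H window; consecutive points above ``threshold`` become
    anterograde sub-segments, below ``-threshold`` retrograde, the rest stay
    unlabeled.  Non-persistent segments pass through unchanged.
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError("threshold must be in (0, 1)")
    cos_all = _moving_average(_cos_theta(traj, geom), window)
    out: List[Segment] = []
    for seg in segments:
        if seg.state != PERSISTENT:
            out.append(seg)
            continue
        idx = np.arange(seg.start_index, seg.end_index)  # step i is x_i -> x_{i+1}
        cos = cos_all[idx]
        code = np.zeros(cos.size, dtype=int)
        with np.errstate(invalid="ignore"):
            code[cos > threshold] = 1
            code[cos < -threshold] = 2
        names = {0: None, 1: ANTEROGRADE, 2: RETROGRADE}
        for label, lo, hi in _runs(code):
            start, end = int(idx[lo]), int(idx[hi - 1]) + 1
            duration = (end - start) * traj.dt
            disp = float(np.linalg.norm(traj.positions[end] - traj.positions[start]))
            out.append(
                Segment(
                    PERSISTENT,
                    start,
                    end,
                    duration,
                    disp,
                    disp / duration if duration > 0 else 0.0,
                    seg.mean_h,
                    direction=names[label],
                    track_id=traj.track_id,
                )
            )
    return out


def count_switches(segments: Sequence[Segment]) -> int:
    """Transitions between classified states, ignoring unclassified gaps."""
    states = [s.state for s in segments if s.state in (PERSISTENT, ANTI_PERSISTENT)]
    return sum(1 for a, b in zip(states[:-1], states[1:]) if a != b)


def filter_tracks_for_direction(
    tracks: Sequence[Tuple[Trajectory, Sequence[Segment]]],
    min_excursion: float = 0.5,
    window: int = 15,
    min_switches: int = 2,
) -> List[Tuple[Trajectory, Sequence[Segment]]]:
    """Keep tracks suitable for directional statistics.

    Criteria: maximum distance from the starting position exceeds
    ``min_excursion`` (micrometres), more points than the window, and more
    than ``min_switches`` transitions between classified states.
    """
    kept = []
    for traj, segments in tracks:
        excursion = float(
            np.max(np.linalg.norm(traj.positions - traj.positions[0], axis=1))
        )
        if (
            excursion > min_excursion
            and traj.n_points > window
            and count_switches(segments) > min_switches
        ):
            kept.append((traj, segments))
    return kept


def segment_stats(segments: Sequence[Segment], traj: Trajectory):
    """Tidy per-segment statistics table (pandas DataFrame).

    Displacement is the Euclidean distance between segment endpoints,
    duration the index span times dt, and mean speed their ratio.
    """
    import pandas as pd

    rows = []
    for seg in segments:
        if seg.end_index <= seg.start_index:
            raise ParameterError("zero-duration segment")
        disp = float(
            np.linalg.norm(traj.positions[seg.end_index] - traj.positions[seg.start_index])
        )
        duration = (seg.end_index - seg.start_index) * traj.dt
        rows.append(
            {
                "track_id": traj.track_id,
                "state": seg.state,
                "direction": seg.direction,
                "start_index": seg.start_index,
                "end_index": seg.end_index,
                "duration_s": duration,
                "displacement_um": disp,
                "mean_speed_um_s": disp / duration,
                "mean_h": seg.mean_h,
            }
        )
    return pd.DataFrame(rows)
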