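"""Track-file I/O.

Tracks travel as delimited text with a header row and columns
``track_id, t, x[, y]`` — time in seconds, positions in micrometres.
Labeled fixtures carry an extra ``h_true`` column.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ParameterError
from .trajectory import LabeledTrajectory, Trajectory

__all__ = ["read_tracks", "write_tracks"]

log = logging.getLogger("hurstnet")

_DT_TOLERANCE = 0.01  # 1% spread counts as uniform sampling


def read_tracks(path: Union[str, Path], sep: str = ",") -> List[Trajectory]:
    """Read trajectories from a delimited text file.

    Rows are grouped by ``track_id``; non-numeric rows and rows breaking
    time monotonicity are skipped (counts logged).  Each track's sampling
    interval is the median time step; a spread beyond 1% marks the track as
    non-uniform (its explicit ``times`` are kept).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    required = {"track_id", "t", "x"}
    if not required.issubset(df.columns):
        raise ParameterError(f"track file needs columns {sorted(required)}")
    value_cols = [c for c in ("t", "x", "y") if c in df.columns]
    coerced = df[value_cols].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        log.warning("%s: skipped %d malformed rows", path.name, int(bad.sum()))
    df = df.loc[~bad].copy()
    df[value_cols] = coerced.loc[~bad]
    if df.empty:
        raise ParameterError(f"{path}: no valid rows")

    tracks: List[Trajectory] = []
    for track_id, group in df.groupby("track_id", sort=False):
        t = group["t"].to_numpy()
        keep = np.ones(t.size, dtype=bool)
        last = -np.inf
        for i, ti in enumerate(t):
            if ti <= last:
                keep[i] = False
            else:
                last = ti
        if (~keep).any():
            log.warning(
                "track %r: dropped %d non-monotone rows", track_id, int((~keep).sum())
            )
        group = group.loc[keep]
        if len(group) < 2:
            log.warning("track %r: fewer than 2 valid points, skipped", track_id)
            continue
        t = group["t"].to_numpy()
        cols = ["x", "y"] if "y" in group.columns and group["y"].notna().all() else ["x"]
        pos = group[cols].to_numpy()
        steps = np.diff(t)
        dt = float(np.median(steps))
        uniform = np.all(np.abs(steps - dt) <= _DT_TOLERANCE * dt)
        tracks.append(
            Trajectory(track_id, dt, pos, times=None if uniform else t - t[0])
        )
    if not tracks:
        raise ParameterError(f"{path}: no usable tracks")
    return tracks


def write_tracks(
    path: Union[str, Path],
    tracks: Sequence[Union[Trajectory, LabeledTrajectory]],
    sep: str = ",",
) -> None:
    """Write trajectories (optionally labeled) as delimited text."""
    rows = []
    for item in tracks:
        labels = None
        if isinstance(item, LabeledTrajectory):
            labels = item.true_hurst_series
            traj = item.trajectory
        else:
            traj = item
        t = traj.time_stamps()
        for i in range(traj.n_points):
            row = {"track_id": traj.track_id, "t": t[i], "x": traj.positions[i, 0]}
            if traj.n_dim == 2:
                row["y"] = traj.positions[i, 1]
            if labels is not None:
                row["h_true"] = labels[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
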