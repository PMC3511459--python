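"""Trajectory fixes: reading/writing, step derivation and resampling.

A trajectory is a regularly sampled sequence of planar fixes (seconds,
meters).  Resampling at a time unit ``T`` keeps every ``T/dt``-th fix; the
observed headings and speeds of the resampled path are the observables of
the movement model: ``theta_t`` is the bearing of the displacement from
retained fix ``t`` to ``t+1`` (0 = east, ``pi/2`` = north) and ``v_t`` is its
length divided by ``T``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "StepSeries", "read_fixes", "write_fixes",
           "derive_steps", "total_length", "EARTH_RADIUS_M"]

EARTH_RADIUS_M = 6371_000.0


@dataclass(frozen=True)
class Trajectory:
    """Regularly sampled planar fixes (times in s, coordinates in m)."""

    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.xs, dtype=float)
        y = np.asarray(self.ys, dtype=float)
        if t.size < 2:
            raise ValueError("a trajectory needs at least two fixes")
        if not (t.size == x.size == y.size):
            raise ValueError("times, xs, ys must have equal length")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing (no duplicates)")
        if np.max(np.abs(dt - dt[0])) > 1e-6:
            raise ValueError("irregular sampling: resample to a constant interval first")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "xs", x)
        object.__setattr__(self, "ys", y)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_fixes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class StepSeries:
    """Headings and speeds at a fixed time unit, plus the retained fixes."""

    time_unit: float
    headings: np.ndarray          # theta_t, length n_steps
    speeds: np.ndarray            # v_t (m/s), length n_steps
    fixes: Optional[np.ndarray] = None   # retained (x, y), shape (n_steps+1, 2)
    label: str = ""

    def __post_init__(self):
        h = np.asarray(self.headings, dtype=float)
        v = np.asarray(self.speeds, dtype=float)
        if h.size != v.size:
            raise ValueError("headings and speeds must have equal length")
        object.__setattr__(self, "headings", h)
        object.__setattr__(self, "speeds", v)
        if self.fixes is not None:
            f = np.asarray(self.fixes, dtype=float)
            if f.shape != (h.size + 1, 2):
                raise ValueError("fixes must have shape (n_steps + 1, 2)")
            object.__setattr__(self, "fixes", f)

    @property
    def n_steps(self) -> int:
        return int(self.headings.size)


def _project_lonlat(lon: np.ndarray, lat: np.ndarray):
    """Local tangent-plane (equirectangular) projection about the mean
    latitude, in meters.  Convenience plumbing for small extents only."""
    lat0 = np.deg2rad(np.mean(lat))
    x = EARTH_RADIUS_M * np.cos(lat0) * np.deg2rad(lon - np.mean(lon))
    y = EARTH_RADIUS_M * np.deg2rad(lat - np.mean(lat))
    return x, y


def read_fixes(path, label: str = "") -> Trajectory:
    """Read delimited fixes (comma or tab, header row).

    Columns ``time,x,y`` are taken as seconds/meters; ``time,lon,lat`` are
    projected to a local tangent plane (this projection is plumbing — for
    serious work project externally, e.g. to UTM).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "time" not in df.columns:
        raise ValueError("input must have a 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if np.unique(t).size != t.size:
        raise ValueError("duplicate timestamps in input")
    if {"x", "y"} <= set(df.columns):
        x = df["x"].to_numpy(dtype=float)
        y = df["y"].to_numpy(dtype=float)
    elif {"lon", "lat"} <= set(df.columns):
        warnings.warn("projecting lon/lat with a local tangent plane; "
                      "use a proper projection for large extents")
        x, y = _project_lonlat(df["lon"].to_numpy(float), df["lat"].to_numpy(float))
    else:
        raise ValueError("input must have columns time,x,y or time,lon,lat")
    return Trajectory(t, x, y, label=label or str(path))


def write_fixes(traj: Trajectory, path) -> None:
    """Write fixes as CSV with columns time,x,y."""
    pd.DataFrame({"time": traj.times, "x": traj.xs, "y": traj.ys}).to_csv(
        Path(path), index=False)


def derive_steps(traj: Trajectory, time_unit: float) -> StepSeries:
    """Resample at time unit ``T`` (keeping fixes 0, T/dt, 2*T/dt, ...) and
    derive headings/speeds.  ``T`` must be an integer multiple of the sampling
    interval; trailing fixes that do not complete a step are dropped.  Steps
    with zero displacement get an undefined (NaN) heading and a warning."""
    stride_f = time_unit / traj.dt
    stride = int(round(stride_f))
    if stride < 1 or abs(stride_f - stride) > 1e-9:
        raise ValueError(
            f"time unit {time_unit} is not an integer multiple of dt={traj.dt}")
    idx = np.arange(0, traj.n_fixes, stride)
    if idx.size < 2:
        raise ValueError("time unit too coarse: fewer than two retained fixes")
    x = traj.xs[idx]
    y = traj.ys[idx]
    dx = np.diff(x)
    dy = np.diff(y)
    dist = np.hypot(dx, dy)
    headings = np.arctan2(dy, dx)
    if np.any(dist == 0):
        warnings.warn("zero-length step(s): heading undefined (NaN); "
                      "such series cannot be fitted as-is")
        headings = np.where(dist == 0, np.nan, headings)
    speeds = dist / time_unit
    return StepSeries(time_unit=float(time_unit), headings=headings,
                      speeds=speeds, fixes=np.column_stack([x, y]),
                      label=traj.label)


def total_length(traj: Trajectory) -> float:
    """Sum of consecutive Euclidean step lengths (m)."""
    return float(np.hypot(np.diff(traj.xs), np.diff(traj.ys)).sum())
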