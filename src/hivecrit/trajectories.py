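"""Trajectory ingestion, resampling, filtering, and kinetic-energy series.

Raw detections are rows (individual_id, timestamp, x, y) with absolute UNIX
timestamps in seconds.  Each individual's trajectory is resampled to a
uniform grid by linear interpolation; grid points outside the individual's
observed time span hold the nearest endpoint and are flagged as non-covered,
so that ``coverage`` (the covered fraction) can drive an inactivity filter.

Activity is measured by the per-interval "kinetic energy"

    K(t) = dx^2 + dy^2,

the squared displacement between consecutive grid points — a massless proxy
for activity level (no mass or 1/2 factor).  The hive-level series is the
per-time mean (optionally sum) of the individual energies.  All windows are
half-open [start, end) in absolute seconds.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeeTrack",
    "EnergySeries",
    "HiveActivitySeries",
    "DayNightWindow",
    "Segment",
    "TrackUnusableError",
    "read_detections",
    "resample_track",
    "filter_inactive",
    "kinetic_energy",
    "hive_activity",
    "partition_windows",
    "write_series",
    "read_series",
]


class TrackUnusableError(ValueError):
    """Fewer than 2 usable detections: the trajectory cannot be reconstructed."""


@dataclass
class BeeTrack:
    """One individual's positions on a uniform time grid t0 + i*dt."""

    individual_id: str
    t0: float
    dt: float
    x: np.ndarray
    y: np.ndarray
    coverage: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.size != self.y.size or self.x.size < 1:
            raise ValueError("x and y must have equal length >= 1")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must lie in [0, 1]")

    def __len__(self) -> int:
        return self.x.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.x.size)

    def total_displacement(self) -> float:
        if self.x.size < 2:
            return 0.0
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())


@dataclass
class EnergySeries:
    """Squared displacement per interval; element i covers [t_i, t_{i+1})."""

    individual_id: str
    t0: float
    dt: float
    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.float64)
        if (self.k < 0).any():
            raise ValueError("kinetic energy must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.k.size)


@dataclass
class HiveActivitySeries:
    t0: float
    dt: float
    k: np.ndarray
    n_individuals: int
    aggregate: str = "mean"

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.k.size)


@dataclass(frozen=True)
class DayNightWindow:
    label: str  # "day" or "night"
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError("window start must precede end")


@dataclass
class Segment:
    label: str
    times: np.ndarray
    values: np.ndarray


def read_detections(path: str | Path) -> pd.DataFrame:
    """Read a detections table; comma or tab dialect auto-detected from the header."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    expected = ["individual_id", "timestamp", "x", "y"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"expected header {expected}, got {list(df.columns)}")
    return df


def resample_track(
    detections,
    dt: float = 1.0,
    t_start: float | None = None,
    t_end: float | None = None,
    individual_id: str | None = None,
) -> BeeTrack:
    """Linear interpolation of one individual's detections onto a uniform grid.

    ``detections`` is a DataFrame (timestamp, x, y[, individual_id]) or an
    iterable of (timestamp, x, y) tuples.  Duplicate timestamps keep the
    first detection.  The grid spans [t_start, t_end] (defaults: the track's
    own observed span); grid points outside the observed span hold the
    nearest endpoint and reduce ``coverage``.
    """
    if isinstance(detections, pd.DataFrame):
        t = detections["timestamp"].to_numpy(dtype=np.float64)
        x = detections["x"].to_numpy(dtype=np.float64)
        y = detections["y"].to_numpy(dtype=np.float64)
        if individual_id is None and "individual_id" in detections:
            ids = detections["individual_id"].unique()
            if len(ids) > 1:
                raise ValueError("detections contain multiple individuals")
            individual_id = str(ids[0]) if len(ids) else "unknown"
    else:
        rows = list(detections)
        arr = np.asarray(rows, dtype=np.float64)
        if arr.size == 0:
            raise TrackUnusableError("no detections")
        t, x, y = arr[:, 0], arr[:, 1], arr[:, 2]
    if not np.isfinite(t).all() or not np.isfinite(x).all() or not np.isfinite(y).all():
        raise ValueError("detections contain non-finite values")

    order = np.argsort(t, kind="stable")
    t, x, y = t[order], x[order], y[order]
    keep = np.concatenate([[True], np.diff(t) > 0])  # first detection wins on ties
    t, x, y = t[keep], x[keep], y[keep]
    if t.size < 2:
        raise TrackUnusableError("fewer than 2 usable detections after de-duplication")
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone timestamps after de-duplication")

    lo = t[0] if t_start is None else float(t_start)
    hi = t[-1] if t_end is None else float(t_end)
    if hi < lo:
        raise ValueError("t_end must not precede t_start")
    n = int(np.floor((hi - lo) / dt)) + 1
    grid = lo + dt * np.arange(n)
    gx = np.interp(grid, t, x)  # holds endpoints outside the span
    gy = np.interp(grid, t, y)
    covered = (grid >= t[0]) & (grid <= t[-1])
    return BeeTrack(
        individual_id=individual_id or "unknown",
        t0=lo,
        dt=dt,
        x=gx,
        y=gy,
        coverage=float(covered.mean()),
    )


def filter_inactive(
    tracks: Iterable[BeeTrack],
    min_coverage: float = 0.8,
    min_total_displacement: float = 1e-9,
) -> list[BeeTrack]:
    """Keep tracks with coverage >= min_coverage AND total displacement >= threshold.

    Order is preserved; an empty result is allowed.  The displacement default
    is a tiny positive value, so perfectly motionless tracks are dropped.
    """
    if not (0.0 <= min_coverage <= 1.0):
        raise ValueError("min_coverage must lie in [0, 1]")
    if min_total_displacement < 0:
        raise ValueError("min_total_displacement must be >= 0")
    return [
        tr
        for tr in tracks
        if tr.coverage >= min_coverage and tr.total_displacement() >= min_total_displacement
    ]


def kinetic_energy(track: BeeTrack) -> EnergySeries:
    """K[i] = (x[i+1]-x[i])^2 + (y[i+1]-y[i])^2; length = len(track) - 1."""
    if len(track) < 2:
        raise ValueError("track must have at least 2 points")
    k = np.diff(track.x) ** 2 + np.diff(track.y) ** 2
    return EnergySeries(individual_id=track.individual_id, t0=track.t0, dt=track.dt, k=k)


def hive_activity(
    series: Sequence[EnergySeries],
    aggregate: str = "mean",
) -> HiveActivitySeries:
    """Elementwise mean (default) or sum of individual energy series.

    All series must share t0, dt, and length.  The mean is the default since
    every downstream statistic (Pearson r, Hurst slope) is invariant to the
    positive constant factor distinguishing it from the sum.
    """
    series = list(series)
    if not series:
        raise ValueError("need at least one energy series")
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    ref = series[0]
    for s in series[1:]:
        if s.k.size != ref.k.size or s.t0 != ref.t0 or s.dt != ref.dt:
            raise ValueError("all series must share t0, dt and length")
    stack = np.vstack([s.k for s in series])
    agg = stack.mean(axis=0) if aggregate == "mean" else stack.sum(axis=0)
    return HiveActivitySeries(
        t0=ref.t0, dt=ref.dt, k=agg, n_individuals=len(series), aggregate=aggregate
    )


def partition_windows(series, windows: Sequence[DayNightWindow]) -> list[Segment]:
    """Split a series into labelled segments by half-open windows [start, end).

    Windows must be non-overlapping.  A window with no overlap yields an
    empty segment rather than an error.
    """
    ws = sorted(windows, key=lambda w: w.start)
    for a, b in zip(ws, ws[1:]):
        if b.start < a.end:
            raise ValueError("windows must be non-overlapping")
    times = series.times
    values = series.k
    out = []
    for w in windows:
        mask = (times >= w.start) & (times < w.end)
        out.append(Segment(label=w.label, times=times[mask], values=values[mask]))
    return out


def write_series(series, path: str | Path, metadata: dict | None = None) -> None:
    """Delimited text `t,value` plus a sidecar JSON of metadata."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "value"])
        for t, v in zip(series.times, series.k):
            writer.writerow([f"{t:.6f}", repr(float(v))])
    meta = {"dt": series.dt, "t0": series.t0}
    meta["n_individuals"] = getattr(series, "n_individuals", 1)
    if metadata:
        meta.update(metadata)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a `t,value` series; returns (times, values)."""
    df = pd.read_csv(path)
    return df["t"].to_numpy(dtype=np.float64), df["value"].to_numpy(dtype=np.float64)
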