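"""Localization-table I/O, photoblinking grouping, and time windowing.

Tables follow the ThunderSTORM CSV dialect by default (header names
``frame``, ``x [nm]``, ``y [nm]``, ``uncertainty [nm]``); any remapping and
a unit scale factor can be supplied through :class:`Dialect`.

A fluorophore blinks: one molecule appears as several localizations in
nearby frames.  :func:`group_localizations` merges appearances that are
chainable by links no longer than ``max_distance`` (nm) with frame gaps of
at most ``max_off_frames`` dark frames, replacing each group by its mean
position at its first frame.  :func:`window_by_frames` then slices a live
acquisition into fixed-duration point patterns (e.g. 12,000 frames at
50 fps cut into 250-frame windows gives 48 patterns of 5 s each).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import FormatError, GeometryError, ParameterError, ParseError
from .patterns import PointPattern, Window


@dataclass(frozen=True)
class Dialect:
    """Column-name map (and coordinate unit scale) for localization CSVs."""

    frame: str = "frame"
    x: str = "x [nm]"
    y: str = "y [nm]"
    uncertainty: Optional[str] = "uncertainty [nm]"
    intensity: Optional[str] = None
    channel: Optional[str] = None
    scale: float = 1.0  # multiply raw coordinates by this to obtain nm


THUNDERSTORM = Dialect()


@dataclass(frozen=True)
class GroupingParams:
    max_off_frames: int = 3
    max_distance: float = 50.0  # nm

    def __post_init__(self) -> None:
        if self.max_off_frames < 0 or self.max_distance < 0:
            raise ParameterError("grouping thresholds must be >= 0")
        if not np.isfinite(self.max_distance):
            raise ParameterError("max_distance must be finite")


@dataclass
class LocalizationTable:
    """Per-peak records (frame, x, y, ...) plus acquisition metadata.

    ``data`` always carries columns ``frame`` (int, >= 1), ``x``, ``y`` (nm)
    and optionally ``uncertainty``, ``intensity``, ``channel`` and any extra
    columns (e.g. ground-truth emitter ids from the simulator).
    """

    data: pd.DataFrame
    window: Window
    acquisition_fps: Optional[float] = None
    n_frames: Optional[int] = None

    def __post_init__(self) -> None:
        for col in ("frame", "x", "y"):
            if col not in self.data.columns:
                raise FormatError(f"table is missing mandatory column {col!r}")
        frames = self.data["frame"].to_numpy()
        if len(frames) and frames.min() < 1:
            raise ParameterError("frame indices must be >= 1")
        if self.n_frames is None and len(frames):
            self.n_frames = int(frames.max())
        if self.n_frames is not None and len(frames) and frames.max() > self.n_frames:
            raise ParameterError("record frame exceeds n_frames")
        pts = self.data[["x", "y"]].to_numpy(dtype=float)
        if len(pts) and not self.window.contains(pts).all():
            raise GeometryError("all localizations must lie inside the window")

    @property
    def n(self) -> int:
        return len(self.data)

    def points(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def to_pattern(self, label: str = "") -> PointPattern:
        return PointPattern(self.points(), self.window, label=label)

    def select_channel(self, channel: str) -> "LocalizationTable":
        if "channel" not in self.data.columns:
            raise FormatError("table has no channel column")
        sub = self.data[self.data["channel"] == channel].reset_index(drop=True)
        return replace(self, data=sub)


def read_localizations(
    path,
    dialect: Dialect = THUNDERSTORM,
    window: Optional[Window] = None,
    fps: Optional[float] = None,
    n_frames: Optional[int] = None,
) -> LocalizationTable:
    """Read a ThunderSTORM-style CSV into a LocalizationTable.

    The observation window is inferred from the data extent unless given.
    Raises :class:`FormatError` for missing mandatory columns and
    :class:`ParseError` (with the offending row index) for non-numeric
    coordinates.
    """
    raw = pd.read_csv(path)
    colmap = {"frame": dialect.frame, "x": dialect.x, "y": dialect.y}
    for key, src in list(colmap.items()):
        if src not in raw.columns:
            raise FormatError(f"missing mandatory column {src!r} in {path}")
    optional = {"uncertainty": dialect.uncertainty, "intensity": dialect.intensity, "channel": dialect.channel}
    data = pd.DataFrame()
    for key, src in colmap.items():
        vals = pd.to_numeric(raw[src], errors="coerce")
        bad = vals.index[vals.isna() & raw[src].notna()]
        if len(bad):
            raise ParseError(f"non-numeric value in column {src!r} at row {bad[0]}")
        if vals.isna().any():
            raise ParseError(f"missing value in column {src!r} at row {vals.index[vals.isna()][0]}")
        data[key] = vals
    data["frame"] = data["frame"].astype(int)
    data["x"] *= dialect.scale
    data["y"] *= dialect.scale
    for key, src in optional.items():
        if src is not None and src in raw.columns:
            if key == "channel":
                data[key] = raw[src].astype(str)
            else:
                data[key] = pd.to_numeric(raw[src], errors="coerce")
                if key == "uncertainty":
                    data[key] *= dialect.scale
    mapped = {dialect.frame, dialect.x, dialect.y} | {
        src for src in optional.values() if src is not None
    }
    for col in raw.columns:  # carry extra columns (e.g. ground-truth ids) through
        if col not in mapped:
            data[col] = raw[col]
    if window is None:
        window = Window.from_points(data[["x", "y"]].to_numpy(dtype=float))
    return LocalizationTable(data=data, window=window, acquisition_fps=fps, n_frames=n_frames)


def write_localizations(table: LocalizationTable, path, dialect: Dialect = THUNDERSTORM) -> None:
    """Write a table back to the ThunderSTORM-style dialect (nm units)."""
    out = pd.DataFrame()
    out[dialect.frame] = table.data["frame"]
    out[dialect.x] = table.data["x"] / dialect.scale
    out[dialect.y] = table.data["y"] / dialect.scale
    if dialect.uncertainty and "uncertainty" in table.data.columns:
        out[dialect.uncertainty] = table.data["uncertainty"] / dialect.scale
    if dialect.intensity and "intensity" in table.data.columns:
        out[dialect.intensity] = table.data["intensity"]
    if dialect.channel and "channel" in table.data.columns:
        out[dialect.channel] = table.data["channel"]
    for col in table.data.columns:
        if col not in ("frame", "x", "y", "uncertainty", "intensity", "channel"):
            out[col] = table.data[col]
    out.to_csv(path, index=False)


def group_localizations(table: LocalizationTable, params: GroupingParams) -> LocalizationTable:
    """Merge blinking re-appearances of one molecule into a single record.

    Two records belong to one group iff they are connected by a chain of
    links, each with spatial distance <= max_distance and frame gap
    <= max_off_frames + 1 (i.e. at most max_off_frames dark frames between
    appearances).  Merged position is the mean of member positions; merged
    frame is the first frame; intensities sum; uncertainties average; any
    other column takes the first member's value.  The partition is
    transitive single linkage in (space, time), hence order-invariant.
    """
    if table.n == 0:
        raise ParameterError("table must be non-empty")
    df = table.data
    pts = table.points()
    frames = df["frame"].to_numpy()
    tree = cKDTree(pts)
    pairs = tree.query_pairs(params.max_distance, output_type="ndarray")
    if pairs.shape[0]:
        gap_ok = np.abs(frames[pairs[:, 0]] - frames[pairs[:, 1]]) <= params.max_off_frames + 1
        pairs = pairs[gap_ok]
    n = table.n
    if pairs.shape[0]:
        graph = coo_matrix((np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, raw_labels = connected_components(graph, directed=False)
    else:
        raw_labels = np.arange(n)
    order = np.lexsort((np.arange(n), frames))  # stable: earliest record defines group id order
    _, labels_sorted = np.unique(raw_labels[order], return_inverse=True)
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted

    grouped = df.assign(_group=labels)
    agg: Dict[str, object] = {"frame": "min", "x": "mean", "y": "mean"}
    if "uncertainty" in df.columns:
        agg["uncertainty"] = "mean"
    if "intensity" in df.columns:
        agg["intensity"] = "sum"
    for col in df.columns:
        if col not in agg and col != "_group":
            agg[col] = "first"
    merged = grouped.groupby("_group", sort=True).agg(agg)
    merged["n_locs"] = grouped.groupby("_group", sort=True).size()
    merged = merged.reset_index(drop=True)
    return LocalizationTable(
        data=merged,
        window=table.window,
        acquisition_fps=table.acquisition_fps,
        n_frames=table.n_frames,
    )


def window_by_frames(table: LocalizationTable, frames_per_window: int) -> List[PointPattern]:
    """Slice the acquisition into consecutive non-overlapping frame blocks.

    Each block becomes one PointPattern with t_start = k * frames / fps; a
    trailing partial block is dropped.
    """
    if frames_per_window < 1:
        raise ParameterError("frames_per_window must be >= 1")
    if table.acquisition_fps is None:
        raise ParameterError("acquisition_fps is required for windowing")
    if table.n_frames is None:
        raise ParameterError("n_frames is required for windowing")
    n_windows = table.n_frames // frames_per_window
    frames = table.data["frame"].to_numpy()
    block = (frames - 1) // frames_per_window
    pts = table.points()
    label = ""
    if "channel" in table.data.columns and table.data["channel"].nunique() == 1:
        label = str(table.data["channel"].iloc[0])
    dt = frames_per_window / table.acquisition_fps
    out = []
    for k in range(n_windows):
        sel = block == k
        out.append(
            PointPattern(pts[sel], table.window, label=label, t_start=k * dt, t_end=(k + 1) * dt)
        )
    return out
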