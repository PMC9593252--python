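"""Core geometric containers: observation windows and 2D point patterns.

Coordinates are continuous nanometres with the origin at the lower-left
corner of the observation window; densities are reported per square
micrometre, the unit used throughout membrane-biology work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import GeometryError, ParameterError

NM2_PER_UM2 = 1e6


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window, in nm."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (np.isfinite([self.x_min, self.y_min, self.x_max, self.y_max]).all()):
            raise ParameterError("window bounds must be finite")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ParameterError("window must have positive extent")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area_nm2(self) -> float:
        return self.width * self.height

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / NM2_PER_UM2

    @property
    def origin(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min])

    @property
    def sizes(self) -> np.ndarray:
        return np.array([self.width, self.height])

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Boolean mask of points inside the (closed) window."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (p[:, 0] >= self.x_min - atol)
            & (p[:, 0] <= self.x_max + atol)
            & (p[:, 1] >= self.y_min - atol)
            & (p[:, 1] <= self.y_max + atol)
        )

    def intersects(self, other: "Window") -> bool:
        return not (
            other.x_max <= self.x_min
            or other.x_min >= self.x_max
            or other.y_max <= self.y_min
            or other.y_min >= self.y_max
        )

    def as_tuple(self) -> tuple:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    @classmethod
    def square(cls, side: float, origin: Sequence[float] = (0.0, 0.0)) -> "Window":
        return cls(origin[0], origin[1], origin[0] + side, origin[1] + side)

    @classmethod
    def from_points(cls, points: np.ndarray, pad: float = 0.0) -> "Window":
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if p.size == 0:
            raise ParameterError("cannot infer a window from an empty point set")
        return cls(
            p[:, 0].min() - pad,
            p[:, 1].min() - pad,
            p[:, 0].max() + pad,
            p[:, 1].max() + pad,
        )


def windows_match(a: Window, b: Window, atol: float = 1e-6) -> bool:
    return np.allclose(a.as_tuple(), b.as_tuple(), atol=atol)


@dataclass
class PointPattern:
    """A set of 2D molecule coordinates (nm) in a rectangular window.

    ``t_start``/``t_end`` (seconds) are set when the pattern is one
    fixed-duration slice of a live acquisition.
    """

    points: np.ndarray
    window: Window
    label: str = ""
    t_start: Optional[float] = None
    t_end: Optional[float] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ParameterError("points must be an (n, 2) array")
        if not np.isfinite(pts).all():
            raise ParameterError("points must be finite")
        if pts.shape[0] and not self.window.contains(pts).all():
            raise GeometryError("all points must lie inside the window")
        self.points = pts

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    def __len__(self) -> int:
        return self.n

    @property
    def density(self) -> float:
        """Point density in molecules per square micrometre."""
        return self.n / self.window.area_um2

    def with_points(self, points: np.ndarray) -> "PointPattern":
        return replace(self, points=points)


def crop_roi(pattern: PointPattern, rect: Window) -> PointPattern:
    """Restrict a pattern to a rectangular ROI; the ROI becomes the new window.

    Boundary points are retained (closed rectangle).
    """
    if not isinstance(rect, Window):
        rect = Window(*rect)
    if not pattern.window.intersects(rect):
        raise GeometryError("ROI does not intersect the observation window")
    mask = rect.contains(pattern.points) if pattern.n else np.zeros(0, bool)
    return PointPattern(
        pattern.points[mask] if pattern.n else pattern.points,
        rect,
        label=pattern.label,
        t_start=pattern.t_start,
        t_end=pattern.t_end,
    )
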