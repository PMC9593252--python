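"""Fixed-radius nanodomain detection and in/out density enrichment.

One species (e.g. a GPI-anchored raft marker) is partitioned into clusters
by chaining all links shorter than a distance threshold d_th (single
linkage; default 80 nm).  Clusters are tallied into size classes
(monomers, dimers, 3-, 4-, 5-mers, larger), and clusters of at least
``min_cluster_size`` points are turned into domain polygons (convex hull
dilated by a buffer; degenerate clusters become unions of discs).  A
second species is then scored for enrichment: its density inside the
domain polygons versus outside, the fold ratio, and the fraction of its
molecules falling inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import unary_union

from .errors import DegenerateDataError, GeometryError, ParameterError
from .patterns import NM2_PER_UM2, PointPattern, windows_match

SIZE_CLASS_KEYS = ("1", "2", "3", "4", "5", "6+")


@dataclass(frozen=True)
class DomainParams:
    d_th: float = 80.0  # nm link threshold
    min_cluster_size: int = 3  # points needed for a polygonal domain
    buffer: float = 40.0  # nm dilation of the hull / disc radius

    def __post_init__(self) -> None:
        if not (self.d_th > 0):
            raise ParameterError("d_th must be > 0")
        if self.min_cluster_size < 1:
            raise ParameterError("min_cluster_size must be >= 1")
        if self.buffer < 0:
            raise ParameterError("buffer must be >= 0")


@dataclass
class DomainSet:
    pattern: PointPattern
    labels: np.ndarray  # cluster id per point
    params: DomainParams
    polygons: Optional[List] = None  # shapely polygons, one per retained cluster
    polygon_cluster_ids: Optional[np.ndarray] = None
    domain_union: Optional[object] = None  # unary union of polygons

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    @property
    def size_classes(self) -> Dict[str, int]:
        """Counts of monomers, dimers, ..., and clusters of 6 or more."""
        sizes = self.cluster_sizes
        out = {k: 0 for k in SIZE_CLASS_KEYS}
        for s in sizes:
            out[str(s) if s <= 5 else "6+"] += 1
        return out

    @property
    def total_domain_area_um2(self) -> float:
        if self.domain_union is None:
            return 0.0
        return float(self.domain_union.area) / NM2_PER_UM2

    @property
    def window_area_um2(self) -> float:
        return self.pattern.window.area_um2

    @property
    def area_fraction(self) -> float:
        return self.total_domain_area_um2 / self.window_area_um2

    def cluster_indices(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cid)


@dataclass
class EnrichmentReport:
    density_in: float  # molecules / um^2 (NaN-free; zero-area raises earlier)
    density_out: float
    fold: float
    fraction_in: float
    area_fraction: float
    n_in: int
    n_out: int
    d_th: float

    def to_dict(self) -> dict:
        return {
            "density_in_per_um2": self.density_in,
            "density_out_per_um2": self.density_out,
            "fold": self.fold,
            "fraction_in": self.fraction_in,
            "area_fraction": self.area_fraction,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "d_th_nm": self.d_th,
        }


def find_domains(pattern: PointPattern, params: Optional[DomainParams] = None) -> DomainSet:
    """Single-linkage clustering at d_th: two points share a cluster iff
    they are connected by a chain of links each <= d_th (strict: a pair at
    d_th + epsilon does not link).  Order-invariant by construction."""
    params = params or DomainParams()
    if pattern.n == 0:
        raise ParameterError("pattern must be non-empty")
    tree = cKDTree(pattern.points)
    pairs = tree.query_pairs(params.d_th, output_type="ndarray")
    n = pattern.n
    if pairs.shape[0]:
        data = np.ones(pairs.shape[0])
        graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, raw = connected_components(graph, directed=False)
    else:
        raw = np.arange(n)
    # relabel to consecutive ids in first-appearance order (deterministic)
    _, labels = np.unique(raw, return_inverse=True)
    return DomainSet(pattern=pattern, labels=labels, params=params)


def _cluster_polygon(points: np.ndarray, buffer: float):
    hull = MultiPoint(points).convex_hull
    if hull.geom_type == "Polygon":
        return hull.buffer(buffer, quad_segs=16) if buffer > 0 else hull
    # monomers, dimers, collinear clusters: union of discs around members
    if buffer > 0:
        return unary_union([Point(p).buffer(buffer, quad_segs=16) for p in points])
    return hull.buffer(0)  # degenerate, zero area


def domain_polygons(domains: DomainSet, params: Optional[DomainParams] = None) -> DomainSet:
    """Populate domain polygons for clusters of >= min_cluster_size points.

    Polygons are clipped to the observation window so domain area never
    exceeds window area."""
    params = params or domains.params
    win = domains.pattern.window
    win_box = box(win.x_min, win.y_min, win.x_max, win.y_max)
    polys, ids = [], []
    sizes = domains.cluster_sizes
    for cid in range(domains.n_clusters):
        if sizes[cid] < params.min_cluster_size:
            continue
        pts = domains.pattern.points[domains.cluster_indices(cid)]
        poly = _cluster_polygon(pts, params.buffer).intersection(win_box)
        if poly.is_empty:
            continue
        polys.append(poly)
        ids.append(cid)
    domains.polygons = polys
    domains.polygon_cluster_ids = np.asarray(ids, dtype=int)
    domains.domain_union = unary_union(polys) if polys else None
    domains.params = params
    return domains


def inout_density(domains: DomainSet, other: PointPattern) -> EnrichmentReport:
    """Density of a second species inside vs outside the domain polygons.

    Points exactly on a polygon boundary count as inside (closed polygons).
    """
    if domains.polygons is None:
        raise ParameterError("call domain_polygons before inout_density")
    if not windows_match(domains.pattern.window, other.window):
        raise GeometryError("domain pattern and probe pattern must share a window")
    area_total = domains.window_area_um2
    area_in = domains.total_domain_area_um2
    if area_in == 0:
        raise DegenerateDataError("zero total domain area: density_in undefined")
    area_out = area_total - area_in
    union = domains.domain_union
    shapely.prepare(union)
    if other.n:
        inside = shapely.covers(union, shapely.points(other.points))
        n_in = int(inside.sum())
    else:
        n_in = 0
    n_out = other.n - n_in
    density_in = n_in / area_in
    density_out = n_out / area_out if area_out > 0 else float("nan")
    fold = density_in / density_out if density_out > 0 else float("inf")
    return EnrichmentReport(
        density_in=density_in,
        density_out=density_out,
        fold=fold,
        fraction_in=n_in / other.n if other.n else float("nan"),
        area_fraction=domains.area_fraction,
        n_in=n_in,
        n_out=n_out,
        d_th=domains.params.d_th,
    )


def sensitivity_sweep(
    pattern: PointPattern,
    other: PointPattern,
    d_th_values: Sequence[float],
    base_params: Optional[DomainParams] = None,
) -> List[EnrichmentReport]:
    """Re-run the full domain/enrichment analysis at several link thresholds
    (the buffer and size cutoff are shared across thresholds)."""
    if len(d_th_values) < 1:
        raise ParameterError("need at least one threshold")
    base = base_params or DomainParams()
    reports = []
    for d_th in d_th_values:
        params = DomainParams(d_th=d_th, min_cluster_size=base.min_cluster_size, buffer=base.buffer)
        ds = domain_polygons(find_domains(pattern, params))
        reports.append(inout_density(ds, other))
    return reports
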