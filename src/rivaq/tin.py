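"""Triangulated irregular network (TIN) surfaces over scattered elevation points.

A TIN represents a piezometric surface (groundwater head) or a river
water-surface as a set of non-overlapping triangles whose vertices are the
measured points.  Each triangle defines a unique plane

    z = a*x + b*y + c

from which three attributes follow:

* ``elevation`` — mean of the three vertex elevations (m),
* ``slope``     — |grad z| = hypot(a, b), dimensionless rise/run; on a
  piezometric surface this is the hydraulic gradient *i*,
* ``aspect``    — azimuth of the *downslope* direction −grad z, in degrees
  clockwise from grid north, i.e. the direction water flows.

Coordinates must be planar projected metres; gradients are meaningless in
geographic degrees.  A flat triangle (slope 0) has no aspect and carries
``defined_aspect = False``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import LineString, Polygon
from shapely.strtree import STRtree

from .errors import (
    AmbiguousElevationError,
    DegeneratePointSetError,
    OutsideSurfaceError,
)

#: slope below this is treated as exactly flat (no defined aspect)
FLAT_SLOPE = 1e-12

#: barycentric tolerance for point-in-triangle tests (per unit bary coord)
_BARY_EPS = 1e-9


@dataclass(frozen=True)
class SurfacePoint:
    """A surveyed elevation/head point in projected metres."""

    x: float
    y: float
    z: float


@dataclass(frozen=True)
class TriangleAttributes:
    elevation: float
    slope: float
    aspect: float
    defined_aspect: bool


def _plane_aspect(a: float, b: float) -> tuple[float, bool]:
    """Azimuth of the downslope vector (−a, −b), clockwise from north."""
    if math.hypot(a, b) <= FLAT_SLOPE:
        return math.nan, False
    return math.degrees(math.atan2(-a, -b)) % 360.0, True


class TriangulatedSurface:
    """A triangulated surface with per-triangle plane attributes.

    Parameters
    ----------
    vertices : (n, 3) array of x, y, z
    triangles : (m, 3) int array of vertex indices, positively oriented
        or not (orientation is irrelevant to the fitted plane)
    kind : "piezometric" or "river_stage"
    """

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray, kind: str):
        self.vertices = np.asarray(vertices, dtype=float)
        self.triangles = np.asarray(triangles, dtype=int)
        self.kind = kind
        self._planes = self._fit_planes()
        self._bary = self._barycentric_transforms()
        self._tree: STRtree | None = None
        self._polys: list[Polygon] | None = None

    # -- construction helpers -------------------------------------------------

    def _fit_planes(self) -> np.ndarray:
        """Plane coefficients (a, b, c) per triangle, z = a x + b y + c."""
        tri = self.vertices[self.triangles]  # (m, 3, 3)
        x, y, z = tri[:, :, 0], tri[:, :, 1], tri[:, :, 2]
        # solve the 3x3 system per triangle
        ones = np.ones_like(x)
        A = np.stack([x, y, ones], axis=2)  # (m, 3, 3)
        return np.linalg.solve(A, z[..., None])[..., 0]

    def _barycentric_transforms(self) -> tuple[np.ndarray, np.ndarray]:
        tri = self.vertices[self.triangles, :2]  # (m, 3, 2)
        r3 = tri[:, 2, :]
        T = np.stack([tri[:, 0, :] - r3, tri[:, 1, :] - r3], axis=2)  # (m,2,2)
        det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
        inv = np.empty_like(T)
        inv[:, 0, 0] = T[:, 1, 1]
        inv[:, 0, 1] = -T[:, 0, 1]
        inv[:, 1, 0] = -T[:, 1, 0]
        inv[:, 1, 1] = T[:, 0, 0]
        inv /= det[:, None, None]
        return inv, r3

    # -- basic geometry -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.triangles)

    def triangle_area(self, index: int) -> float:
        p = self.vertices[self.triangles[index], :2]
        return 0.5 * abs(
            (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
            - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1])
        )

    def triangle_polygon(self, index: int) -> Polygon:
        return Polygon(self.vertices[self.triangles[index], :2])

    def _strtree(self) -> tuple[STRtree, list[Polygon]]:
        if self._tree is None:
            self._polys = [self.triangle_polygon(i) for i in range(len(self))]
            self._tree = STRtree(self._polys)
        return self._tree, self._polys  # type: ignore[return-value]

    # -- queries --------------------------------------------------------------

    def find_triangle(self, x: float, y: float) -> int:
        """Index of the triangle containing (x, y); lowest index on ties.

        Points exactly on a shared edge or vertex belong to the adjacent
        triangle with the lowest index — a deterministic tie-break.
        """
        inv, r3 = self._bary
        d = np.array([x, y]) - r3  # (m, 2)
        l1 = inv[:, 0, 0] * d[:, 0] + inv[:, 0, 1] * d[:, 1]
        l2 = inv[:, 1, 0] * d[:, 0] + inv[:, 1, 1] * d[:, 1]
        l3 = 1.0 - l1 - l2
        inside = (l1 >= -_BARY_EPS) & (l2 >= -_BARY_EPS) & (l3 >= -_BARY_EPS)
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            raise OutsideSurfaceError(
                f"outside surface extent: point ({x}, {y})"
            )
        return int(idx[0])

    def elevation_at(self, x: float, y: float) -> float:
        """Linearly interpolated surface value at (x, y)."""
        a, b, c = self._planes[self.find_triangle(x, y)]
        return float(a * x + b * y + c)


def build_tin(
    points: Iterable[SurfacePoint] | np.ndarray, kind: str = "piezometric"
) -> TriangulatedSurface:
    """Delaunay-triangulate (x, y) projections of elevation points.

    Raises
    ------
    DegeneratePointSetError
        fewer than 3 points, or all collinear.
    AmbiguousElevationError
        duplicate (x, y) locations carrying conflicting z.
    """
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float)
    else:
        arr = np.array([[p.x, p.y, p.z] for p in points], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or not np.all(np.isfinite(arr)):
        raise DegeneratePointSetError("degenerate point set: need finite (x, y, z)")

    # collapse exact duplicates; conflicting z at one location is an error
    _, first, inverse = np.unique(
        arr[:, :2], axis=0, return_index=True, return_inverse=True
    )
    if first.size < arr.shape[0]:
        for loc in range(first.size):
            zs = arr[inverse == loc, 2]
            if np.ptp(zs) > 0:
                x, y = arr[first[loc], :2]
                raise AmbiguousElevationError(
                    f"ambiguous elevation at ({x}, {y}): z values {sorted(set(zs))}"
                )
        arr = arr[np.sort(first)]

    if arr.shape[0] < 3:
        raise DegeneratePointSetError("degenerate point set: fewer than 3 points")
    try:
        dt = Delaunay(arr[:, :2])
    except QhullError as exc:
        raise DegeneratePointSetError(f"degenerate point set: {exc}") from exc
    if dt.simplices.size == 0:
        raise DegeneratePointSetError("degenerate point set: collinear points")
    return TriangulatedSurface(arr, dt.simplices, kind)


def triangle_attributes(
    surface: TriangulatedSurface, triangle_index: int
) -> TriangleAttributes:
    """Elevation, slope and downslope aspect of one triangle."""
    a, b, _ = surface._planes[triangle_index]
    slope = math.hypot(a, b)
    aspect, defined = _plane_aspect(a, b)
    if slope <= FLAT_SLOPE:
        slope = 0.0
    zmean = float(surface.vertices[surface.triangles[triangle_index], 2].mean())
    return TriangleAttributes(zmean, slope, aspect, defined)


def sample_at(surface: TriangulatedSurface, x: float, y: float) -> TriangleAttributes:
    """Attributes of the triangle containing (x, y)."""
    return triangle_attributes(surface, surface.find_triangle(x, y))


def _circular_mean_deg(angles: np.ndarray, weights: np.ndarray) -> float:
    rad = np.radians(angles)
    s = float(np.sum(weights * np.sin(rad)))
    c = float(np.sum(weights * np.cos(rad)))
    return math.degrees(math.atan2(s, c)) % 360.0


def sample_segment(
    surface: TriangulatedSurface,
    segment: Sequence[Sequence[float]],
) -> TriangleAttributes:
    """Length-weighted attributes along a straight segment ((x0, y0), (x1, y1)).

    Slope and elevation are length-weighted means over the triangles the
    segment crosses (elevation integrates the plane exactly along each
    crossed chord); aspect is the length-weighted circular mean of crossed
    triangles' aspects.  A zero-length segment degenerates to
    :func:`sample_at` of its single point.
    """
    (x0, y0), (x1, y1) = segment
    if math.hypot(x1 - x0, y1 - y0) == 0.0:
        return sample_at(surface, x0, y0)

    line = LineString([(x0, y0), (x1, y1)])
    tree, polys = surface._strtree()
    cand = sorted(int(i) for i in tree.query(line))
    weights, slopes, aspects, defined, elevs = [], [], [], [], []
    contributing: list[int] = []
    for ti in cand:
        inter = polys[ti].intersection(line)
        if inter.is_empty:
            continue
        parts = getattr(inter, "geoms", [inter])
        for part in parts:
            if not isinstance(part, LineString) or part.length == 0.0:
                continue
            mid = part.interpolate(0.5, normalized=True)
            a, b, c = surface._planes[ti]
            contributing.append(ti)
            weights.append(part.length)
            slopes.append(math.hypot(a, b))
            asp, ok = _plane_aspect(a, b)
            aspects.append(asp if ok else 0.0)
            defined.append(ok)
            elevs.append(a * mid.x + b * mid.y + c)
    if not weights:
        # segment grazes the hull or lies outside; fall back to midpoint
        return sample_at(surface, (x0 + x1) / 2.0, (y0 + y1) / 2.0)
    if len(set(contributing)) == 1:
        # whole segment in one triangle: exact midpoint lookup
        return triangle_attributes(surface, contributing[0])

    w = np.asarray(weights)
    slope = float(np.average(slopes, weights=w))
    elev = float(np.average(elevs, weights=w))
    dmask = np.asarray(defined)
    if slope <= FLAT_SLOPE or not dmask.any():
        return TriangleAttributes(elev, max(slope, 0.0) if slope > FLAT_SLOPE else 0.0,
                                  math.nan, False)
    aspect = _circular_mean_deg(np.asarray(aspects)[dmask], w[dmask])
    return TriangleAttributes(elev, slope, aspect, True)


def to_geojson(surface: TriangulatedSurface) -> dict:
    """Serialize as a GeoJSON FeatureCollection of triangle Polygons."""
    features = []
    for i in range(len(surface)):
        attrs = triangle_attributes(surface, i)
        ring = surface.vertices[surface.triangles[i], :2].tolist()
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "elevation": attrs.elevation,
                    "slope": attrs.slope,
                    "aspect": None if not attrs.defined_aspect else attrs.aspect,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(surface: TriangulatedSurface, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(to_geojson(surface), fh)
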