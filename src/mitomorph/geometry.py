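"""Planar geometry primitives for annotation morphometry.

All traced structures on a micrograph are reduced to two primitives: closed
simple polygons (interfibrillar regions, mitochondrial cross-sections, outer
membranes) and open polylines (inner-membrane / cristae traces).  Every
downstream quantity is a ratio of areas or lengths, so coordinates are plain
continuous pixel positions with no physical calibration attached; the pixel
scale cancels.

Areas use the absolute shoelace sum — annotators' winding direction is not
controlled, so orientation must not matter.  Polygon intersection (needed to
clip mitochondria to the interfibrillar region) is delegated to shapely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import shapely
import shapely.geometry as sgeom

__all__ = [
    "Point",
    "Polygon",
    "Polyline",
    "GeometryError",
    "DegeneratePolygonError",
    "SelfIntersectionError",
    "polygon_area",
    "polyline_length",
    "clip_to_region",
]

# Relative tolerance below which a polygon is considered collapsed (its area
# is negligible versus the square of its bounding-box diagonal).
_DEGENERATE_REL_AREA = 1e-12


class GeometryError(ValueError):
    """Invalid geometric input (degenerate or self-intersecting trace)."""


class DegeneratePolygonError(GeometryError):
    """Polygon with (near-)zero area: collinear or repeated vertices."""


class SelfIntersectionError(GeometryError):
    """Polygon whose boundary crosses itself."""


@dataclass(frozen=True)
class Point:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise GeometryError(f"non-finite coordinates ({self.x}, {self.y})")


def _as_array(vertices: Sequence) -> np.ndarray:
    arr = np.asarray(
        [(v.x, v.y) if isinstance(v, Point) else tuple(v) for v in vertices],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise GeometryError("vertices must be a sequence of (x, y) pairs")
    if not np.isfinite(arr).all():
        raise GeometryError("non-finite vertex coordinates")
    return arr


@dataclass(frozen=True)
class Polygon:
    """Closed contour; the last vertex connects implicitly back to the first.

    ``label`` is carried only for error messages (e.g. which traced
    mitochondrion was self-intersecting).
    """

    vertices: tuple[Point, ...]
    label: str | None = field(default=None, compare=False)

    def __init__(self, vertices: Sequence, label: str | None = None):
        arr = _as_array(vertices)
        # drop an explicitly repeated closing vertex
        if len(arr) > 1 and np.allclose(arr[0], arr[-1]):
            arr = arr[:-1]
        if len(arr) < 3:
            raise GeometryError(
                f"polygon {label or '<unnamed>'} needs >=3 distinct vertices, "
                f"got {len(arr)}"
            )
        object.__setattr__(
            self, "vertices", tuple(Point(x, y) for x, y in arr)
        )
        object.__setattr__(self, "label", label)

    @property
    def coords(self) -> np.ndarray:
        return _as_array(self.vertices)

    def to_shapely(self) -> sgeom.Polygon:
        return sgeom.Polygon(self.coords)


@dataclass(frozen=True)
class Polyline:
    """Open trace with at least two vertices."""

    vertices: tuple[Point, ...]
    label: str | None = field(default=None, compare=False)

    def __init__(self, vertices: Sequence, label: str | None = None):
        arr = _as_array(vertices)
        if len(arr) < 2:
            raise GeometryError(
                f"polyline {label or '<unnamed>'} needs >=2 vertices"
            )
        object.__setattr__(
            self, "vertices", tuple(Point(x, y) for x, y in arr)
        )
        object.__setattr__(self, "label", label)

    @property
    def coords(self) -> np.ndarray:
        return _as_array(self.vertices)


def _validated_shapely(p: Polygon) -> sgeom.Polygon:
    name = p.label or "<unnamed>"
    sp = p.to_shapely()
    if not sp.is_valid:
        # collinear vertices fold the ring onto a line: degenerate, not crossed
        xy = p.coords - p.coords[0]
        d = xy[np.argmax(np.hypot(xy[:, 0], xy[:, 1]))]
        cross = np.abs(d[0] * xy[:, 1] - d[1] * xy[:, 0])
        scale = max(np.ptp(p.coords[:, 0]), np.ptp(p.coords[:, 1]), 1.0)
        if np.all(cross <= 1e-12 * scale**2):
            raise DegeneratePolygonError(f"polygon {name} is degenerate")
        ring = sgeom.LineString(np.vstack([p.coords, p.coords[:1]]))
        if not ring.is_simple:
            raise SelfIntersectionError(
                f"polygon {name} is self-intersecting"
            )
        raise DegeneratePolygonError(f"polygon {name} is degenerate")
    return sp


def polygon_area(p: Polygon) -> float:
    """Absolute shoelace area of a simple polygon, in squared pixels.

    Orientation-independent; raises :class:`SelfIntersectionError` or
    :class:`DegeneratePolygonError` on invalid traces.
    """
    sp = _validated_shapely(p)
    xy = p.coords
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    span = max(np.ptp(x), np.ptp(y), 1.0)
    if area <= _DEGENERATE_REL_AREA * span * span:
        raise DegeneratePolygonError(
            f"polygon {p.label or '<unnamed>'} has zero area"
        )
    assert np.isclose(area, sp.area)  # shoelace and shapely must agree
    return float(area)


def polyline_length(line: Union[Polyline, Polygon]) -> float:
    """Total Euclidean length in pixels.

    For a :class:`Polygon` the closing segment is included (perimeter).
    """
    xy = line.coords
    if isinstance(line, Polygon):
        xy = np.vstack([xy, xy[:1]])
    seg = np.diff(xy, axis=0)
    length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if length <= 0.0:
        raise GeometryError(
            f"trace {line.label or '<unnamed>'} has zero length"
        )
    return length


def clip_to_region(p: Polygon, region: Union[Polygon, sgeom.base.BaseGeometry]) -> float:
    """Area of ``p`` ∩ ``region`` in squared pixels.

    Returns 0 when disjoint and ``polygon_area(p)`` when ``p`` lies inside
    the region.  ``region`` may be a :class:`Polygon` or a prepared shapely
    geometry (e.g. the union of several interfibrillar regions).
    """
    sp = _validated_shapely(p)
    if isinstance(region, Polygon):
        sregion = _validated_shapely(region)
    else:
        sregion = region
    return float(sp.intersection(sregion).area)
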