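"""Object representations, bounded domains, and signed nearest-neighbor distances.

Two populations of sub-cellular objects live in a bounded region Omega:
"query" objects X (points, e.g. virus centroids) and "reference" objects Y
(points or closed polygonal outlines, e.g. endosome outlines).  The basic
datum of the whole framework is the signed distance from each x in X to its
nearest neighbor in Y: positive outside a reference outline, negative inside
it, zero on the boundary.

All coordinates are continuous, in pixel units, with the origin at the image
corner; mask pixel (r, c) occupies the square [c, c+1) x [r, r+1) and has
center (c + 0.5, r + 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import shapely
from shapely.geometry import LinearRing, Point as ShapelyPoint, Polygon as ShapelyPolygon
from shapely.strtree import STRtree

__all__ = [
    "PointRef",
    "PolygonRef",
    "ObjectSet",
    "Domain",
    "DistanceSample",
    "signed_distance",
    "signed_nn_distances",
    "nn_distances",
    "domain_grid",
]

#: tolerance for the point-in-polygon boundary decision, in pixels
BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class PointRef:
    """A point-like reference object."""

    xy: tuple[float, float]


class PolygonRef:
    """A simple closed polygonal outline.

    Vertices are normalized so that the first vertex is not repeated at the
    end; closure is implicit.  Degenerate (fewer than 3 distinct vertices)
    or self-intersecting outlines are rejected.
    """

    __slots__ = ("vertices", "_polygon", "_ring")

    def __init__(self, vertices: Sequence[Sequence[float]]):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("polygon vertices must be an (n, 2) array")
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(np.unique(np.round(v, 12), axis=0)) < 3:
            raise ValueError("degenerate polygon: fewer than 3 distinct vertices")
        ring = LinearRing(v)
        if not ring.is_simple:
            raise ValueError("polygon outline is self-intersecting")
        self.vertices = v
        self._ring = ring
        self._polygon = ShapelyPolygon(v)
        if self._polygon.area <= 0:
            raise ValueError("degenerate polygon: zero area")

    def __repr__(self) -> str:  # pragma: no cover
        return f"PolygonRef({len(self.vertices)} vertices)"


ReferenceObject = Union[PointRef, PolygonRef]


@dataclass
class ObjectSet:
    """The two object populations of one cell: query points X and references Y."""

    X: np.ndarray  # (N, 2) float array of query point coordinates
    Y: list[ReferenceObject] = field(default_factory=list)
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.size == 0:
            self.X = self.X.reshape(0, 2)
        if self.X.shape[1] != 2:
            raise ValueError("X must be an (N, 2) array of 2D points")


class Domain:
    """The bounded region Omega, as a binary mask or a polygon.

    A mask is a 2D boolean array; True marks pixels inside Omega.  A polygon
    domain is any simple polygon in pixel coordinates.
    """

    def __init__(
        self,
        mask: np.ndarray | None = None,
        polygon: Sequence[Sequence[float]] | ShapelyPolygon | None = None,
    ):
        if (mask is None) == (polygon is None):
            raise ValueError("provide exactly one of mask or polygon")
        self.mask: np.ndarray | None = None
        self.polygon: ShapelyPolygon | None = None
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.ndim != 2:
                raise ValueError("mask must be 2D")
            if not mask.any():
                raise ValueError("domain mask has no interior pixels")
            self.mask = mask
            self.bounding_box = (float(mask.shape[1]), float(mask.shape[0]))
        else:
            poly = polygon if isinstance(polygon, ShapelyPolygon) else ShapelyPolygon(polygon)
            if poly.area <= 0:
                raise ValueError("domain polygon has non-positive area")
            self.polygon = poly
            minx, miny, maxx, maxy = poly.bounds
            self.bounding_box = (float(maxx), float(maxy))

    @classmethod
    def rectangle(cls, width: float, height: float) -> "Domain":
        """Axis-aligned rectangular domain [0, width] x [0, height]."""
        return cls(polygon=[(0, 0), (width, 0), (width, height), (0, height)])

    @property
    def area(self) -> float:
        if self.mask is not None:
            return float(self.mask.sum())
        return float(self.polygon.area)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized interior test for an (n, 2) array of points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.mask is not None:
            c = np.floor(pts[:, 0]).astype(int)
            r = np.floor(pts[:, 1]).astype(int)
            ok = (r >= 0) & (r < self.mask.shape[0]) & (c >= 0) & (c < self.mask.shape[1])
            out = np.zeros(len(pts), dtype=bool)
            out[ok] = self.mask[r[ok], c[ok]]
            return out
        return shapely.contains_xy(self.polygon, pts[:, 0], pts[:, 1])


@dataclass
class DistanceSample:
    """Observed signed NN distances D = {d_i}; the sufficient data for inference."""

    d: np.ndarray
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if self.d.size < 1:
            raise ValueError("DistanceSample requires at least one distance")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("DistanceSample contains non-finite values")

    @property
    def N(self) -> int:
        return int(self.d.size)


def _as_reference(obj) -> ReferenceObject:
    if isinstance(obj, (PointRef, PolygonRef)):
        return obj
    arr = np.asarray(obj, dtype=float)
    if arr.shape == (2,):
        return PointRef((float(arr[0]), float(arr[1])))
    return PolygonRef(arr)


def signed_nn_distances(points: np.ndarray, refs: Sequence[ReferenceObject]) -> np.ndarray:
    """Signed distance from each point to its nearest reference object.

    For point references the distance is Euclidean (always >= 0).  For
    polygonal references it is the minimum distance to the outline, negated
    when the point lies strictly inside the polygon.  The nearest neighbor is
    taken in the signed sense, so a point enclosed by an outline reports the
    (negative) distance to that outline even if another object's boundary is
    closer in absolute terms.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    refs = [_as_reference(r) for r in refs]
    if len(refs) == 0:
        raise ValueError("reference set Y is empty; distances are undefined")
    n = len(pts)
    best = np.full(n, np.inf)

    point_refs = [r for r in refs if isinstance(r, PointRef)]
    poly_refs = [r for r in refs if isinstance(r, PolygonRef)]

    if point_refs:
        ref_xy = np.array([r.xy for r in point_refs])
        from scipy.spatial import cKDTree

        d_pt, _ = cKDTree(ref_xy).query(pts, k=1)
        best = np.minimum(best, d_pt)

    if poly_refs:
        rings = [r._ring for r in poly_refs]
        polys = [r._polygon for r in poly_refs]
        geoms = shapely.points(pts)
        tree = STRtree(rings)
        inp, near = tree.query_nearest(geoms, all_matches=False)
        d_ring = np.full(n, np.inf)
        d_ring[inp] = shapely.distance(geoms[inp], np.array(rings, dtype=object)[near])

        # strictly-inside pairs: signed value is -(distance to that outline),
        # and with overlapping outlines the most negative one wins
        ptree = STRtree(polys)
        pi, pj = ptree.query(geoms, predicate="within")
        if len(pi):
            d_in = shapely.distance(geoms[pi], np.array(rings, dtype=object)[pj])
            inside_best = np.full(n, 0.0)
            np.maximum.at(inside_best, pi, d_in)
            is_inside = np.zeros(n, dtype=bool)
            is_inside[pi] = True
            # boundary tolerance: treat near-boundary "inside" hits as d = 0
            inside_best[is_inside & (inside_best < BOUNDARY_TOL)] = 0.0
            d_signed = np.where(is_inside, -inside_best, d_ring)
        else:
            d_signed = d_ring
        best = np.minimum(best, d_signed)

    return best


def signed_distance(x, y) -> float:
    """Signed distance from a single point to a single reference object."""
    return float(signed_nn_distances(np.asarray(x, dtype=float)[None, :], [y])[0])


def nn_distances(objs: ObjectSet) -> DistanceSample:
    """Signed NN distance of every query point; order follows ``objs.X``."""
    if not objs.Y:
        raise ValueError(f"cell {objs.cell_id!r}: reference set Y is empty")
    if len(objs.X) == 0:
        raise ValueError(f"cell {objs.cell_id!r}: no query points X")
    return DistanceSample(signed_nn_distances(objs.X, objs.Y), cell_id=objs.cell_id)


def domain_grid(domain: Domain, spacing: float) -> np.ndarray:
    """Cell-centered Cartesian lattice with the given spacing, clipped to Omega.

    The lattice starts at (spacing/2, spacing/2) so that each lattice point
    represents an equal-area tile of the bounding box.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    w, h = domain.bounding_box
    xs = np.arange(spacing / 2.0, w, spacing)
    ys = np.arange(spacing / 2.0, h, spacing)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("grid spacing exceeds the domain extent")
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts[domain.contains(pts)]
    if len(pts) == 0:
        raise ValueError("no grid points fall inside the domain")
    return pts
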