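"""Triangle-mesh closest-point queries and polyline utilities.

The delineation metric needs three geometric primitives on CT-derived
skull surfaces: (1) the exact closest point on a triangulated surface to an
arbitrary 3-D point, (2) projection of a digitized curve onto the surface
(pointwise closest-point "snapping"), and (3) uniform arc-length
resampling of polylines (0.25 mm is the planning default).

Closest-point queries are exact: a KD-tree over the mesh vertices gives a
guaranteed upper bound on the closest distance, a KD-tree over triangle
centroids prunes to the triangles that could beat that bound, and the
exact point–triangle distance (face/edge/vertex region classification via
``trimesh.triangles.closest_point``) decides among the survivors.  Ties
between equidistant triangles are broken by lowest triangle index, so the
query is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import NamedTuple

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "TriSurface",
    "Polyline3D",
    "SurfacePoint",
    "closest_point_on_surface",
    "project_polyline",
    "resample_polyline",
    "resample_polyline_count",
]

_MIN_TRIANGLE_AREA = 1e-12  # mm^2
_TIE_TOL = 1e-12  # mm, equidistant-triangle tie tolerance


class SurfacePoint(NamedTuple):
    """Result of a closest-point query."""

    point: np.ndarray  # (3,) foot point on the surface, mm
    distance: float  # mm
    triangle: int  # index of the supporting triangle


@dataclass(frozen=True)
class TriSurface:
    """A triangulated surface in mm.

    Invariants checked on construction: all vertex indices valid, all
    coordinates finite, no triangle with area below 1e-12 mm².
    """

    vertices: np.ndarray  # (V, 3) mm
    triangles: np.ndarray  # (F, 3) int vertex indices

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if len(v) == 0 or len(f) == 0:
            raise DegenerateInputError("surface must have vertices and triangles")
        if not np.all(np.isfinite(v)):
            raise DegenerateInputError("vertex coordinates must be finite")
        if f.min() < 0 or f.max() >= len(v):
            raise DegenerateInputError("triangle indices out of range")
        tri = v[f]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        if np.any(areas < _MIN_TRIANGLE_AREA):
            raise DegenerateInputError(
                f"{int(np.sum(areas < _MIN_TRIANGLE_AREA))} degenerate triangles "
                f"(area < {_MIN_TRIANGLE_AREA} mm^2)"
            )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", f)
        self.vertices.flags.writeable = False
        self.triangles.flags.writeable = False

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "TriSurface":
        return cls(np.asarray(mesh.vertices, float), np.asarray(mesh.faces, np.int64))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.triangles.copy(), process=False
        )

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def transformed(self, t) -> "TriSurface":
        """Surface with vertices mapped by a rigid transform."""
        return TriSurface(t.apply(self.vertices), self.triangles.copy())

    def triangle_normal(self, index: int) -> np.ndarray:
        """Unit normal of one triangle (right-handed vertex order)."""
        a, b, c = self._corners[index]
        n = np.cross(b - a, c - a)
        return n / np.linalg.norm(n)

    def triangle_normals(self, indices: np.ndarray) -> np.ndarray:
        tri = self._corners[np.asarray(indices, dtype=np.int64)]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    @cached_property
    def _corners(self) -> np.ndarray:
        """(F, 3, 3) triangle corner coordinates."""
        return self.vertices[self.triangles]

    @cached_property
    def _centroids(self) -> np.ndarray:
        return self._corners.mean(axis=1)

    @cached_property
    def _radii(self) -> np.ndarray:
        """Circumscribing radius of each triangle about its centroid."""
        return np.linalg.norm(
            self._corners - self._centroids[:, None, :], axis=2
        ).max(axis=1)

    @cached_property
    def _vertex_tree(self) -> cKDTree:
        return cKDTree(self.vertices)

    @cached_property
    def _centroid_tree(self) -> cKDTree:
        return cKDTree(self._centroids)

    def closest_points(
        self, points: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Exact closest surface points for an (N, 3) query array.

        Returns ``(feet, distances, triangle_indices)``.  The distance to the
        nearest mesh vertex bounds the answer from above; only triangles
        whose centroid lies within that bound plus the largest triangle
        radius can contain a closer point, and the exact point-triangle
        distance is evaluated on those.
        """
        P = np.atleast_2d(np.asarray(points, dtype=float))
        if P.shape[1] != 3:
            raise DegenerateInputError("query points must be (N, 3)")
        if len(P) == 0:
            return np.zeros((0, 3)), np.zeros(0), np.zeros(0, dtype=np.int64)
        upper, _ = self._vertex_tree.query(P)
        r_max = float(self._radii.max())
        # tiny slack keeps triangles exactly at the bound inside the candidate set
        radii = upper + r_max + 1e-9 * (1.0 + upper)
        cand_lists = self._centroid_tree.query_ball_point(P, radii)
        counts = np.fromiter((len(c) for c in cand_lists), dtype=np.int64, count=len(P))
        # the vertex bound guarantees every point has at least one candidate
        flat_tri = np.concatenate(
            [np.sort(np.asarray(c, dtype=np.int64)) for c in cand_lists]
        )
        flat_pts = np.repeat(P, counts, axis=0)
        feet_all = trimesh.triangles.closest_point(self._corners[flat_tri], flat_pts)
        dist_all = np.linalg.norm(feet_all - flat_pts, axis=1)
        feet = np.empty_like(P)
        dist = np.empty(len(P))
        tri_idx = np.empty(len(P), dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(counts)])
        for i in range(len(P)):
            s, e = offsets[i], offsets[i + 1]
            d = dist_all[s:e]
            dmin = d.min()
            # candidates are sorted by triangle index: the first within the
            # tie tolerance is the lowest-index equidistant triangle
            j = s + int(np.argmax(d <= dmin + _TIE_TOL))
            feet[i] = feet_all[j]
            dist[i] = dist_all[j]
            tri_idx[i] = flat_tri[j]
        return feet, dist, tri_idx

    def closest_point(self, point: np.ndarray) -> SurfacePoint:
        feet, dist, tri = self.closest_points(np.asarray(point, float).reshape(1, 3))
        return SurfacePoint(feet[0], float(dist[0]), int(tri[0]))


@dataclass(frozen=True)
class Polyline3D:
    """An ordered 3-D polyline in mm (>= 2 distinct points).

    Consecutive duplicate points are removed on construction and the arc
    length must be positive.
    """

    points: np.ndarray  # (N, 3) mm
    label: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if p.size and not np.all(np.isfinite(p)):
            raise DegenerateInputError("polyline coordinates must be finite")
        if len(p) >= 2:
            keep = np.ones(len(p), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(p, axis=0), axis=1) > 0
            p = p[keep]
        if len(p) < 2:
            raise DegenerateInputError("polyline needs >= 2 distinct points")
        object.__setattr__(self, "points", p)
        self.points.flags.writeable = False

    @cached_property
    def arclengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])

    def __len__(self) -> int:
        return len(self.points)

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Linear interpolation at arc-length parameter(s) ``s`` (clamped)."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        return np.stack(
            [np.interp(s, self.arclengths, self.points[:, k]) for k in range(3)],
            axis=-1,
        )

    def closest_param(self, point: np.ndarray) -> tuple[float, np.ndarray, float]:
        """Arc-length parameter, foot point and distance of the closest
        point on the polyline to ``point``; ties pick the smallest
        parameter."""
        p = np.asarray(point, dtype=float).reshape(3)
        a = self.points[:-1]
        b = self.points[1:]
        ab = b - a
        ab2 = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / ab2, 0.0, 1.0)
        feet = a + t[:, None] * ab
        d = np.linalg.norm(feet - p, axis=1)
        i = int(np.argmin(d))  # argmin returns the first minimum: smallest param
        s = float(self.arclengths[i] + t[i] * np.sqrt(ab2[i]))
        return s, feet[i], float(d[i])

    def slice_arclength(self, s0: float, s1: float, label: str | None = None) -> "Polyline3D":
        """Sub-polyline over the arc-length interval ``[s0, s1]``."""
        if not s0 < s1:
            raise InvalidParameterError(f"need s0 < s1, got [{s0}, {s1}]")
        s0 = max(0.0, s0)
        s1 = min(self.length, s1)
        inner = self.arclengths[(self.arclengths > s0) & (self.arclengths < s1)]
        params = np.concatenate([[s0], inner, [s1]])
        return Polyline3D(self.point_at(params), label=self.label if label is None else label)

    def transformed(self, t) -> "Polyline3D":
        return Polyline3D(t.apply(self.points), label=self.label)


def resample_polyline(curve: Polyline3D, step: float) -> Polyline3D:
    """Resample at uniform arc-length spacing ``step`` (mm).

    Both endpoints are always retained; the final spacing may be shorter
    than ``step``.  A curve shorter than one step yields just its two
    endpoints.
    """
    if not step > 0:
        raise InvalidParameterError(f"step must be > 0, got {step}")
    L = curve.length
    params = np.arange(0.0, L, step)
    if L - params[-1] > 1e-12 * max(L, 1.0):
        params = np.append(params, L)
    else:
        params[-1] = L
    if len(params) < 2:
        params = np.array([0.0, L])
    return Polyline3D(curve.point_at(params), label=curve.label)


def resample_polyline_count(curve: Polyline3D, n: int) -> Polyline3D:
    """Resample to exactly ``n`` points at uniform normalized arc length."""
    if n < 2:
        raise InvalidParameterError(f"need n >= 2, got {n}")
    params = np.linspace(0.0, curve.length, n)
    return Polyline3D(curve.point_at(params), label=curve.label)


def closest_point_on_surface(surface: TriSurface, point: np.ndarray) -> SurfacePoint:
    """Exact closest point on ``surface`` to ``point`` (foot, distance, triangle)."""
    return surface.closest_point(point)


def project_polyline(surface: TriSurface, curve: Polyline3D) -> Polyline3D:
    """Snap each curve point to its closest surface point (order preserved).

    The projection is pointwise-independent — it models digitization with a
    tracked pointer and enforces no continuity across concave gaps.
    """
    feet, _, _ = surface.closest_points(curve.points)
    return Polyline3D(feet, label=curve.label)
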