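"""Rigid transforms and named coordinate-frame graphs.

The navigation chain couples several trackers and devices, each reporting
poses in its own coordinate system: the electromagnetic tracker (``EMTS``),
the EM sensor glued to the QR marker (``QR_SENSOR``), the QR marker itself
(``QR_MARKER``), the head-mounted display (``HMD``), the patient reference
sensor (``PATIENT_SENSOR``), the CT/planning frame (``CT``) and the optical
tracker used for evaluation (``OTS``).  A :class:`RigidTransform` maps
points (mm) between two such frames; a :class:`FrameGraph` stores the
calibrated edges and resolves the composite transform along any connected
path, inverting edges traversed backwards.

Conventions: right-handed frames, millimetres, transforms stored as
rotation + translation and serialized as 4x4 homogeneous row-major
matrices.  The CT frame is defined by the mesh coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .errors import (
    FrameConsistencyError,
    InvalidTransformError,
    UnreachableFrameError,
)

__all__ = [
    "RigidTransform",
    "FrameGraph",
    "STANDARD_FRAMES",
    "compose",
    "invert",
    "transform_points",
    "resolve_frame_path",
    "random_rigid_transform",
]

#: Frames every navigation graph knows about by default.
STANDARD_FRAMES = (
    "EMTS",
    "QR_SENSOR",
    "QR_MARKER",
    "HMD",
    "PATIENT_SENSOR",
    "CT",
    "OTS",
)

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion: ``x -> R @ x + t`` with ``det(R) = +1``.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Orthonormal rotation matrix (dimensionless).
    translation : (3,) ndarray
        Translation in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3) or not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise InvalidTransformError("rotation must be a finite 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise InvalidTransformError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidTransformError("rotation has determinant -1 (reflection)")
        # re-orthonormalize to keep long compositions at machine precision
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        self.rotation.flags.writeable = False
        self.translation.flags.writeable = False

    # -- constructors -------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major, mm)."""
        M = np.asarray(matrix, dtype=float)
        if M.shape != (4, 4):
            raise InvalidTransformError(f"expected 4x4 matrix, got {M.shape}")
        if not np.allclose(M[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise InvalidTransformError("last row of homogeneous matrix must be 0 0 0 1")
        return cls(M[:3, :3], M[:3, 3])

    @classmethod
    def from_axis_angle(
        cls,
        axis: Iterable[float],
        angle_rad: float,
        translation: Iterable[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rotation of ``angle_rad`` about ``axis`` through the origin."""
        a = np.asarray(axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise InvalidTransformError("axis must be non-zero")
        a = a / n
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    # -- core operations ----------------------------------------------

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix, row-major."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``self`` first, then ``other``."""
        return RigidTransform(
            other.rotation @ self.rotation,
            other.rotation @ self.translation + other.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector) of mm points."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if p.size and not np.all(np.isfinite(p)):
            raise ValueError("points must be finite")
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        """Matrix-style composition: ``(A @ B)(x) == A(B(x))``."""
        return other.compose(self)

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        with np.printoptions(precision=4, suppress=True):
            return f"RigidTransform(t={self.translation}, R=\n{self.rotation})"


# -- functional aliases (module-level verbs used throughout the package) --


def compose(first: RigidTransform, second: RigidTransform) -> RigidTransform:
    """Applying the result equals applying ``first`` then ``second``."""
    return first.compose(second)


def invert(t: RigidTransform) -> RigidTransform:
    return t.inverse()


def transform_points(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    if p.size == 0:
        return np.zeros((0, 3))
    return t.apply(p)


def random_rigid_transform(
    rng: np.random.Generator, max_translation_mm: float = 100.0
) -> RigidTransform:
    """Uniform random rotation (QR of a Gaussian matrix, sign-fixed) plus a
    uniform translation in ``[-max_translation_mm, max_translation_mm]^3``."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    return RigidTransform(Q, t)


class FrameGraph:
    """Directed graph of named coordinate frames linked by rigid transforms.

    At most one edge exists per ordered frame pair; adding ``A -> B``
    implicitly makes ``B -> A`` resolvable as the inverse.  Resolution runs a
    breadth-first (shortest-path) search on the undirected view; when several
    distinct simple paths connect the endpoints, all of them are checked for
    mutual consistency on a unit probe and a contradiction raises
    :class:`FrameConsistencyError` rather than silently picking one.
    """

    #: agreement tolerance (mm) between alternative paths on a unit probe
    CONSISTENCY_TOL_MM = 1e-6
    #: cap on the number of alternative simple paths examined
    MAX_PATHS = 64

    def __init__(self, frames: Iterable[str] = STANDARD_FRAMES):
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(frames)

    @property
    def frames(self) -> set[str]:
        return set(self._graph.nodes)

    def add_frame(self, name: str) -> None:
        self._graph.add_node(name)

    def add_edge(
        self, source: str, target: str, transform: RigidTransform, replace: bool = False
    ) -> None:
        """Register ``transform`` as mapping points from ``source`` to ``target``."""
        if not isinstance(transform, RigidTransform):
            raise InvalidTransformError("edge label must be a RigidTransform")
        if source == target:
            raise ValueError("self-edges are not allowed")
        if not replace and self._graph.has_edge(source, target):
            raise ValueError(f"edge {source}->{target} already present (use replace=True)")
        self._graph.add_node(source)
        self._graph.add_node(target)
        self._graph.add_edge(source, target, transform=transform)

    def _edge_transform(self, a: str, b: str) -> RigidTransform:
        if self._graph.has_edge(a, b):
            return self._graph.edges[a, b]["transform"]
        return self._graph.edges[b, a]["transform"].inverse()

    def _path_transform(self, path: list[str]) -> RigidTransform:
        t = RigidTransform.identity()
        for a, b in zip(path, path[1:]):
            t = t.compose(self._edge_transform(a, b))
        return t

    def resolve(self, source: str, target: str) -> RigidTransform:
        """Composite transform mapping points in ``source`` to ``target``."""
        for name in (source, target):
            if name not in self._graph:
                raise UnreachableFrameError(f"unknown frame {name!r}")
        if source == target:
            return RigidTransform.identity()
        undirected = self._graph.to_undirected(as_view=True)
        try:
            shortest = nx.shortest_path(undirected, source, target)
        except nx.NetworkXNoPath:
            raise UnreachableFrameError(f"no path from {source!r} to {target!r}") from None
        result = self._path_transform(shortest)
        # probe alternative routes for calibration contradictions
        probe = np.vstack([np.zeros(3), np.eye(3)])  # origin + unit basis
        expected = result.apply(probe)
        for i, path in enumerate(nx.all_simple_paths(undirected, source, target)):
            if i >= self.MAX_PATHS:
                break
            if path == shortest:
                continue
            alt = self._path_transform(path).apply(probe)
            err = float(np.max(np.linalg.norm(alt - expected, axis=1)))
            if err > self.CONSISTENCY_TOL_MM:
                raise FrameConsistencyError(
                    f"paths {shortest} and {path} disagree by {err:.3g} mm"
                )
        return result


def resolve_frame_path(graph: FrameGraph, source: str, target: str) -> RigidTransform:
    return graph.resolve(source, target)
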