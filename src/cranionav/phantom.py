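"""Seeded synthesis of skull-like phantoms and measurement-noise models.

No skull mesh ships with the package; instead a parametric stand-in is
generated: the cranial vault is modeled as the upper half of an ellipsoid
(default semi-axes 70 x 55 x 50 mm, a child-skull scale), which captures
the two properties the accuracy study actually exercises — a convex
vault and a distinct anterior–posterior axis — without anatomical mesh
assets.  Real skull surfaces can be supplied from STL/PLY files instead.

Each phantom carries:

* six suture curves: the **sagittal** (midline plane section), the
  **coronal** and **lambdoid** (transverse plane sections at configurable
  fractions of the anterior–posterior axis) and three **virtual** sutures
  at evenly spaced fractions in between;
* six **anatomical landmarks** clustered on the anterior face region
  (the nose/eye region used for patient alignment) — deliberately far
  from the posterior lambdoid suture, which is what produces the
  posterior error gradient;
* a configurable number of **fiducial markers** (10 for an SK1-like
  layout, 8 for SK2-like) spread over the vault by seeded stratified
  sampling, standing in for the conical evaluation markers.

Two noise processes stand in for the measurement chain:
:func:`perturb_points` models pointer/tracker digitization error
(isotropic Gaussian per axis) and :func:`simulate_drawn_suture` models a
human tracing a displayed curve — a Gaussian displacement field in the
local tangent plane, *correlated along the curve* (pen strokes are
smooth), optionally biased sideways, and re-projected onto the surface.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import InvalidParameterError
from .mesh import Polyline3D, TriSurface, project_polyline, resample_polyline
from .registration import LabeledPointSet
from .transforms import RigidTransform, random_rigid_transform

__all__ = [
    "PhantomSpec",
    "PhantomModel",
    "NoiseSpec",
    "make_phantom",
    "perturb_points",
    "simulate_drawn_suture",
    "SUTURE_LABELS",
    "DELINEATED_SUTURES",
]

#: all suture curves carried by a phantom
SUTURE_LABELS = ("coronal", "virtual_1", "virtual_2", "virtual_3", "lambdoid", "sagittal")
#: sutures included in the delineation task (sagittal is visualized only)
DELINEATED_SUTURES = ("coronal", "virtual_1", "virtual_2", "virtual_3", "lambdoid")

#: fixed anterior landmark layout: (azimuth rad about +z from +x, elevation rad)
#: — a cluster around the nose/eye region of the anterior face
_LANDMARK_LAYOUT = {
    "nasion": (0.00, 0.30),
    "glabella": (0.00, 0.48),
    "left_orbit": (0.35, 0.38),
    "right_orbit": (-0.35, 0.38),
    "left_canthus": (0.55, 0.22),
    "right_canthus": (-0.55, 0.22),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and sampling parameters of a synthetic skull phantom.

    ``axes_mm`` are the ellipsoid semi-axes (anterior-posterior,
    left-right, inferior-superior); ``tessellation`` is the icosphere
    subdivision level (4 gives ~2.6k triangles after halving);
    ``coronal_fraction``/``lambdoid_fraction`` place the transverse suture
    planes along the AP axis in [-1, 1] (anterior positive).
    """

    name: str = "SK1"
    axes_mm: tuple[float, float, float] = (70.0, 55.0, 50.0)
    n_fiducials: int = 10
    tessellation: int = 4
    coronal_fraction: float = 0.35
    lambdoid_fraction: float = -0.55
    suture_spacing_mm: float = 0.25  # the planning resample step

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.axes_mm) or len(self.axes_mm) != 3:
            raise InvalidParameterError(f"invalid ellipsoid axes {self.axes_mm}")
        if self.n_fiducials < 4:
            raise InvalidParameterError("need >= 4 fiducials")
        if self.tessellation < 3:
            raise InvalidParameterError("tessellation level must be >= 3")
        if not -1.0 < self.lambdoid_fraction < self.coronal_fraction < 1.0:
            raise InvalidParameterError(
                "need -1 < lambdoid_fraction < coronal_fraction < 1"
            )
        if self.suture_spacing_mm <= 0:
            raise InvalidParameterError("suture_spacing_mm must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise channels of the simulated measurement chain (all mm).

    ``digitization_sigma``: isotropic per-axis sd of tracked-pointer
    point measurements.  ``delineation_sigma``: marginal sd of the
    in-tangent-plane displacement field of a human tracing a curve;
    ``delineation_correlation_length``: arc-length scale over which that
    field is correlated; ``systematic_offset``: signed constant bias
    perpendicular to the curve within the tangent plane.
    """

    digitization_sigma: float = 0.0
    delineation_sigma: float = 0.0
    delineation_correlation_length: float = 20.0
    systematic_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.digitization_sigma < 0 or self.delineation_sigma < 0:
            raise InvalidParameterError("sigmas must be >= 0")
        if self.delineation_correlation_length <= 0:
            raise InvalidParameterError("correlation length must be > 0")


@dataclass(frozen=True)
class PhantomModel:
    """A generated phantom: surface, sutures, landmarks, fiducials, pose."""

    spec: PhantomSpec
    seed: int
    surface: TriSurface
    sutures: dict[str, Polyline3D]
    anatomical_landmarks: LabeledPointSet
    fiducials: LabeledPointSet
    patient_sensor_pose: RigidTransform

    @property
    def name(self) -> str:
        return self.spec.name


def _half_ellipsoid_mesh(axes: tuple[float, float, float], tessellation: int) -> TriSurface:
    """Upper half (z >= 0) of a triangulated ellipsoid."""
    sphere = trimesh.creation.icosphere(subdivisions=tessellation)
    sphere.vertices = sphere.vertices * np.asarray(axes)
    half = trimesh.intersections.slice_mesh_plane(
        sphere, plane_normal=[0.0, 0.0, 1.0], plane_origin=[0.0, 0.0, 0.0]
    )
    # slicing can leave sliver triangles along the cut; drop them
    tri = half.triangles
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    half.update_faces(areas > 1e-9)
    half.remove_unreferenced_vertices()
    return TriSurface.from_trimesh(half)


def _transverse_section(
    axes: tuple[float, float, float], fraction: float, spacing: float, label: str
) -> Polyline3D:
    """Analytic section of the upper half-ellipsoid by the plane x = fraction * a."""
    a, b, c = axes
    x0 = fraction * a
    scale = np.sqrt(max(1.0 - fraction**2, 1e-12))
    by, cz = b * scale, c * scale
    # quarter-ellipse perimeter estimate -> number of samples at ~spacing
    perimeter = np.pi * np.sqrt((by**2 + cz**2) / 2.0)
    n = max(int(np.ceil(perimeter / spacing)) + 1, 8)
    theta = np.linspace(0.0, np.pi, n)  # left ear over the vault to right ear
    pts = np.column_stack(
        [np.full(n, x0), by * np.cos(theta), cz * np.sin(theta)]
    )
    return Polyline3D(pts, label=label)


def _sagittal_section(
    axes: tuple[float, float, float],
    anterior_fraction: float,
    posterior_fraction: float,
    spacing: float,
) -> Polyline3D:
    """Midline (y = 0) arc from the coronal plane back to the lambdoid plane."""
    a, _, c = axes
    phi0 = np.arccos(np.clip(anterior_fraction, -1.0, 1.0))
    phi1 = np.arccos(np.clip(posterior_fraction, -1.0, 1.0))
    arc = abs(phi1 - phi0) * np.sqrt((a**2 + c**2) / 2.0)
    n = max(int(np.ceil(arc / spacing)) + 1, 8)
    phi = np.linspace(phi0, phi1, n)
    pts = np.column_stack([a * np.cos(phi), np.zeros(n), c * np.sin(phi)])
    return Polyline3D(pts, label="sagittal")


def _ellipsoid_point(
    axes: tuple[float, float, float], azimuth: float, elevation: float
) -> np.ndarray:
    a, b, c = axes
    ce = np.cos(elevation)
    return np.array(
        [a * ce * np.cos(azimuth), b * ce * np.sin(azimuth), c * np.sin(elevation)]
    )


def make_phantom(spec: PhantomSpec, seed: int) -> PhantomModel:
    """Generate a phantom deterministically from ``(spec, seed)``.

    Sutures, landmarks and fiducials are constructed analytically on the
    ellipsoid and then projected onto the faceted mesh, so every carried
    point lies on the generated surface (within projection round-off).
    """
    rng = np.random.default_rng(seed)
    surface = _half_ellipsoid_mesh(spec.axes_mm, spec.tessellation)

    # suture curves: analytic plane sections, resampled, snapped to the mesh
    fractions = {"coronal": spec.coronal_fraction, "lambdoid": spec.lambdoid_fraction}
    virt = np.linspace(spec.coronal_fraction, spec.lambdoid_fraction, 5)[1:4]
    for k, f in enumerate(virt, start=1):
        fractions[f"virtual_{k}"] = float(f)
    sutures: dict[str, Polyline3D] = {}
    for label, f in fractions.items():
        curve = _transverse_section(spec.axes_mm, f, spec.suture_spacing_mm, label)
        sutures[label] = project_polyline(
            surface, resample_polyline(curve, spec.suture_spacing_mm)
        )
    sag = _sagittal_section(
        spec.axes_mm, spec.coronal_fraction, spec.lambdoid_fraction, spec.suture_spacing_mm
    )
    sutures["sagittal"] = project_polyline(
        surface, resample_polyline(sag, spec.suture_spacing_mm)
    )

    # six anterior anatomical landmarks (nose/eye region), snapped to the mesh
    lm_pos = np.array(
        [_ellipsoid_point(spec.axes_mm, az, el) for az, el in _LANDMARK_LAYOUT.values()]
    )
    feet, _, _ = surface.closest_points(lm_pos)
    landmarks = LabeledPointSet(tuple(_LANDMARK_LAYOUT), feet)

    # fiducials: stratified in azimuth over the vault, seeded jitter
    n_f = spec.n_fiducials
    az_edges = np.linspace(0.0, 2.0 * np.pi, n_f + 1)
    az = az_edges[:-1] + rng.uniform(0.15, 0.85, n_f) * np.diff(az_edges)
    el = rng.uniform(0.35, 1.05, n_f)  # keep markers on the vault, off the cut rim
    fid_pos = np.array(
        [_ellipsoid_point(spec.axes_mm, a_, e_) for a_, e_ in zip(az, el)]
    )
    feet, _, _ = surface.closest_points(fid_pos)
    fiducials = LabeledPointSet(tuple(f"M{i + 1}" for i in range(n_f)), feet)

    pose = random_rigid_transform(rng, max_translation_mm=200.0)
    return PhantomModel(
        spec=spec,
        seed=seed,
        surface=surface,
        sutures=sutures,
        anatomical_landmarks=landmarks,
        fiducials=fiducials,
        patient_sensor_pose=pose,
    )


def perturb_points(points: LabeledPointSet, sigma: float, seed: int) -> LabeledPointSet:
    """Add independent zero-mean Gaussian offsets, sd ``sigma`` per axis (mm)."""
    if sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=points.positions.shape)
    return LabeledPointSet(points.labels, points.positions + noise)


def _smoothed_unit_field(
    rng: np.random.Generator, arclengths: np.ndarray, correlation_length: float
) -> np.ndarray:
    """A Gaussian field along the curve with unit marginal sd.

    White noise at the sample points is convolved with a Gaussian kernel
    of scale ``correlation_length`` (arc-length units) and rescaled per
    sample so the marginal sd is exactly 1 despite edge truncation.
    """
    z = rng.standard_normal(len(arclengths))
    d = arclengths[:, None] - arclengths[None, :]
    w = np.exp(-0.5 * (d / correlation_length) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    field = w @ z
    return field / np.sqrt(np.sum(w**2, axis=1))


def simulate_drawn_suture(
    surface: TriSurface,
    reference: Polyline3D,
    noise: NoiseSpec,
    seed: int,
    step: float = 0.25,
) -> Polyline3D:
    """Simulate a human delineation of ``reference`` on ``surface``.

    The reference is projected and resampled at ``step``; each sample is
    displaced in the local tangent plane by a correlated Gaussian field
    (independent along-curve and cross-curve components, marginal sd
    ``delineation_sigma``, correlation length
    ``delineation_correlation_length``) plus ``systematic_offset``
    applied cross-curve; the displaced points are re-projected onto the
    surface.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    base = resample_polyline(project_polyline(surface, reference), step)
    pts = base.points
    if (
        noise.delineation_sigma == 0.0
        and noise.systematic_offset == 0.0
    ):
        return Polyline3D(pts, label=reference.label)

    # local frame: curve tangent and in-tangent-plane normal ("cross-curve")
    tangents = np.gradient(pts, base.arclengths, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    _, _, tri_idx = surface.closest_points(pts)
    normals = surface.triangle_normals(tri_idx)
    cross = np.cross(normals, tangents)
    cross /= np.linalg.norm(cross, axis=1, keepdims=True)

    sigma = noise.delineation_sigma
    corr = noise.delineation_correlation_length
    along = sigma * _smoothed_unit_field(rng, base.arclengths, corr)
    perp = sigma * _smoothed_unit_field(rng, base.arclengths, corr)
    perp = perp + noise.systematic_offset
    displaced = pts + along[:, None] * tangents + perp[:, None] * cross
    drawn = project_polyline(surface, Polyline3D(displaced, label=reference.label))
    return drawn
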