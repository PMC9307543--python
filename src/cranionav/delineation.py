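"""The suture-delineation distance metric d = S_A / D_L.

A drawn (digitized) suture is compared to the planned (CT-annotated)
suture by the area-based distance

    d = S_A / D_L                                   (mm)

where ``S_A`` (mm²) is the surface area spanned between the overlapping
parts of the two curves and ``D_L`` (mm) is the length of the overlap.
For parallel curves at constant separation h with full overlap this
reduces exactly to d = h; in general it is the mean separation weighted
along the overlap.

Pipeline per pair: both curves are projected onto the skull surface and
resampled at a uniform step (0.25 mm planning default), the reference is
clipped to the arc-length interval its curve shares with the drawn one
(and vice versa), and the strip between the clipped curves is triangulated
between index-matched resampled points to measure ``S_A``.

Conventions chosen here (the metric's definition leaves them open):
``D_L`` is measured along the clipped *reference* curve; ``S_A`` is the
3-D area of the ruled triangle strip between corresponding points (split
along the shorter diagonal), not a geodesic area on the mesh; and
correspondence is by uniform normalized arc length after clipping, not by
closest-point re-matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidParameterError, NoOverlapError
from .mesh import (
    Polyline3D,
    TriSurface,
    project_polyline,
    resample_polyline,
    resample_polyline_count,
)

__all__ = [
    "DelineationError",
    "clip_to_overlap",
    "spanned_area",
    "delineation_distance",
    "DEFAULT_STEP_MM",
]

#: default resampling step along suture curves, mm
DEFAULT_STEP_MM = 0.25


@dataclass(frozen=True)
class DelineationError:
    """Delineation error for one reference/drawn suture pair.

    ``distance = spanned_area / overlap_length`` exactly (float division);
    ``overlap_fraction`` is the overlap length over the full reference
    length, in [0, 1].
    """

    spanned_area: float  # S_A, mm^2
    overlap_length: float  # D_L, mm
    overlap_fraction: float
    reference_label: str = ""
    drawn_label: str = ""
    distance: float = field(init=False)  # d, mm

    def __post_init__(self) -> None:
        if self.spanned_area < 0 or self.overlap_length <= 0:
            raise DegenerateInputError("need S_A >= 0 and D_L > 0")
        if not 0.0 <= self.overlap_fraction <= 1.0 + 1e-12:
            raise DegenerateInputError("overlap_fraction must be in [0, 1]")
        object.__setattr__(self, "distance", self.spanned_area / self.overlap_length)


def clip_to_overlap(
    reference: Polyline3D,
    drawn: Polyline3D,
    min_overlap: float = DEFAULT_STEP_MM,
) -> tuple[Polyline3D, Polyline3D, float]:
    """Clip both curves to their mutually overlapping arc-length spans.

    The reference is clipped to ``[t0, t1]``, the (ordered) arc-length
    parameters of the closest reference points to the drawn curve's two
    endpoints; the drawn curve is clipped symmetrically against the
    reference's endpoints.  Returns the clipped curves and the overlap
    length ``D_L = t1 - t0`` measured on the reference.

    Raises
    ------
    NoOverlapError
        If the overlap span on either curve is below ``min_overlap`` mm
        (e.g. the drawn curve lies entirely beyond one end of the
        reference, so both its endpoints project to the same reference
        endpoint).
    """
    t0, _, _ = reference.closest_param(drawn.points[0])
    t1, _, _ = reference.closest_param(drawn.points[-1])
    t0, t1 = sorted((t0, t1))
    u0, _, _ = drawn.closest_param(reference.points[0])
    u1, _, _ = drawn.closest_param(reference.points[-1])
    u0, u1 = sorted((u0, u1))
    overlap = t1 - t0
    if overlap < min_overlap or (u1 - u0) < min(min_overlap, 1e-9):
        raise NoOverlapError(
            f"overlap span {overlap:.4g} mm below minimum {min_overlap:.4g} mm"
        )
    return (
        reference.slice_arclength(t0, t1),
        drawn.slice_arclength(u0, u1),
        float(overlap),
    )


def _triangle_areas(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)


def spanned_area(
    reference_clipped: Polyline3D, drawn_clipped: Polyline3D, step: float = DEFAULT_STEP_MM
) -> float:
    """Area (mm²) of the ruled strip between two clipped curves.

    Both curves are resampled to the same point count
    ``N = ceil(max(L1, L2) / step) + 1`` at uniform normalized arc length;
    points correspond by index; each quad between consecutive
    correspondence pairs is split into two triangles along its shorter
    diagonal and the triangle areas are summed.
    """
    if not step > 0:
        raise InvalidParameterError(f"step must be > 0, got {step}")
    L = max(reference_clipped.length, drawn_clipped.length)
    if L <= 0:
        raise DegenerateInputError("clipped curves must have positive length")
    n = int(np.ceil(L / step)) + 1
    n = max(n, 2)
    a = resample_polyline_count(reference_clipped, n).points
    b = resample_polyline_count(drawn_clipped, n).points
    a0, a1 = a[:-1], a[1:]
    b0, b1 = b[:-1], b[1:]
    diag_a0b1 = np.linalg.norm(a0 - b1, axis=1)
    diag_a1b0 = np.linalg.norm(a1 - b0, axis=1)
    use_a0b1 = diag_a0b1 <= diag_a1b0
    # split along the shorter diagonal of the quad (a0, b0, b1, a1)
    area_1 = np.where(
        use_a0b1,
        _triangle_areas(a0, b0, b1),
        _triangle_areas(a0, b0, a1),
    )
    area_2 = np.where(
        use_a0b1,
        _triangle_areas(a0, b1, a1),
        _triangle_areas(a1, b0, b1),
    )
    return float(np.sum(area_1 + area_2))


def delineation_distance(
    surface: TriSurface,
    reference: Polyline3D,
    drawn: Polyline3D,
    step: float = DEFAULT_STEP_MM,
) -> DelineationError:
    """Full scoring pipeline for one reference/drawn suture pair.

    Projects both curves onto ``surface``, resamples them at ``step``,
    clips them to their mutual overlap, and returns
    ``d = S_A / D_L`` with the supporting quantities.
    """
    if not step > 0:
        raise InvalidParameterError(f"step must be > 0, got {step}")
    # project, resample, then re-project: resampling interpolates on chords,
    # so a final snap keeps both sample sets on the surface (symmetric
    # treatment; a no-op on planar patches)
    ref_s = project_polyline(
        surface, resample_polyline(project_polyline(surface, reference), step)
    )
    drw_s = project_polyline(
        surface, resample_polyline(project_polyline(surface, drawn), step)
    )
    ref_clip, drw_clip, d_l = clip_to_overlap(ref_s, drw_s, min_overlap=step)
    s_a = spanned_area(ref_clip, drw_clip, step)
    return DelineationError(
        spanned_area=s_a,
        overlap_length=d_l,
        overlap_fraction=min(d_l / ref_s.length, 1.0),
        reference_label=reference.label,
        drawn_label=drawn.label,
    )
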