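"""Closest-point queries, curve projection and arc-length resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cranionav import (
    DegenerateInputError,
    InvalidParameterError,
    Polyline3D,
    TriSurface,
    closest_point_on_surface,
    project_polyline,
    random_rigid_transform,
    resample_polyline,
    resample_polyline_count,
)

from conftest import make_sphere_surface


def oracle_point_triangle_distances(p: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """Independent exact point-triangle distance, vectorized over triangles.

    Formulated differently from the implementation: the unconstrained
    in-plane foot is taken when its barycentric coordinates are feasible,
    otherwise the minimum over the three clamped edge-segment projections.
    """
    a, b, c = corners[:, 0], corners[:, 1], corners[:, 2]
    e0, e1 = b - a, c - a
    d00 = np.einsum("ij,ij->i", e0, e0)
    d01 = np.einsum("ij,ij->i", e0, e1)
    d11 = np.einsum("ij,ij->i", e1, e1)
    w = p - a
    d20 = np.einsum("ij,ij->i", w, e0)
    d21 = np.einsum("ij,ij->i", w, e1)
    denom = d00 * d11 - d01**2
    s = (d11 * d20 - d01 * d21) / denom
    t = (d00 * d21 - d01 * d20) / denom
    inside = (s >= 0) & (t >= 0) & (s + t <= 1)
    foot = a + s[:, None] * e0 + t[:, None] * e1
    d_face = np.where(inside, np.linalg.norm(p - foot, axis=1), np.inf)

    def seg_dist(u, v):
        uv = v - u
        tt = np.clip(np.einsum("ij,ij->i", p - u, uv) / np.einsum("ij,ij->i", uv, uv), 0, 1)
        return np.linalg.norm(p - (u + tt[:, None] * uv), axis=1)

    d_edges = np.minimum(np.minimum(seg_dist(a, b), seg_dist(b, c)), seg_dist(c, a))
    return np.minimum(d_face, d_edges)


class TestClosestPoint:
    def test_mesh_vertex_maps_to_itself(self, planar_surface):
        v = planar_surface.vertices[17]
        sp = closest_point_on_surface(planar_surface, v)
        assert sp.distance < 1e-12
        np.testing.assert_allclose(sp.point, v, atol=1e-12)

    def test_perpendicular_foot_above_planar_patch(self, planar_surface):
        p = np.array([40.0, 5.0, 2.0])
        sp = closest_point_on_surface(planar_surface, p)
        assert sp.distance == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(sp.point, [40.0, 5.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("surface_kind", ["sphere", "phantom"])
    def test_matches_exhaustive_oracle(self, surface_kind, sphere_surface, small_phantom):
        surface = sphere_surface if surface_kind == "sphere" else small_phantom.surface
        rng = np.random.default_rng(21)
        lo, hi = surface.vertices.min(axis=0), surface.vertices.max(axis=0)
        pts = rng.uniform(lo - 10, hi + 10, size=(100, 3))
        feet, dist, tri = surface.closest_points(pts)
        corners = surface.vertices[surface.triangles]
        for p, d in zip(pts, dist):
            d_all = oracle_point_triangle_distances(p, corners)
            assert d == pytest.approx(float(d_all.min()), abs=1e-9)

    def test_result_never_beats_vertex_distances(self, sphere_surface):
        rng = np.random.default_rng(22)
        pts = rng.uniform(-90, 90, size=(50, 3))
        _, dist, _ = sphere_surface.closest_points(pts)
        for p, d in zip(pts, dist):
            vmin = np.linalg.norm(sphere_surface.vertices - p, axis=1).min()
            assert d <= vmin + 1e-12

    def test_tie_breaks_to_lowest_triangle_index(self):
        # a point exactly above a shared edge is equidistant to both faces
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        faces = np.array([[0, 1, 3], [0, 3, 2]])
        surf = TriSurface(verts, faces)
        sp = closest_point_on_surface(surf, np.array([0.5, 0.5, 1.0]))
        assert sp.triangle == 0

    def test_invariants_rejected(self):
        with pytest.raises(DegenerateInputError):
            TriSurface(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)  # collinear
        with pytest.raises(DegenerateInputError):
            TriSurface(verts, np.array([[0, 1, 2]]))
        good = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        with pytest.raises(DegenerateInputError):
            TriSurface(good, np.array([[0, 1, 5]]))


class TestProjection:
    def test_on_surface_curve_unchanged(self, planar_surface):
        curve = Polyline3D(np.array([[0, 0, 0], [30, 5, 0], [80, -2, 0]], float))
        out = project_polyline(planar_surface, curve)
        np.testing.assert_allclose(out.points, curve.points, atol=1e-9)

    def test_offset_curve_drops_to_footprint(self, planar_surface):
        pts = np.array([[10.0, 0.0, 4.0], [50.0, 5.0, 4.0], [90.0, 10.0, 4.0]])
        out = project_polyline(planar_surface, Polyline3D(pts))
        expected = pts.copy()
        expected[:, 2] = 0.0
        np.testing.assert_allclose(out.points, expected, atol=1e-9)

    def test_radial_projection_onto_sphere_within_chord_bound(self):
        # analytic oracle: projection of an external point onto a sphere is
        # radial; the faceted mesh can differ by at most the chord height
        surface = make_sphere_surface(radius=60.0, subdivisions=4)
        corners = surface.vertices[surface.triangles]
        sides = np.stack(
            [np.linalg.norm(corners[:, i] - corners[:, (i + 1) % 3], axis=1) for i in range(3)]
        )
        areas = 0.5 * np.linalg.norm(
            np.cross(corners[:, 1] - corners[:, 0], corners[:, 2] - corners[:, 0]), axis=1
        )
        circumradius = (sides.prod(axis=0) / (4 * areas)).max()
        edge_len = sides.max()
        # max gap between a facet and the sphere: at the circumcenter
        chord_height = 60.0 - np.sqrt(60.0**2 - circumradius**2)
        rng = np.random.default_rng(23)
        dirs = rng.normal(size=(40, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        external = dirs * 75.0
        feet, _, _ = surface.closest_points(external)
        radial = dirs * 60.0
        err = np.linalg.norm(feet - radial, axis=1)
        assert err.max() < 2 * edge_len  # lateral slide within one facet
        # radial distance error is bounded by the chord height
        assert np.abs(np.linalg.norm(feet, axis=1) - 60.0).max() < chord_height + 1e-9

    def test_projection_idempotent(self, small_phantom):
        rng = np.random.default_rng(24)
        curve = Polyline3D(rng.uniform(-40, 40, size=(25, 3)) + [0, 0, 40])
        once = project_polyline(small_phantom.surface, curve)
        twice = project_polyline(small_phantom.surface, once)
        np.testing.assert_allclose(twice.points, once.points, atol=1e-9)


class TestResampling:
    def test_straight_segment_arithmetic(self):
        seg = Polyline3D(np.array([[0, 0, 0], [10, 0, 0]], float))
        out = resample_polyline(seg, 0.25)
        assert len(out) == 41
        spacing = np.linalg.norm(np.diff(out.points, axis=0), axis=1)
        np.testing.assert_allclose(spacing, 0.25, atol=1e-12)

    def test_endpoints_always_retained(self):
        curve = Polyline3D(np.array([[0, 0, 0], [3, 4, 0], [3, 4, 7.3]], float))
        out = resample_polyline(curve, 0.4)
        np.testing.assert_allclose(out.points[0], curve.points[0], atol=1e-12)
        np.testing.assert_allclose(out.points[-1], curve.points[-1], atol=1e-12)

    def test_curve_shorter_than_step_gives_endpoints(self):
        seg = Polyline3D(np.array([[0, 0, 0], [1, 0, 0]], float))
        out = resample_polyline(seg, 5.0)
        assert len(out) == 2
        np.testing.assert_allclose(out.points, seg.points, atol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_length_bounds_for_random_polylines(self, seed):
        # chords never exceed arcs, and the resampled curve still connects
        # the original endpoints, so its length is bracketed
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(scale=3.0, size=(int(rng.integers(2, 20)), 3)), axis=0)
        try:
            curve = Polyline3D(pts)
        except DegenerateInputError:
            return
        step = float(rng.uniform(0.05, 2.0))
        out = resample_polyline(curve, step)
        assert out.length <= curve.length + 1e-9
        assert out.length >= np.linalg.norm(curve.points[-1] - curve.points[0]) - 1e-9

    def test_length_loss_below_one_step_on_smooth_curve(self):
        theta = np.linspace(0, np.pi, 2000)
        arc = Polyline3D(np.column_stack([50 * np.cos(theta), 50 * np.sin(theta), 5 * theta]))
        for step in (0.1, 0.5, 1.0, 2.0):
            out = resample_polyline(arc, step)
            assert 0 <= arc.length - out.length < step

    def test_length_converges_monotonically(self):
        theta = np.linspace(0, np.pi, 200)
        arc = Polyline3D(np.column_stack([50 * np.cos(theta), 50 * np.sin(theta), theta]))
        lengths = [resample_polyline(arc, s).length for s in (1.0, 0.5, 0.25, 0.125)]
        assert all(a <= b + 1e-12 for a, b in zip(lengths, lengths[1:]))
        assert arc.length - lengths[-1] < 0.125

    def test_count_resampling(self):
        seg = Polyline3D(np.array([[0, 0, 0], [10, 0, 0]], float))
        out = resample_polyline_count(seg, 5)
        np.testing.assert_allclose(out.points[:, 0], [0, 2.5, 5, 7.5, 10], atol=1e-12)

    def test_invalid_step_rejected(self):
        seg = Polyline3D(np.array([[0, 0, 0], [1, 0, 0]], float))
        with pytest.raises(InvalidParameterError):
            resample_polyline(seg, 0.0)
        with pytest.raises(InvalidParameterError):
            resample_polyline(seg, -1.0)


class TestPolyline:
    def test_consecutive_duplicates_removed(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        assert len(Polyline3D(pts)) == 3

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            Polyline3D(np.array([[1.0, 2.0, 3.0]]))
        with pytest.raises(DegenerateInputError):
            Polyline3D(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))

    def test_closest_param_on_segment(self):
        seg = Polyline3D(np.array([[0, 0, 0], [10, 0, 0]], float))
        s, foot, d = seg.closest_param(np.array([3.0, 4.0, 0.0]))
        assert s == pytest.approx(3.0)
        assert d == pytest.approx(4.0)
        np.testing.assert_allclose(foot, [3, 0, 0], atol=1e-12)

    def test_closest_param_clamps_to_ends(self):
        seg = Polyline3D(np.array([[0, 0, 0], [10, 0, 0]], float))
        s, _, _ = seg.closest_param(np.array([-5.0, 1.0, 0.0]))
        assert s == 0.0
        s, _, _ = seg.closest_param(np.array([25.0, 1.0, 0.0]))
        assert s == pytest.approx(10.0)

    def test_rigid_motion_preserves_length(self):
        rng = np.random.default_rng(25)
        curve = Polyline3D(np.cumsum(rng.normal(size=(12, 3)), axis=0))
        T = random_rigid_transform(rng)
        assert curve.transformed(T).length == pytest.approx(curve.length, rel=1e-12)
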