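"""Shared fixtures: small analytic meshes and a session-scoped phantom."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from cranionav import PhantomSpec, TriSurface, make_phantom


def make_grid_surface(
    x_range=(-10.0, 160.0),
    y_range=(-10.0, 20.0),
    nx: int = 18,
    ny: int = 7,
    z: float = 0.0,
) -> TriSurface:
    """A flat rectangular grid mesh in the z = const plane."""
    xs = np.linspace(*x_range, nx)
    ys = np.linspace(*y_range, ny)
    verts = np.array([[x, y, z] for y in ys for x in xs])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b, c, d = a + 1, a + nx, a + nx + 1
            faces += [[a, b, d], [a, d, c]]
    return TriSurface(verts, np.array(faces))


def make_sphere_surface(radius: float = 60.0, subdivisions: int = 4) -> TriSurface:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface.from_trimesh(mesh)


@pytest.fixture(scope="session")
def planar_surface() -> TriSurface:
    return make_grid_surface()


@pytest.fixture(scope="session")
def sphere_surface() -> TriSurface:
    return make_sphere_surface()


@pytest.fixture(scope="session")
def small_phantom():
    """A coarse phantom shared by read-only tests."""
    return make_phantom(PhantomSpec(name="SK1", tessellation=3), seed=11)
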