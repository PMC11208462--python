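"""Shared geometric fixtures: icospheres, planar patches, hemisphere domes."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from aneukit.mesh import TriSurfaceMesh
from aneukit.synthetic import DomeSpec, make_dome_mesh


def icosphere_mesh(subdivisions: int = 4, radius: float = 1.0) -> TriSurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurfaceMesh(np.array(tm.vertices), np.array(tm.faces))


def planar_patch(
    nx: int = 12,
    ny: int = 12,
    x0: float = 0.0,
    y0: float = 0.0,
    lx: float = 1.0,
    ly: float = 1.0,
) -> TriSurfaceMesh:
    """Regular triangulated rectangle in the z=0 plane (CCW from +z)."""
    xs = np.linspace(x0, x0 + lx, nx)
    ys = np.linspace(y0, y0 + ly, ny)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return TriSurfaceMesh(verts, np.array(faces))


def interior_vertex_mask(mesh: TriSurfaceMesh) -> np.ndarray:
    """Vertices not on any boundary (once-used) edge."""
    f = mesh.faces
    edges = np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    mask = np.ones(mesh.n_vertices, dtype=bool)
    mask[np.unique(uniq[counts == 1])] = False
    return mask


@pytest.fixture(scope="session")
def unit_icosphere() -> TriSurfaceMesh:
    return icosphere_mesh(subdivisions=4)


@pytest.fixture(scope="session")
def fine_icosphere() -> TriSurfaceMesh:
    """Unit icosphere with max edge length below 0.05."""
    return icosphere_mesh(subdivisions=5)


@pytest.fixture(scope="session")
def hemisphere():
    """2 mm hemispherical dome plus its neck plane (moderate resolution)."""
    return make_dome_mesh(DomeSpec(cap_radius=2e-3, mesh_edge_length=1.5e-4, seed=1))


@pytest.fixture(scope="session")
def fine_hemisphere():
    """2 mm hemispherical dome at the planted-feature contract resolution."""
    return make_dome_mesh(DomeSpec(cap_radius=2e-3, mesh_edge_length=1e-4, seed=1))
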