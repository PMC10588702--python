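"""Shared geometry fixtures; everything is generated, nothing is loaded."""

import numpy as np
import pytest

from nephrosim import (
    PhantomSpec,
    TriMesh,
    build_edge_topology,
    make_icosphere,
    make_kidney_phantom,
)


@pytest.fixture
def unit_triangle() -> TriMesh:
    """Single CCW triangle of area 0.5 in the z = 0 plane, normal +z."""
    return TriMesh(
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        np.array([[0, 1, 2]]),
    )


@pytest.fixture
def flat_quad() -> TriMesh:
    """Two coplanar triangles sharing edge (0, 2); labels one per face."""
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [0.0, 1.0, 0.0]]
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return TriMesh(verts, faces, {0: "left", 1: "right"})


@pytest.fixture
def tetrahedron() -> TriMesh:
    """Unit right-corner tetrahedron, outward wound; volume 1/6."""
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(verts, faces)


@pytest.fixture
def cube() -> TriMesh:
    """Unit cube triangulated into 12 outward-wound faces; volume 1."""
    verts = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (-z)
            [4, 5, 6], [4, 6, 7],  # top (+z)
            [0, 1, 5], [0, 5, 4],  # -y
            [2, 3, 7], [2, 7, 6],  # +y
            [1, 2, 6], [1, 6, 5],  # +x
            [3, 0, 4], [3, 4, 7],  # -x
        ]
    )
    return TriMesh(verts, faces)


@pytest.fixture(scope="session")
def icosphere2() -> TriMesh:
    return make_icosphere(2)


@pytest.fixture(scope="session")
def icosphere3() -> TriMesh:
    return make_icosphere(3)


@pytest.fixture(scope="session")
def phantom():
    """Default kidney phantom and its region partition."""
    return make_kidney_phantom(PhantomSpec())


@pytest.fixture
def folded_quad() -> TriMesh:
    """Two triangles sharing edge (0, 1), folded out of plane."""
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, 1.0, 0.6], [0.5, -1.0, 0.6]]
    )
    faces = np.array([[0, 1, 2], [1, 0, 3]])
    return TriMesh(verts, faces)


@pytest.fixture
def quad_topology(flat_quad):
    return build_edge_topology(flat_quad)
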