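"""Deterministic generators for test and demo geometry.

The training scenario needs a kidney-like closed surface with an attached,
face-labelled tumor lobe.  No scanned anatomy ships with the package;
instead :func:`make_kidney_phantom` builds an equivalent-by-construction
phantom — a bean-shaped deformation of an icosphere with a smooth exophytic
bulge whose faces are labelled ``"cancerous"`` — so every pipeline stage
(deformation, marking, cutting, resection) is exercisable offline and
reproducibly.  All generators are pure functions of their arguments and
seed: the same spec yields bit-identical meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import MeshError, TriMesh

__all__ = [
    "PhantomSpec",
    "make_grid_sheet",
    "make_icosphere",
    "loop_subdivide",
    "make_kidney_phantom",
]

HEALTHY = "healthy"
CANCEROUS = "cancerous"


@dataclass
class PhantomSpec:
    """Parameters of the synthetic kidney phantom.

    Defaults describe an adult kidney (~11 x 7 x 5 cm half-extents
    0.055/0.035/0.025 m) carrying a peripheral exophytic mass of roughly
    0.25 of the mean organ radius (a 3-5 cm class lesion), at icosphere
    subdivision 3 (1280 faces) — coarse enough for interactive CPU physics,
    fine enough for stable dihedral constraints.
    """

    subdivision: int = 3
    kidney_scale: tuple[float, float, float] = (0.055, 0.035, 0.025)
    tumor_radius_fraction: float = 0.25
    tumor_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    indent_direction: tuple[float, float, float] = (0.0, -1.0, 0.0)
    indent_depth: float = 0.25
    bulge_height: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.subdivision < 0:
            raise ValueError("subdivision must be >= 0")
        if not 0.0 < self.tumor_radius_fraction < 0.5:
            raise ValueError("tumor_radius_fraction must lie in (0, 0.5)")
        if any(s <= 0 for s in self.kidney_scale):
            raise ValueError("kidney_scale entries must be positive")


def make_grid_sheet(nx: int, ny: int, spacing: float) -> TriMesh:
    """Planar triangulated sheet in z = 0 with CCW winding seen from +z.

    ``nx * ny`` vertices and ``2 (nx-1) (ny-1)`` faces.  The minimal open
    testbed for deformation and stretch/bend constraints.
    """
    if nx < 2 or ny < 2:
        raise ValueError("grid sheet needs nx, ny >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            c = (i + 1) * ny + j + 1
            d = i * ny + j + 1
            faces.append((a, b, c))
            faces.append((a, c, d))
    return TriMesh(verts, np.array(faces, dtype=np.int64))


# Icosahedron: 12 vertices from three orthogonal golden rectangles.
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=np.float64,
)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def make_icosphere(subdivision: int, radius: float = 1.0) -> TriMesh:
    """Icosahedron refined ``subdivision`` times, vertices on the sphere.

    Face count is ``20 * 4**subdivision``; all vertices lie at exactly
    ``radius`` from the origin (projected after each refinement level).
    """
    if not 0 <= subdivision <= 5:
        raise ValueError("subdivision must lie in [0, 5]")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivision):
        verts, faces = _midpoint_subdivide(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return TriMesh(verts * radius, faces)


def _midpoint_subdivide(verts: np.ndarray, faces: np.ndarray):
    """Split each triangle into four via edge midpoints (shared, deterministic)."""
    mid_cache: dict[tuple[int, int], int] = {}
    new_verts = [v for v in verts]

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key not in mid_cache:
            mid_cache[key] = len(new_verts)
            new_verts.append(0.5 * (verts[a] + verts[b]))
        return mid_cache[key]

    new_faces = []
    for a, b, c in faces:
        ab = midpoint(int(a), int(b))
        bc = midpoint(int(b), int(c))
        ca = midpoint(int(c), int(a))
        new_faces.extend([(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)])
    return np.array(new_verts), np.array(new_faces, dtype=np.int64)


def loop_subdivide(mesh: TriMesh, levels: int = 1) -> TriMesh:
    """Loop subdivision: each level splits faces 4-for-1 and smooths toward
    the limit surface.  Labels are not propagated (refined meshes are
    re-labelled by the caller if needed)."""
    from trimesh.remesh import subdivide_loop

    if levels < 0:
        raise ValueError("levels must be >= 0")
    if levels == 0:
        return mesh.copy()
    v, f = subdivide_loop(mesh.vertices, mesh.faces, iterations=levels)
    return TriMesh(np.asarray(v, dtype=np.float64), np.asarray(f, dtype=np.int64))


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_kidney_phantom(spec: PhantomSpec | None = None
                        ) -> tuple[TriMesh, dict[str, set[int]]]:
    """Closed kidney-like phantom with a face-labelled tumor lobe.

    Construction, on the unit icosphere before anisotropic scaling:

    1. a smooth radial indentation around ``indent_direction`` produces the
       renal-hilum "bean" concavity (depth jittered slightly by ``seed``);
    2. a smooth radial bulge of angular radius ``alpha`` around
       ``tumor_direction`` models the exophytic mass, where ``alpha``
       corresponds to a spherical cap cut by a sphere of radius
       ``tumor_radius_fraction`` (chord metric on the unit sphere);
    3. faces whose unit-sphere centroids fall inside that tumor sphere are
       labelled ``"cancerous"``, everything else ``"healthy"``; the label
       region is then cleaned to a single edge-connected component with a
       smooth boundary;
    4. vertices are scaled by ``kidney_scale``.

    Returns the labelled mesh and its region partition.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    base = make_icosphere(spec.subdivision, radius=1.0)
    verts = base.vertices.copy()
    unit = verts / np.linalg.norm(verts, axis=1, keepdims=True)

    t_dir = np.asarray(spec.tumor_direction, dtype=np.float64)
    t_dir = t_dir / np.linalg.norm(t_dir)
    i_dir = np.asarray(spec.indent_direction, dtype=np.float64)
    i_dir = i_dir / np.linalg.norm(i_dir)

    # chord radius rho on the unit sphere -> cap angular radius alpha
    rho = spec.tumor_radius_fraction
    alpha = 2.0 * np.arcsin(min(rho / 2.0, 1.0))

    # bean indentation: radial dent with smooth falloff, seed-jittered depth
    depth = spec.indent_depth * (1.0 + 0.1 * rng.standard_normal())
    ang_i = np.arccos(np.clip(unit @ i_dir, -1.0, 1.0))
    dent = depth * _smoothstep(1.0 - ang_i / (0.45 * np.pi))

    # exophytic tumor bulge around the tumor axis
    ang_t = np.arccos(np.clip(unit @ t_dir, -1.0, 1.0))
    bulge = spec.bulge_height * rho * _smoothstep(1.0 - ang_t / (1.5 * alpha))

    radial = 1.0 - dent + bulge
    verts = unit * radial[:, None]

    # label faces on the unit sphere: centroid inside the tumor sphere
    cap_center = t_dir
    centroids = unit[base.faces].mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    inside = np.linalg.norm(centroids - cap_center, axis=1) < rho
    labels = {fi: (CANCEROUS if inside[fi] else HEALTHY)
              for fi in range(len(base.faces))}

    mesh = TriMesh(verts * np.asarray(spec.kidney_scale), base.faces.copy(), labels)
    _clean_tumor_labels(mesh)
    return mesh, mesh.regions()


def _clean_tumor_labels(mesh: TriMesh) -> None:
    """Reduce the cancerous label set to one edge-connected region with a
    smooth boundary (no face attached to the region by a single vertex or
    a single edge pinch)."""
    labels = mesh.face_labels
    assert labels is not None
    neigh = _face_neighbors(mesh)

    def cancer_set() -> set[int]:
        return {fi for fi, lab in labels.items() if lab == CANCEROUS}

    # keep only the largest edge-connected cancerous component
    cs = cancer_set()
    if not cs:
        raise MeshError("phantom produced no cancerous faces")
    comps = _components_within(cs, neigh)
    keep = max(comps, key=lambda c: (len(c), -min(c)))
    for fi in cs - keep:
        labels[fi] = HEALTHY

    # smooth: a face disagreeing with >= 2 of its 3 edge-neighbors flips
    for _ in range(10):
        flips = []
        cs = cancer_set()
        for fi in range(len(mesh.faces)):
            nb = neigh[fi]
            if len(nb) < 3:
                continue
            same = sum((n in cs) == (fi in cs) for n in nb)
            if same <= 1:
                flips.append(fi)
        if not flips:
            break
        for fi in flips:
            labels[fi] = HEALTHY if labels[fi] == CANCEROUS else CANCEROUS
    # smoothing may have split the region: keep largest component again
    cs = cancer_set()
    comps = _components_within(cs, neigh)
    for fi in cs - max(comps, key=lambda c: (len(c), -min(c))):
        labels[fi] = HEALTHY


def _face_neighbors(mesh: TriMesh) -> list[list[int]]:
    from .mesh import _edge_face_map

    neigh: list[list[int]] = [[] for _ in range(len(mesh.faces))]
    for fl in _edge_face_map(mesh.faces).values():
        if len(fl) == 2:
            neigh[fl[0]].append(fl[1])
            neigh[fl[1]].append(fl[0])
    return neigh


def _components_within(faces: set[int], neigh: list[list[int]]) -> list[set[int]]:
    seen: set[int] = set()
    out: list[set[int]] = []
    for start in sorted(faces):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            f = stack.pop()
            for n in neigh[f]:
                if n in faces and n not in comp:
                    comp.add(n)
                    stack.append(n)
        seen |= comp
        out.append(comp)
    return out
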