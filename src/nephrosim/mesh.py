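"""Triangle-mesh data model, standard-format I/O, and surface geometry.

Everything downstream (forces, constraints, cutting) operates on a plain
triangle surface mesh: an ``(n, 3)`` float64 vertex array in meters and an
``(m, 3)`` int64 face array with counter-clockwise winding seen from outside
(outward normals).  Faces may carry region labels (e.g. ``"healthy"`` /
``"cancerous"``) which drive tumor resection.

Conventions
-----------
* Vertex indices are 0-based internally; OBJ's 1-based indices are converted
  at the I/O boundary.
* Non-manifold edges (shared by more than two faces) are rejected when
  building edge topology — both physics cores assume at most two faces per
  edge.
* Degenerate (zero-area) faces contribute zero area, zero normal and zero
  pressure rather than raising mid-simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "TriMesh",
    "EdgeTopology",
    "MeshError",
    "load_mesh",
    "save_mesh",
    "face_areas",
    "face_normals",
    "vertex_normals",
    "build_edge_topology",
    "mesh_volume",
    "connected_components",
    "is_closed",
    "face_adjacency",
    "submesh",
]


class MeshError(ValueError):
    """Raised for invalid mesh data or unreadable mesh files."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class TriMesh:
    """A triangle surface mesh with optional per-face region labels.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in meters.
    faces : (m, 3) int array
        Vertex-index triples, counter-clockwise seen from outside.
    face_labels : dict, optional
        Map from face index to region name.  Faces absent from the map are
        unlabelled.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3), got {self.faces.shape}")
        self.validate()

    def validate(self) -> None:
        n = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                bad = int(np.argmax((self.faces < 0) | (self.faces >= n)).item() // 3)
                raise MeshError(
                    f"face {bad} references a vertex outside [0, {n})"
                )
            rep = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if rep.any():
                raise MeshError(f"face {int(np.argmax(rep))} repeats a vertex index")
        if self.face_labels is not None:
            for fi in self.face_labels:
                if not 0 <= fi < len(self.faces):
                    raise MeshError(f"face label key {fi} is not a valid face index")

    @property
    def vertex_count(self) -> int:
        return len(self.vertices)

    @property
    def face_count(self) -> int:
        return len(self.faces)

    def regions(self) -> dict[str, set[int]]:
        """Partition of labelled faces: region name -> set of face indices."""
        out: dict[str, set[int]] = {}
        if self.face_labels:
            for fi, name in self.face_labels.items():
                out.setdefault(name, set()).add(fi)
        return out

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            dict(self.face_labels) if self.face_labels else None,
        )


@dataclass
class EdgeTopology:
    """Edge and dihedral structure of a mesh at its rest configuration.

    ``edges`` holds each unordered vertex pair once, as ``(i, j)`` with
    ``i < j``; ``rest_lengths`` are the Euclidean edge lengths in the rest
    mesh.  Every interior edge (exactly two adjacent faces) yields one
    dihedral record ``(x1, x2, x3, x4)``: the shared edge is ``(x1, x2)``,
    oriented so the first face contains the directed edge ``x1 -> x2``;
    ``x3``/``x4`` are the opposite vertices of the first/second face.  The
    rest dihedral angle ``phi12`` is ``arccos(n1 . n2)`` with ``n1``/``n2``
    the unit normals of triangles ``(x1, x3, x2)`` and ``(x1, x2, x4)``
    (a flat pair gives ``phi12 = 0``).
    """

    edges: np.ndarray              # (E, 2) int64, i < j
    rest_lengths: np.ndarray       # (E,)
    dihedral_vertices: np.ndarray  # (D, 4) int64
    rest_angles: np.ndarray        # (D,) radians in [0, pi]
    dihedral_edges: np.ndarray     # (D,) index into ``edges`` of the shared edge
    edge_faces: dict[tuple[int, int], list[int]] = field(default_factory=dict)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def edge_index(self) -> dict[tuple[int, int], int]:
        return {(int(i), int(j)): k for k, (i, j) in enumerate(self.edges)}


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _cross_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Un-normalized face normals: cross product of two edge vectors.

    The norm of each row is twice the face area; the direction is the
    outward normal for counter-clockwise winding.
    """
    p0, p1, p2 = (vertices[faces[:, k]] for k in range(3))
    return np.cross(p1 - p0, p2 - p0)


def face_areas(mesh: TriMesh, positions: np.ndarray | None = None) -> np.ndarray:
    """Per-face areas in m**2 (degenerate faces give 0)."""
    v = mesh.vertices if positions is None else positions
    return 0.5 * np.linalg.norm(_cross_areas(v, mesh.faces), axis=1)


def face_normals(mesh: TriMesh, positions: np.ndarray | None = None) -> np.ndarray:
    """Unit outward face normals; zero vector for degenerate faces."""
    v = mesh.vertices if positions is None else positions
    c = _cross_areas(v, mesh.faces)
    norms = np.linalg.norm(c, axis=1)
    out = np.zeros_like(c)
    ok = norms > 0.0
    out[ok] = c[ok] / norms[ok, None]
    return out


def vertex_normals(mesh: TriMesh, positions: np.ndarray | None = None) -> np.ndarray:
    """Area-weighted unit vertex normals.

    The cross product of two face edge vectors already carries the face area
    as its magnitude, so summing it per incident vertex gives the
    area-weighted average before normalization.  Isolated vertices (no
    non-degenerate incident face) get a zero vector and a warning, never NaN.
    """
    v = mesh.vertices if positions is None else positions
    c = _cross_areas(v, mesh.faces)
    acc = np.zeros((len(v), 3))
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], c)
    norms = np.linalg.norm(acc, axis=1)
    ok = norms > 0.0
    out = np.zeros_like(acc)
    out[ok] = acc[ok] / norms[ok, None]
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} vertex normals undefined (isolated or degenerate);"
            " set to zero",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def _edge_face_map(faces: np.ndarray) -> dict[tuple[int, int], list[int]]:
    ef: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (int(u), int(v)) if u < v else (int(v), int(u))
            ef.setdefault(key, []).append(fi)
    return ef


def dihedral_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                   p4: np.ndarray) -> float:
    """Angle arccos(n1 . n2) between triangles (p1,p3,p2) and (p1,p2,p4).

    Zero for a coplanar, consistently wound pair.  The dot product is
    clamped to [-1, 1] before arccos.
    """
    n1 = np.cross(p3 - p1, p2 - p1)
    n2 = np.cross(p2 - p1, p4 - p1)
    l1 = np.linalg.norm(n1)
    l2 = np.linalg.norm(n2)
    if l1 == 0.0 or l2 == 0.0:
        return 0.0
    d = float(np.dot(n1 / l1, n2 / l2))
    return float(np.arccos(np.clip(d, -1.0, 1.0)))


def build_edge_topology(mesh: TriMesh) -> EdgeTopology:
    """Extract edges, rest lengths and dihedral pairs from the rest mesh.

    Raises
    ------
    MeshError
        If any edge is shared by more than two faces (non-manifold).
    """
    ef = _edge_face_map(mesh.faces)
    for key, fl in ef.items():
        if len(fl) > 2:
            raise MeshError(f"non-manifold edge {key} shared by {len(fl)} faces")
    edge_list = sorted(ef)
    edges = np.array(edge_list, dtype=np.int64).reshape(-1, 2)
    v = mesh.vertices
    rest = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    if (rest <= 0.0).any():
        raise MeshError("zero-length edge in rest mesh")

    quads: list[tuple[int, int, int, int]] = []
    angles: list[float] = []
    d_edge: list[int] = []
    for k, key in enumerate(edge_list):
        fl = ef[key]
        if len(fl) != 2:
            continue
        f1 = mesh.faces[fl[0]]
        f2 = mesh.faces[fl[1]]
        a, b = key
        # orient the edge so face 1 traverses x1 -> x2
        if not _has_directed(f1, a, b):
            a, b = b, a
        x3 = int(f1[~np.isin(f1, (a, b))][0])
        x4 = int(f2[~np.isin(f2, (a, b))][0])
        phi = dihedral_angle(v[a], v[b], v[x3], v[x4])
        quads.append((a, b, x3, x4))
        angles.append(phi)
        d_edge.append(k)
    return EdgeTopology(
        edges=edges,
        rest_lengths=rest,
        dihedral_vertices=np.array(quads, dtype=np.int64).reshape(-1, 4),
        rest_angles=np.asarray(angles, dtype=np.float64),
        dihedral_edges=np.asarray(d_edge, dtype=np.int64),
        edge_faces=ef,
    )


def _has_directed(face: np.ndarray, a: int, b: int) -> bool:
    """True if ``face`` contains the directed edge a -> b in cyclic order."""
    f = [int(x) for x in face]
    for k in range(3):
        if f[k] == a and f[(k + 1) % 3] == b:
            return True
    return False


def is_closed(mesh: TriMesh) -> bool:
    """True if every edge is shared by exactly two faces."""
    return all(len(fl) == 2 for fl in _edge_face_map(mesh.faces).values())


def mesh_volume(mesh: TriMesh, positions: np.ndarray | None = None) -> float:
    """Signed enclosed volume via the divergence theorem (m**3).

    Positive for a closed, outward-wound surface.  An open mesh triggers a
    warning but still returns the signed tetrahedron sum.
    """
    v = mesh.vertices if positions is None else positions
    if not is_closed(mesh):
        warnings.warn("mesh is not closed; signed volume is approximate",
                      RuntimeWarning, stacklevel=2)
    p0, p1, p2 = (v[mesh.faces[:, k]] for k in range(3))
    return float(np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0)


def face_adjacency(mesh: TriMesh,
                   exclude_edges: set[tuple[int, int]] | None = None
                   ) -> coo_matrix:
    """Sparse face-adjacency matrix over shared edges.

    ``exclude_edges`` suppresses adjacency across the given (i<j) vertex
    pairs — the primitive behind cut-based mesh separation.
    """
    rows, cols = [], []
    for key, fl in _edge_face_map(mesh.faces).items():
        if len(fl) == 2 and not (exclude_edges and key in exclude_edges):
            rows.append(fl[0])
            cols.append(fl[1])
    m = len(mesh.faces)
    data = np.ones(len(rows), dtype=np.int8)
    return coo_matrix((data, (rows, cols)), shape=(m, m))


def connected_components(mesh: TriMesh,
                         exclude_edges: set[tuple[int, int]] | None = None
                         ) -> list[set[int]]:
    """Face components under shared-edge connectivity.

    Returned in deterministic order: sorted by each component's smallest
    face index.
    """
    if len(mesh.faces) == 0:
        return []
    n, labels = _cc(face_adjacency(mesh, exclude_edges), directed=False)
    comps: dict[int, set[int]] = {}
    for fi, lab in enumerate(labels):
        comps.setdefault(int(lab), set()).add(fi)
    return sorted(comps.values(), key=min)


def submesh(mesh: TriMesh, face_indices: set[int] | list[int]) -> TriMesh:
    """Extract the given faces into an independent mesh with its own
    (re-indexed, duplicated) vertices."""
    fidx = np.array(sorted(face_indices), dtype=np.int64)
    faces = mesh.faces[fidx]
    used = np.unique(faces)
    remap = {int(old): new for new, old in enumerate(used)}
    new_faces = np.vectorize(remap.__getitem__)(faces).astype(np.int64)
    labels = None
    if mesh.face_labels:
        labels = {
            k: mesh.face_labels[int(old)]
            for k, old in enumerate(fidx)
            if int(old) in mesh.face_labels
        }
    return TriMesh(mesh.vertices[used].copy(), new_faces, labels or None)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("obj", "ply", "stl")


def _infer_format(path: Path, fmt: str | None) -> str:
    f = (fmt or path.suffix.lstrip(".")).lower()
    if f not in _FORMATS:
        raise MeshError(f"unsupported mesh format {f!r}; expected one of {_FORMATS}")
    return f


def load_mesh(path: str | Path, fmt: str | None = None) -> TriMesh:
    """Read a triangle mesh from OBJ, ascii PLY, or STL (ascii or binary).

    OBJ group lines (``g name``) populate ``face_labels``.  STL triangle
    soups are welded on exact coordinate equality.  Non-triangular faces and
    out-of-range indices are rejected with the offending record's location.
    """
    path = Path(path)
    if not path.exists():
        raise MeshError(f"mesh file not found: {path}")
    f = _infer_format(path, fmt)
    if f == "obj":
        return _load_obj(path)
    return _load_via_trimesh(path, f)


def save_mesh(mesh: TriMesh, path: str | Path, fmt: str | None = None) -> None:
    """Write a mesh to OBJ (labels as ``g`` lines), ascii PLY, or ascii STL.

    Vertex and face order are preserved for OBJ and PLY.
    """
    path = Path(path)
    f = _infer_format(path, fmt)
    if f == "obj":
        _save_obj(mesh, path)
    else:
        _save_via_trimesh(mesh, path, f)


def _load_obj(path: Path) -> TriMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    labels: dict[int, str] = {}
    group: str | None = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] == "v":
                if len(tok) < 4:
                    raise MeshError(f"{path}:{ln}: malformed vertex line")
                verts.append([float(x) for x in tok[1:4]])
            elif tok[0] == "f":
                idx = [t.split("/")[0] for t in tok[1:]]
                if len(idx) != 3:
                    raise MeshError(
                        f"{path}:{ln}: non-triangular face with {len(idx)} vertices"
                    )
                tri = [int(i) - 1 for i in idx]
                if any(i < 0 for i in tri):
                    raise MeshError(f"{path}:{ln}: non-positive face index")
                if group is not None:
                    labels[len(faces)] = group
                faces.append(tri)
            elif tok[0] == "g":
                group = tok[1] if len(tok) > 1 else None
                if group == "default":
                    group = None
    v = np.asarray(verts, dtype=np.float64).reshape(-1, 3)
    fc = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    if fc.size and (fc.max() >= len(v)):
        bad = int(np.argmax(fc.max(axis=1) >= len(v)))
        raise MeshError(
            f"{path}: face {bad} references vertex {int(fc[bad].max()) + 1}"
            f" of a {len(v)}-vertex file"
        )
    return TriMesh(v, fc, labels or None)


def _save_obj(mesh: TriMesh, path: Path) -> None:
    labels = mesh.face_labels or {}
    with open(path, "w") as fh:
        fh.write("# nephrosim triangle mesh\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {float(x)!r} {float(y)!r} {float(z)!r}\n")
        current: str | None = None
        for fi, (a, b, c) in enumerate(mesh.faces):
            g = labels.get(fi)
            if g != current:
                fh.write(f"g {g if g is not None else 'default'}\n")
                current = g
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")


def _load_via_trimesh(path: Path, fmt: str) -> TriMesh:
    import trimesh as _tm

    try:
        tm = _tm.load(str(path), file_type=fmt, process=False)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise MeshError(f"unreadable {fmt} file {path}: {exc}") from exc
    if not isinstance(tm, _tm.Trimesh):
        raise MeshError(f"{path}: no triangle geometry found")
    v = np.asarray(tm.vertices, dtype=np.float64)
    f = np.asarray(tm.faces, dtype=np.int64)
    if fmt == "stl":
        v, f = _weld_exact(v, f)
    return TriMesh(v, f)


def _weld_exact(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices with bitwise-identical coordinates (STL triangle soup)."""
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return uniq, inverse[faces].astype(np.int64)


def _save_via_trimesh(mesh: TriMesh, path: Path, fmt: str) -> None:
    import trimesh as _tm

    tm = _tm.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if fmt == "ply":
        data = _tm.exchange.ply.export_ply(tm, encoding="ascii")
    else:
        data = _tm.exchange.stl.export_stl_ascii(tm).encode()
    with open(path, "wb") as fh:
        fh.write(data if isinstance(data, bytes) else data.encode())
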