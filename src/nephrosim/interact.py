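"""Headless surface interaction: ray picking, cut marking, resection.

In the interactive trainer the user points a tracked controller at the
organ; here the same gestures arrive as scripted data.  A ray picks a
surface point; a sequence of surface samples marks a cut path across the
triangles; the path's crossed edges drive constraint removal (immediate
severing, or weakening so tearing detaches them under load); and a closed
path around the labelled tumor lobe lets :func:`resect` split the mesh
into the remaining organ and the excised specimen.

Cuts run along existing mesh edges — no re-meshing, the vertex count stays
constant.  Separation duplicates the vertices shared by the two sides so
each output is an independent mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh import (
    MeshError,
    TriMesh,
    EdgeTopology,
    connected_components,
    submesh,
)
from .pbd import ConstraintSet

__all__ = [
    "Ray",
    "CutPath",
    "ray_triangle",
    "cast_ray",
    "mark_cut_path",
    "apply_cut",
    "resect",
    "region_boundary_edges",
    "order_edge_loop",
    "boundary_cut_samples",
]


@dataclass
class Ray:
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        d = np.asarray(self.direction, dtype=np.float64)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("ray direction must be unit length")
        self.direction = d


@dataclass
class CutPath:
    """Ordered surface samples plus the mesh edges their segments cross."""

    points: np.ndarray                      # (k, 3)
    face_indices: np.ndarray                # (k,)
    crossed_edges: list[tuple[int, int]]    # ordered, (i < j) pairs
    closed: bool


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------

def ray_triangle(ray: Ray, p0, p1, p2, eps: float = 1e-12):
    """Moeller-Trumbore ray/triangle intersection.

    Returns ``(t, (u, v, w))`` with ``t > 0`` and barycentric coordinates
    summing to one, or ``None`` on a miss (including rays parallel to the
    plane and intersections behind the origin).
    """
    p0, p1, p2 = (np.asarray(q, float) for q in (p0, p1, p2))
    e1 = p1 - p0
    e2 = p2 - p0
    h = np.cross(ray.direction, e2)
    a = float(e1 @ h)
    if abs(a) < eps:
        return None
    f = 1.0 / a
    s = ray.origin - p0
    u = f * float(s @ h)
    if u < -eps or u > 1.0 + eps:
        return None
    q = np.cross(s, e1)
    v = f * float(ray.direction @ q)
    if v < -eps or u + v > 1.0 + eps:
        return None
    t = f * float(e2 @ q)
    if t <= eps:
        return None
    u = min(max(u, 0.0), 1.0)
    v = min(max(v, 0.0), 1.0 - u)
    return t, (1.0 - u - v, u, v)


def cast_ray(mesh: TriMesh, ray: Ray, positions: np.ndarray | None = None):
    """Nearest positive-t hit over all faces: ``(face_index, point)`` or
    ``None``.  Ties at identical t break toward the smaller face index."""
    v = mesh.vertices if positions is None else positions
    best_t = np.inf
    best_face = -1
    for fi, (a, b, c) in enumerate(mesh.faces):
        hit = ray_triangle(ray, v[a], v[b], v[c])
        if hit is not None and hit[0] < best_t:
            best_t, best_face = hit[0], fi
    if best_face < 0:
        return None
    return best_face, ray.origin + best_t * ray.direction


# ---------------------------------------------------------------------------
# Cut marking
# ---------------------------------------------------------------------------

def _face_adjacency_lists(mesh: TriMesh):
    from .mesh import _edge_face_map

    adj: dict[int, list[tuple[int, tuple[int, int]]]] = {}
    for key, fl in _edge_face_map(mesh.faces).items():
        if len(fl) == 2:
            adj.setdefault(fl[0], []).append((fl[1], key))
            adj.setdefault(fl[1], []).append((fl[0], key))
    return adj


def _face_walk_edges(adj, fa: int, fb: int) -> list[tuple[int, int]]:
    """Shared edges along the shortest face-adjacency walk fa -> fb (BFS,
    deterministic neighbor order)."""
    if fa == fb:
        return []
    prev: dict[int, tuple[int, tuple[int, int]]] = {fa: (-1, (-1, -1))}
    frontier = [fa]
    while frontier and fb not in prev:
        nxt = []
        for f in frontier:
            for g, edge in sorted(adj.get(f, [])):
                if g not in prev:
                    prev[g] = (f, edge)
                    nxt.append(g)
        frontier = nxt
    if fb not in prev:
        raise MeshError(f"faces {fa} and {fb} are not surface-connected")
    edges = []
    f = fb
    while f != fa:
        f, edge = prev[f]
        edges.append(edge)
    edges.reverse()
    return edges


def mark_cut_path(mesh: TriMesh, samples, closure_tol: float | None = None,
                  surface_tol: float = 1e-6) -> CutPath:
    """Connect ordered surface samples into a cut path.

    ``samples`` is a sequence of ``(point, face_index)`` pairs (as produced
    by :func:`cast_ray`).  Consecutive samples are joined across the
    surface; every mesh edge separating the faces traversed between them is
    recorded, in order, as a crossed edge.  The path is closed when the
    last sample returns within ``closure_tol`` of the first (default:
    1.5x the mean edge length).

    Samples farther than ``surface_tol`` (times the mesh scale) from their
    face's plane are rejected with their index.
    """
    pts = np.array([np.asarray(p, float) for p, _ in samples]).reshape(-1, 3)
    fidx = np.array([int(f) for _, f in samples], dtype=np.int64)
    scale = float(np.linalg.norm(np.ptp(mesh.vertices, axis=0))) or 1.0
    for k, (p, fi) in enumerate(zip(pts, fidx)):
        a, b, c = mesh.faces[fi]
        n = np.cross(mesh.vertices[b] - mesh.vertices[a],
                     mesh.vertices[c] - mesh.vertices[a])
        ln = np.linalg.norm(n)
        if ln == 0.0:
            continue
        dist = abs(float((p - mesh.vertices[a]) @ (n / ln)))
        if dist > surface_tol * scale:
            raise MeshError(f"sample {k} lies {dist:g} m off face {fi}")

    adj = _face_adjacency_lists(mesh)
    crossed: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for k in range(len(fidx) - 1):
        for edge in _face_walk_edges(adj, int(fidx[k]), int(fidx[k + 1])):
            if edge not in seen:
                seen.add(edge)
                crossed.append(edge)

    if closure_tol is None:
        i, j = np.array(list({tuple(sorted((int(a), int(b))))
                              for f in mesh.faces
                              for a, b in ((f[0], f[1]), (f[1], f[2]),
                                           (f[2], f[0]))})).T
        closure_tol = 1.5 * float(np.mean(np.linalg.norm(
            mesh.vertices[i] - mesh.vertices[j], axis=1)))
    closed = len(pts) > 2 and (
        int(fidx[0]) == int(fidx[-1])
        or float(np.linalg.norm(pts[0] - pts[-1])) <= closure_tol
    )
    return CutPath(points=pts, face_indices=fidx, crossed_edges=crossed,
                   closed=closed)


# ---------------------------------------------------------------------------
# Cutting constraints
# ---------------------------------------------------------------------------

def apply_cut(constraints: ConstraintSet, cut_path: CutPath,
              mode: str = "sever", break_threshold: float = 0.2) -> ConstraintSet:
    """Turn a marked path into constraint changes, in place.

    ``sever`` removes the stretch constraint on every crossed edge and any
    bend constraint whose shared edge is crossed, immediately.  ``weaken``
    instead marks the crossed stretch constraints breakable with
    ``break_threshold`` so that :func:`nephrosim.pbd.tear_step` detaches
    them under load.  Never adds constraints.
    """
    if mode not in ("sever", "weaken"):
        raise ValueError("mode must be 'sever' or 'weaken'")
    lookup = constraints.stretch_edge_lookup()
    rows = []
    for edge in cut_path.crossed_edges:
        row = lookup.get(edge)
        if row is None or not constraints.stretch_alive[row]:
            warnings.warn(f"crossed edge {edge} has no live stretch constraint",
                          RuntimeWarning, stacklevel=2)
            continue
        rows.append(row)
    if mode == "sever":
        constraints.remove_stretch(rows)
        cut = set(cut_path.crossed_edges)
        bend_rows = [
            r for r in np.nonzero(constraints.bend_alive)[0]
            if tuple(sorted(map(int, constraints.bend_verts[r][:2]))) in cut
        ]
        constraints.remove_bend(bend_rows)
    else:
        constraints.stretch_breakable[rows] = True
        constraints.stretch_threshold[rows] = break_threshold
    return constraints


# ---------------------------------------------------------------------------
# Resection
# ---------------------------------------------------------------------------

def resect(mesh: TriMesh, cut_path: CutPath, region_label: str
           ) -> tuple[TriMesh, TriMesh]:
    """Separate the mesh along a closed cut and excise the labelled region.

    The crossed-edge cycle partitions the faces; the component whose label
    majority matches ``region_label`` is the excised specimen, the union of
    the rest the remaining organ.  Vertices on the separation line are
    duplicated (one copy per component) so both outputs are independent
    meshes.  Face conservation holds exactly.

    Two separation rules are tried, matching the two ways a closed path can
    encode a cut: (1) the crossed edges form the seam itself — face
    adjacency across them is severed; (2) the crossed edges are the rungs
    bridging the two sides (a zigzag path) — the vertex graph splits when
    they are removed and faces follow their majority vertex side.
    """
    if not cut_path.closed:
        raise MeshError("cut is not closed")
    if region_label not in mesh.regions():
        raise MeshError(f"region label {region_label!r} not present")
    cut = {tuple(sorted(e)) for e in cut_path.crossed_edges}

    comps = connected_components(mesh, exclude_edges=cut)
    if len(comps) < 2:
        comps = _vertex_side_components(mesh, cut)
    if comps is None or len(comps) < 2:
        raise MeshError("cut cycle does not separate the surface")

    labels = mesh.face_labels or {}

    def match_count(comp: set[int]) -> int:
        return sum(1 for f in comp if labels.get(f) == region_label)

    excised_comp = max(comps, key=lambda c: (match_count(c) / len(c), len(c)))
    rest = [f for c in comps if c is not excised_comp for f in c]
    if not rest:
        raise MeshError("cut would excise the entire mesh")
    return submesh(mesh, rest), submesh(mesh, excised_comp)


def _vertex_side_components(mesh: TriMesh, cut: set[tuple[int, int]]):
    """Face partition from the vertex graph with the cut edges removed;
    each face joins the side holding the majority of its vertices."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components as cc

    edges = {tuple(sorted((int(f[a]), int(f[b]))))
             for f in mesh.faces for a, b in ((0, 1), (1, 2), (2, 0))}
    keep = [e for e in edges if e not in cut]
    if not keep:
        return None
    rows = [e[0] for e in keep]
    cols = [e[1] for e in keep]
    n = mesh.vertex_count
    g = coo_matrix((np.ones(len(keep)), (rows, cols)), shape=(n, n))
    ncomp, vlab = cc(g, directed=False)
    if ncomp < 2:
        return None
    comps: dict[int, set[int]] = {}
    for fi, f in enumerate(mesh.faces):
        side = int(np.bincount(vlab[f]).argmax())
        comps.setdefault(side, set()).add(fi)
    return sorted(comps.values(), key=min)


# ---------------------------------------------------------------------------
# Label-boundary helpers (building scripted cuts on labelled phantoms)
# ---------------------------------------------------------------------------

def region_boundary_edges(mesh: TriMesh, region_label: str
                          ) -> list[tuple[int, int]]:
    """Edges whose two adjacent faces straddle the region boundary."""
    from .mesh import _edge_face_map

    labels = mesh.face_labels or {}
    out = []
    for key, fl in _edge_face_map(mesh.faces).items():
        if len(fl) == 2:
            a = labels.get(fl[0]) == region_label
            b = labels.get(fl[1]) == region_label
            if a != b:
                out.append(key)
    return sorted(out)


def order_edge_loop(edges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order a set of edges into a single closed loop (each vertex must
    have degree 2); raises if the set is not one simple cycle."""
    from collections import defaultdict

    nbr = defaultdict(list)
    for i, j in edges:
        nbr[i].append(j)
        nbr[j].append(i)
    if any(len(v) != 2 for v in nbr.values()):
        raise MeshError("edge set is not a simple closed loop")
    start = min(nbr)
    loop = [start]
    prev = None
    while True:
        cur = loop[-1]
        nxt = [v for v in sorted(nbr[cur]) if v != prev]
        prev = cur
        nxt = nxt[0]
        if nxt == start:
            break
        loop.append(nxt)
    ordered = [tuple(sorted((loop[k], loop[(k + 1) % len(loop)])))
               for k in range(len(loop))]
    if set(ordered) != {tuple(sorted(e)) for e in edges}:
        raise MeshError("edge set contains more than one loop")
    return ordered


def boundary_cut_samples(mesh: TriMesh, region_label: str):
    """Scripted cut following a labelled region's boundary loop.

    Emits face-centroid samples that zigzag across every boundary edge in
    loop order — region-side face, outside face — connecting consecutive
    zigzags by short walks over *outside* faces only, so that every pair
    of consecutive samples sits on edge-adjacent faces.  The segments
    therefore cross each boundary edge exactly once and never enter the
    region's interior; severing the crossed edges detaches the region —
    the idealized trainee cut.
    """
    from .mesh import _edge_face_map

    boundary = region_boundary_edges(mesh, region_label)
    if not boundary:
        raise MeshError(f"region {region_label!r} has no boundary")
    loop = order_edge_loop(boundary)
    ef = _edge_face_map(mesh.faces)
    labels = mesh.face_labels or {}
    inside_faces: list[int] = []
    outside_faces: list[int] = []
    for edge in loop:
        f1, f2 = ef[edge]
        if labels.get(f2) == region_label:
            f1, f2 = f2, f1
        inside_faces.append(int(f1))
        outside_faces.append(int(f2))

    # adjacency restricted to faces outside the region
    adj = _face_adjacency_lists(mesh)
    outside_adj = {
        f: [(g, e) for g, e in nb if labels.get(g) != region_label]
        for f, nb in adj.items() if labels.get(f) != region_label
    }

    n = len(loop)
    face_seq: list[int] = []
    for i in range(n):
        face_seq.append(inside_faces[i])
        fb, fb_next = outside_faces[i], outside_faces[(i + 1) % n]
        face_seq.extend(_face_bfs_path(outside_adj, fb, fb_next))
    face_seq.append(inside_faces[0])

    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    samples = []
    for f in face_seq:
        if samples and samples[-1][1] == f:
            continue
        samples.append((centroids[f].copy(), int(f)))
    samples.append((samples[0][0].copy(), samples[0][1]))
    return samples


def _face_bfs_path(adj, fa: int, fb: int) -> list[int]:
    """Face sequence (inclusive) of the shortest walk fa -> fb within the
    given adjacency; deterministic neighbor order."""
    if fa == fb:
        return [fa]
    prev: dict[int, int] = {fa: -1}
    frontier = [fa]
    while frontier and fb not in prev:
        nxt = []
        for f in frontier:
            for g, _ in sorted(adj.get(f, [])):
                if g not in prev:
                    prev[g] = f
                    nxt.append(g)
        frontier = nxt
    if fb not in prev:
        raise MeshError(f"faces {fa} and {fb} are not connected outside"
                        " the region")
    out = [fb]
    while out[-1] != fa:
        out.append(prev[out[-1]])
    out.reverse()
    return out
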