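"""Position-based dynamics: constraints, projection, tearing.

The constraint solver complements the force model: after forces set
tentative velocities, positions are predicted (p = x + v dt), constraints
are projected iteratively in place (Gauss-Seidel, fixed order: stretch,
then bend, then collision), and the velocity is re-derived from the
realized position change, v = (p - x) / dt.  Because positions are
corrected directly, overshoot cannot accumulate — the source of the
method's stability.

Constraint types
----------------
stretch   C(x1, x2) = |x1 - x2| - d12           (equality, per edge)
bend      C(x1..x4) = arccos(n1 . n2) - phi12   (equality, per interior edge)
collision C(x)      = (x - q) . n  >= 0         (inequality, per contact)

Stiffness k in [0, 1] is applied per iteration as
k' = 1 - (1 - k)^(1/iterations) so the total correction after all solver
iterations is independent of the iteration count.  Breakable stretch
constraints model connective tissue: when an edge's extension exceeds its
break threshold the constraint is removed permanently (tearing), which is
how a cut or a pulled tumor lobe detaches.

A note on the bend constraint: its rest angle phi12 is recorded from the
rest geometry, but the normals n1, n2 must be evaluated at the *current*
positions — evaluating both at rest would make the constraint identically
zero and inert.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .mesh import TriMesh, EdgeTopology
from .forces import SoftBodyState

__all__ = [
    "StretchConstraint",
    "BendConstraint",
    "CollisionConstraint",
    "SolverConfig",
    "ConstraintSet",
    "PlaneCollider",
    "TriangleCollider",
    "eval_stretch",
    "project_stretch",
    "eval_bend",
    "bend_gradients",
    "project_bend",
    "generate_collision_constraints",
    "solve_step",
    "total_energy",
    "tear_step",
]


# ---------------------------------------------------------------------------
# Constraint records and colliders
# ---------------------------------------------------------------------------

@dataclass
class StretchConstraint:
    i: int
    j: int
    d12: float
    k_str: float = 1.0
    breakable: bool = False
    break_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("stretch constraint needs two distinct vertices")
        if self.d12 <= 0:
            raise ValueError("rest length must be positive")
        if not 0.0 <= self.k_str <= 1.0:
            raise ValueError("k_str must lie in [0, 1]")
        if self.breakable and self.break_threshold <= 0:
            raise ValueError("breakable constraint needs a positive threshold")


@dataclass
class BendConstraint:
    x1: int
    x2: int
    x3: int
    x4: int
    phi12: float
    k_bend: float = 1.0

    def __post_init__(self) -> None:
        if len({self.x1, self.x2, self.x3, self.x4}) != 4:
            raise ValueError("bend constraint needs four distinct vertices")
        if not 0.0 <= self.phi12 <= np.pi:
            raise ValueError("rest dihedral angle must lie in [0, pi]")
        if not 0.0 <= self.k_bend <= 1.0:
            raise ValueError("k_bend must lie in [0, 1]")


@dataclass
class CollisionConstraint:
    """Inequality constraint (p - point) . normal >= 0 for one vertex."""

    vertex: int
    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=np.float64)
        self.normal = np.asarray(self.normal, dtype=np.float64)
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("collision witness normal must be unit length")


@dataclass
class SolverConfig:
    iterations: int = 5
    dt: float = 0.01
    k_str: float = 0.9
    k_bend: float = 0.5
    break_mode: str = "relative"  # or "absolute"

    def validate(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("k_str", "k_bend"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.break_mode not in ("relative", "absolute"):
            raise ValueError("break_mode must be 'relative' or 'absolute'")


@dataclass
class PlaneCollider:
    """Static half-space: valid region is (x - point) . normal >= 0."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=np.float64)
        n = np.asarray(self.normal, dtype=np.float64)
        self.normal = n / np.linalg.norm(n)


@dataclass
class TriangleCollider:
    """Single static triangle; vertices crossing its plane within the
    triangle's footprint are pushed back to the plane."""

    p0: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=np.float64)
        self.p1 = np.asarray(self.p1, dtype=np.float64)
        self.p2 = np.asarray(self.p2, dtype=np.float64)
        n = np.cross(self.p1 - self.p0, self.p2 - self.p0)
        ln = np.linalg.norm(n)
        if ln == 0:
            raise ValueError("degenerate triangle collider")
        self.normal = n / ln


# ---------------------------------------------------------------------------
# Constraint set (packed arrays; permanent removal supported)
# ---------------------------------------------------------------------------

class ConstraintSet:
    """Packed stretch and bend constraints with alive masks.

    Removal (tearing, cutting) flips the alive flag and is permanent.
    Constructed most conveniently via :meth:`from_topology`.
    """

    def __init__(self,
                 stretch: list[StretchConstraint] | None = None,
                 bend: list[BendConstraint] | None = None) -> None:
        stretch = stretch or []
        bend = bend or []
        self.stretch_ij = np.array(
            [(c.i, c.j) for c in stretch], dtype=np.int64).reshape(-1, 2)
        self.stretch_rest = np.array([c.d12 for c in stretch], dtype=np.float64)
        self.stretch_k = np.array([c.k_str for c in stretch], dtype=np.float64)
        self.stretch_breakable = np.array(
            [c.breakable for c in stretch], dtype=bool)
        self.stretch_threshold = np.array(
            [c.break_threshold for c in stretch], dtype=np.float64)
        self.stretch_alive = np.ones(len(stretch), dtype=bool)
        self.bend_verts = np.array(
            [(c.x1, c.x2, c.x3, c.x4) for c in bend], dtype=np.int64
        ).reshape(-1, 4)
        self.bend_rest = np.array([c.phi12 for c in bend], dtype=np.float64)
        self.bend_k = np.array([c.k_bend for c in bend], dtype=np.float64)
        self.bend_alive = np.ones(len(bend), dtype=bool)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_topology(cls, topology: EdgeTopology, k_str: float = 1.0,
                      k_bend: float = 1.0, breakable: bool = False,
                      break_threshold: float = 0.0,
                      breakable_edges: set[tuple[int, int]] | None = None
                      ) -> "ConstraintSet":
        """One stretch constraint per edge and one bend constraint per
        interior edge of the topology.  ``breakable_edges`` restricts
        breakability to a subset (e.g. the tumor attachment); with
        ``breakable=True`` every constraint is breakable."""
        stretch = []
        for (i, j), rest in zip(topology.edges, topology.rest_lengths):
            brk = breakable or bool(
                breakable_edges and (int(i), int(j)) in breakable_edges)
            stretch.append(StretchConstraint(
                int(i), int(j), float(rest), k_str,
                breakable=brk,
                break_threshold=break_threshold if brk else 0.0))
        bend = [
            BendConstraint(int(q[0]), int(q[1]), int(q[2]), int(q[3]),
                           float(phi), k_bend)
            for q, phi in zip(topology.dihedral_vertices, topology.rest_angles)
        ]
        return cls(stretch, bend)

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_stretch_alive(self) -> int:
        return int(self.stretch_alive.sum())

    @property
    def n_bend_alive(self) -> int:
        return int(self.bend_alive.sum())

    @property
    def n_alive(self) -> int:
        return self.n_stretch_alive + self.n_bend_alive

    def stretch_edge_lookup(self) -> dict[tuple[int, int], int]:
        """Map (i<j) vertex pair -> stretch constraint row."""
        out = {}
        for row, (i, j) in enumerate(self.stretch_ij):
            key = (int(i), int(j)) if i < j else (int(j), int(i))
            out[key] = row
        return out

    def remove_stretch(self, rows) -> None:
        self.stretch_alive[np.asarray(list(rows), dtype=np.int64)] = False

    def remove_bend(self, rows) -> None:
        self.bend_alive[np.asarray(list(rows), dtype=np.int64)] = False

    def alive_stretch_graph_components(self, n_vertices: int) -> int:
        """Number of connected components of the vertex graph induced by
        the alive stretch constraints (isolated vertices excluded)."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components as cc

        ij = self.stretch_ij[self.stretch_alive]
        if len(ij) == 0:
            return 0
        used = np.unique(ij)
        remap = {int(v): k for k, v in enumerate(used)}
        rows = [remap[int(i)] for i in ij[:, 0]]
        cols = [remap[int(j)] for j in ij[:, 1]]
        m = coo_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(len(used), len(used)))
        n, _ = cc(m, directed=False)
        return int(n)

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "schema": "nephrosim-constraints-1",
            "stretch": [
                {
                    "i": int(i), "j": int(j), "d12": float(r), "k_str": float(k),
                    "breakable": bool(b), "break_threshold": float(t),
                }
                for (i, j), r, k, b, t, a in zip(
                    self.stretch_ij, self.stretch_rest, self.stretch_k,
                    self.stretch_breakable, self.stretch_threshold,
                    self.stretch_alive)
                if a
            ],
            "bend": [
                {
                    "x1": int(q[0]), "x2": int(q[1]), "x3": int(q[2]),
                    "x4": int(q[3]), "phi12": float(phi), "k_bend": float(k),
                }
                for q, phi, k, a in zip(
                    self.bend_verts, self.bend_rest, self.bend_k,
                    self.bend_alive)
                if a
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "ConstraintSet":
        if isinstance(source, dict):
            doc = source
        else:
            doc = json.loads(Path(source).read_text())
        if doc.get("schema") != "nephrosim-constraints-1":
            raise ValueError("unrecognized constraint schema")
        stretch = [StretchConstraint(**c) for c in doc["stretch"]]
        bend = [BendConstraint(**c) for c in doc["bend"]]
        return cls(stretch, bend)


# ---------------------------------------------------------------------------
# Scalar reference evaluation / projection
# ---------------------------------------------------------------------------

def eval_stretch(p_i: np.ndarray, p_j: np.ndarray, d12: float) -> float:
    """C = |p_i - p_j| - d12 (negative when compressed)."""
    return float(np.linalg.norm(np.asarray(p_i, float) - np.asarray(p_j, float))
                 - d12)


def _per_iteration_stiffness(k: float, iterations: int) -> float:
    """k' = 1 - (1 - k)^(1/n): total correction independent of n."""
    return 1.0 - (1.0 - k) ** (1.0 / iterations)


def project_stretch(positions: np.ndarray, constraint: StretchConstraint,
                    inverse_masses: np.ndarray, iterations: int = 1
                    ) -> np.ndarray:
    """Mass-weighted projection of one stretch constraint (copy returned).

    With k_str = 1 a single projection satisfies the constraint exactly;
    pinned endpoints (inverse mass 0) never move.  Coincident endpoints
    are skipped (direction undefined).
    """
    p = np.array(positions, dtype=np.float64)
    i, j = constraint.i, constraint.j
    wi, wj = inverse_masses[i], inverse_masses[j]
    if wi + wj == 0.0:
        return p
    d = p[i] - p[j]
    dist = np.linalg.norm(d)
    if dist == 0.0:
        warnings.warn("coincident stretch endpoints; projection skipped",
                      RuntimeWarning, stacklevel=2)
        return p
    kprime = _per_iteration_stiffness(constraint.k_str, iterations)
    s = kprime * (dist - constraint.d12) / ((wi + wj) * dist)
    p[i] -= wi * s * d
    p[j] += wj * s * d
    return p


def eval_bend(p1, p2, p3, p4, phi12: float) -> float:
    """C = arccos(n1 . n2) - phi12 for triangles (p1,p3,p2), (p1,p2,p4).

    The dot product is clamped to [-1, 1].  A degenerate triangle returns
    NaN, signalling the caller to skip the constraint this iteration.
    """
    p1, p2, p3, p4 = (np.asarray(q, float) for q in (p1, p2, p3, p4))
    n1 = np.cross(p3 - p1, p2 - p1)
    n2 = np.cross(p2 - p1, p4 - p1)
    l1, l2 = np.linalg.norm(n1), np.linalg.norm(n2)
    if l1 < 1e-12 or l2 < 1e-12:
        return float("nan")
    d = np.clip(np.dot(n1 / l1, n2 / l2), -1.0, 1.0)
    return float(np.arccos(d) - phi12)


def bend_gradients(p1, p2, p3, p4):
    """Analytic gradients of arccos(n1 . n2) wrt the four points.

    Returns (C_angle, [g1, g2, g3, g4]) where C_angle = arccos(n1 . n2);
    None when the configuration is degenerate or at the arccos endpoints
    (gradient undefined).
    """
    p1, p2, p3, p4 = (np.asarray(q, float) for q in (p1, p2, p3, p4))
    e2, e3, e4 = p2 - p1, p3 - p1, p4 - p1
    u1 = np.cross(e3, e2)
    u2 = np.cross(e2, e4)
    l1, l2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if l1 < 1e-12 or l2 < 1e-12:
        return None
    n1, n2 = u1 / l1, u2 / l2
    d = float(np.clip(np.dot(n1, n2), -1.0, 1.0))
    s2 = 1.0 - d * d
    if s2 < 1e-12:
        return None
    q1 = (n2 - d * n1) / l1
    q2 = (n1 - d * n2) / l2
    g3 = np.cross(e2, q1)
    g4 = np.cross(q2, e2)
    g2 = np.cross(q1, e3) + np.cross(e4, q2)
    g1 = -(g2 + g3 + g4)
    inv = -1.0 / np.sqrt(s2)
    return float(np.arccos(d)), [inv * g1, inv * g2, inv * g3, inv * g4]


def project_bend(positions: np.ndarray, constraint: BendConstraint,
                 inverse_masses: np.ndarray, iterations: int = 1
                 ) -> np.ndarray:
    """Mass-weighted projection of one bend constraint (copy returned).

    Positions move along the analytic gradient of the dihedral-angle
    constraint; near-degenerate gradients are skipped.
    """
    p = np.array(positions, dtype=np.float64)
    idx = [constraint.x1, constraint.x2, constraint.x3, constraint.x4]
    res = bend_gradients(*(p[k] for k in idx))
    if res is None:
        return p
    angle, grads = res
    cval = angle - constraint.phi12
    denom = sum(inverse_masses[k] * float(np.dot(g, g))
                for k, g in zip(idx, grads))
    if denom < 1e-12:
        return p
    kprime = _per_iteration_stiffness(constraint.k_bend, iterations)
    s = kprime * cval / denom
    for k, g in zip(idx, grads):
        p[k] -= s * inverse_masses[k] * g
    return p


# ---------------------------------------------------------------------------
# Collision
# ---------------------------------------------------------------------------

def generate_collision_constraints(
        predicted: np.ndarray,
        colliders: list[PlaneCollider | TriangleCollider],
        start: np.ndarray | None = None) -> list[CollisionConstraint]:
    """One inequality constraint per vertex ending on the wrong side of a
    static collider.  Colliders are fixed geometry — they are never moved
    by the solver."""
    out: list[CollisionConstraint] = []
    for col in colliders:
        if isinstance(col, PlaneCollider):
            depth = (predicted - col.point) @ col.normal
            for v in np.nonzero(depth < 0.0)[0]:
                out.append(CollisionConstraint(int(v), col.point, col.normal))
        elif isinstance(col, TriangleCollider):
            depth = (predicted - col.p0) @ col.normal
            below = depth < 0.0
            if not below.any():
                continue
            inside = _inside_triangle_footprint(
                predicted[below], col.p0, col.p1, col.p2, col.normal)
            for v, ok in zip(np.nonzero(below)[0], inside):
                if ok:
                    out.append(CollisionConstraint(int(v), col.p0, col.normal))
        else:
            raise TypeError(f"unknown collider type {type(col).__name__}")
    return out


def _inside_triangle_footprint(points, a, b, c, normal):
    """Barycentric test of points projected onto the triangle's plane."""
    v0, v1 = b - a, c - a
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    den = d00 * d11 - d01 * d01
    rel = points - a
    rel = rel - np.outer(rel @ normal, normal)
    d20 = rel @ v0
    d21 = rel @ v1
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    return (v >= -1e-12) & (w >= -1e-12) & (v + w <= 1.0 + 1e-12)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def solve_step(state: SoftBodyState, constraints: ConstraintSet,
               config: SolverConfig,
               colliders: list | None = None,
               external_accel: np.ndarray | None = None) -> SoftBodyState:
    """One PBD time step, in place.

    predict p = x + v dt (+ a dt^2); generate collision constraints from
    the predicted positions; ``config.iterations`` Gauss-Seidel sweeps in
    the fixed order stretch -> bend -> collision; then v = (p - x)/dt and
    x = p.  Pinned vertices are never moved.
    """
    config.validate()
    dt = config.dt
    w = state.inverse_masses
    x = state.positions
    p = x + state.velocities * dt
    if external_accel is not None:
        p += np.asarray(external_accel, float) * dt * dt
    p[state.pinned] = x[state.pinned]

    coll = generate_collision_constraints(p, colliders or [], start=x)
    if coll:
        cv = np.array([c.vertex for c in coll], dtype=np.int64)
        cp = np.array([c.point for c in coll], dtype=np.float64)
        cn = np.array([c.normal for c in coll], dtype=np.float64)

    ks = 1.0 - (1.0 - constraints.stretch_k) ** (1.0 / config.iterations)
    kb = 1.0 - (1.0 - constraints.bend_k) ** (1.0 / config.iterations)

    for _ in range(config.iterations):
        if len(constraints.stretch_ij):
            _kernels.sweep_stretch(p, w, constraints.stretch_ij,
                                   constraints.stretch_rest, ks,
                                   constraints.stretch_alive)
        if len(constraints.bend_verts):
            _kernels.sweep_bend(p, w, constraints.bend_verts,
                                constraints.bend_rest, kb,
                                constraints.bend_alive)
        if coll:
            _kernels.sweep_planes(p, w, cv, cp, cn)

    if not np.isfinite(p).all():
        bad = int(np.argmax(~np.isfinite(p).all(axis=1)))
        raise FloatingPointError(f"non-finite position at vertex {bad} after"
                                 " constraint projection")
    free = ~state.pinned
    state.velocities[free] = (p[free] - x[free]) / dt
    state.velocities[state.pinned] = 0.0
    state.positions[free] = p[free]
    return state


def total_energy(positions: np.ndarray, constraints: ConstraintSet) -> float:
    """E_tot = sum(k_str C_str^2 + k_bend C_bend^2) over alive constraints.

    Zero exactly when every weighted constraint is satisfied.
    """
    e = 0.0
    for row in np.nonzero(constraints.stretch_alive)[0]:
        i, j = constraints.stretch_ij[row]
        c = eval_stretch(positions[i], positions[j],
                         constraints.stretch_rest[row])
        e += constraints.stretch_k[row] * c * c
    for row in np.nonzero(constraints.bend_alive)[0]:
        q = constraints.bend_verts[row]
        c = eval_bend(*(positions[k] for k in q), constraints.bend_rest[row])
        if np.isfinite(c):
            e += constraints.bend_k[row] * c * c
    return float(e)


def tear_step(constraints: ConstraintSet, positions: np.ndarray,
              mode: str = "relative") -> list[int]:
    """Remove every breakable stretch constraint past its break threshold.

    ``relative`` mode breaks at extension ratio |p_i - p_j|/d12 - 1 >
    threshold; ``absolute`` at |p_i - p_j| - d12 > threshold.  Removal is
    permanent.  Returns the removed constraint rows for event logging.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    cand = constraints.stretch_alive & constraints.stretch_breakable
    rows = np.nonzero(cand)[0]
    if len(rows) == 0:
        return []
    ij = constraints.stretch_ij[rows]
    lengths = np.linalg.norm(positions[ij[:, 0]] - positions[ij[:, 1]], axis=1)
    rest = constraints.stretch_rest[rows]
    if mode == "relative":
        over = lengths / rest - 1.0
    else:
        over = lengths - rest
    broken = rows[over > constraints.stretch_threshold[rows]]
    constraints.stretch_alive[broken] = False
    return [int(r) for r in broken]
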