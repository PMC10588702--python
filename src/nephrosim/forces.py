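"""Force-based soft-body deformation: springs, damping, pressure, offset.

Each surface vertex is a unit-mass particle.  Per frame a composite force

    F_j = F_spring,j + F_damping,j + F_pressure,j + F_offset,j

is accumulated and integrated semi-implicitly: velocity first from the
force (dv = F dt / m), then a velocity rescale v <- v (1 - d dt) standing
in for the damping term, then position from the new velocity (dp = v dt).
Pressure acts per face as P * area along the current outward normal,
split in equal thirds to the face's vertices, which inflates a closed
surface (the "volumetric effect").  Interactive pokes are spread over
nearby vertices with an inverse-quadratic falloff F / (1 + d^2) so the
contact vertex always receives full strength, and can optionally drive
vertices inward along the surface normal (the offset component).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh import TriMesh, EdgeTopology, face_areas, face_normals, vertex_normals

__all__ = [
    "SoftBodyState",
    "ForceParams",
    "spring_forces",
    "pressure_forces",
    "apply_damping",
    "falloff_force",
    "add_force_to_vertex",
    "composite_force",
    "step",
    "kinetic_energy",
]

OFFSET_MODES = ("inward-normal", "fixed-direction")


@dataclass
class ForceParams:
    """Tunable force and integration parameters.

    Attributes
    ----------
    k_spring : float
        Edge spring stiffness, N/m.
    damping : float
        Velocity damping rate d, 1/s; applied as v (1 - d dt).
    pressure : float
        Surface pressure P, N/m^2; negative deflates.
    offset_magnitude : float
        Extra interaction force, N, pushing contacted vertices along the
        offset direction.
    offset_mode : str
        ``"inward-normal"`` (against the vertex normal at the contact) or
        ``"fixed-direction"`` (along ``offset_direction``).
    dt : float
        Time step, s.
    """

    k_spring: float = 200.0
    damping: float = 20.0
    pressure: float = 0.0
    offset_magnitude: float = 0.0
    offset_mode: str = "inward-normal"
    offset_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    dt: float = 0.01

    def validate(self, mass_min: float = 1.0) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.damping * self.dt <= 1.0:
            raise ValueError(
                f"damping*dt = {self.damping * self.dt:g} outside [0, 1]:"
                " velocities would flip sign"
            )
        if self.offset_mode not in OFFSET_MODES:
            raise ValueError(f"offset_mode must be one of {OFFSET_MODES}")
        if self.k_spring * self.dt ** 2 / mass_min > 1.0:
            warnings.warn(
                "k_spring*dt^2/m > 1: explicit integration may be unstable",
                RuntimeWarning,
                stacklevel=2,
            )


@dataclass
class SoftBodyState:
    """Particle state bound to a mesh: positions, velocities, masses,
    force accumulator, pin flags (pinned = infinite mass, never moves)."""

    positions: np.ndarray      # (n, 3) m
    velocities: np.ndarray     # (n, 3) m/s
    masses: np.ndarray         # (n,) kg
    force_accum: np.ndarray    # (n, 3) N
    pinned: np.ndarray         # (n,) bool

    @classmethod
    def from_mesh(cls, mesh: TriMesh, mass: float = 1.0) -> "SoftBodyState":
        n = mesh.vertex_count
        return cls(
            positions=mesh.vertices.copy(),
            velocities=np.zeros((n, 3)),
            masses=np.full(n, float(mass)),
            force_accum=np.zeros((n, 3)),
            pinned=np.zeros(n, dtype=bool),
        )

    def validate(self) -> None:
        n = len(self.positions)
        for name in ("velocities", "force_accum"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} shape mismatch")
        if (self.masses <= 0).any():
            raise ValueError("masses must be positive")

    @property
    def inverse_masses(self) -> np.ndarray:
        """1/m with pinned vertices at 0 (infinite mass)."""
        w = 1.0 / self.masses
        w[self.pinned] = 0.0
        return w


def spring_forces(topology: EdgeTopology, positions: np.ndarray,
                  k_spring: float) -> np.ndarray:
    """Linear (Hookean) edge-spring forces accumulated per vertex.

    Each edge pulls/pushes its endpoints toward its rest length with
    magnitude ``k_spring * (length - rest)``, equal and opposite, so the
    internal forces always sum to zero.  Coincident endpoints contribute
    nothing (direction undefined).
    """
    i, j = topology.edges[:, 0], topology.edges[:, 1]
    d = positions[j] - positions[i]
    lengths = np.linalg.norm(d, axis=1)
    ok = lengths > 0.0
    mag = np.zeros_like(lengths)
    mag[ok] = k_spring * (lengths[ok] - topology.rest_lengths[ok]) / lengths[ok]
    f = d * mag[:, None]  # force on i, toward j when stretched
    out = np.zeros_like(positions)
    np.add.at(out, i, f)
    np.add.at(out, j, -f)
    return out


def pressure_forces(mesh: TriMesh, positions: np.ndarray,
                    pressure: float) -> np.ndarray:
    """Pressure force P * area along the current outward face normal,
    distributed in equal thirds to each face vertex."""
    out = np.zeros_like(positions)
    if pressure == 0.0:
        return out
    areas = face_areas(mesh, positions)
    normals = face_normals(mesh, positions)
    per_face = (pressure / 3.0) * areas[:, None] * normals
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], per_face)
    return out


def apply_damping(velocity: np.ndarray, damping: float, dt: float) -> np.ndarray:
    """Velocity rescale v (1 - d dt); d dt = 1 stops motion dead."""
    if not 0.0 <= damping * dt <= 1.0:
        raise ValueError("damping*dt outside [0, 1]")
    return velocity * (1.0 - damping * dt)


def falloff_force(force: float, distance: float | np.ndarray):
    """Inverse-quadratic attenuation F / (1 + d^2).

    Full strength at zero distance, strictly decreasing with distance.
    """
    distance = np.asarray(distance, dtype=np.float64)
    if (distance < 0).any():
        raise ValueError("distance must be non-negative")
    return force / (1.0 + distance ** 2)


def add_force_to_vertex(state: SoftBodyState, mesh: TriMesh,
                        contact_point: np.ndarray, force_vector: np.ndarray,
                        radius: float = 0.0,
                        offset_magnitude: float = 0.0,
                        offset_mode: str = "inward-normal",
                        offset_direction=(0.0, 0.0, -1.0)) -> np.ndarray:
    """Load vertices near a contact point into the force accumulator.

    Every vertex within ``radius`` of ``contact_point`` (radius 0: the
    nearest vertex only) receives ``force_vector`` scaled by the falloff of
    its distance to the contact, plus an optional offset push of
    ``offset_magnitude`` driving it into the surface along the inward
    vertex normal (or a fixed direction).  Returns the per-vertex force
    actually added.  A zero-length force vector with zero offset is a no-op.
    """
    contact_point = np.asarray(contact_point, dtype=np.float64)
    force_vector = np.asarray(force_vector, dtype=np.float64)
    fmag = float(np.linalg.norm(force_vector))
    added = np.zeros_like(state.positions)
    if fmag == 0.0 and offset_magnitude == 0.0:
        return added
    dist = np.linalg.norm(state.positions - contact_point, axis=1)
    if radius <= 0.0:
        sel = np.zeros(len(dist), dtype=bool)
        sel[int(np.argmin(dist))] = True
    else:
        sel = dist <= radius
    scale = falloff_force(1.0, dist[sel])  # relative attenuation
    if fmag > 0.0:
        added[sel] = force_vector * scale[:, None]
    if offset_magnitude != 0.0:
        if offset_mode == "inward-normal":
            normals = vertex_normals(mesh, state.positions)
            added[sel] += -offset_magnitude * scale[:, None] * normals[sel]
        elif offset_mode == "fixed-direction":
            d = np.asarray(offset_direction, dtype=np.float64)
            d = d / np.linalg.norm(d)
            added[sel] += offset_magnitude * scale[:, None] * d
        else:
            raise ValueError(f"unknown offset_mode {offset_mode!r}")
    state.force_accum += added
    return added


def composite_force(mesh: TriMesh, topology: EdgeTopology,
                    state: SoftBodyState, params: ForceParams) -> np.ndarray:
    """Total per-vertex force: springs + pressure + accumulated interaction
    (including offset pushes).  The damping component is realized as the
    velocity rescale inside :func:`step`, not as an additive force.

    Raises on NaN with the offending component's name.
    """
    total = np.zeros_like(state.positions)
    for name, comp in (
        ("spring", spring_forces(topology, state.positions, params.k_spring)),
        ("pressure", pressure_forces(mesh, state.positions, params.pressure)),
        ("interaction/offset", state.force_accum),
    ):
        if not np.isfinite(comp).all():
            raise FloatingPointError(f"non-finite {name} force component")
        total += comp
    return total


def step(mesh: TriMesh, topology: EdgeTopology, state: SoftBodyState,
         params: ForceParams, step_index: int = 0) -> SoftBodyState:
    """One semi-implicit Euler step, in place.

    Order: accumulate composite force; dv = F dt / m; damping rescale;
    dp = v dt.  Pinned vertices never move and keep zero velocity.  The
    force accumulator is cleared afterwards; normals are functions of the
    positions and are recomputed from the moved surface by the next force
    evaluation.
    """
    f = composite_force(mesh, topology, state, params)
    free = ~state.pinned
    state.velocities[free] += f[free] * params.dt / state.masses[free, None]
    state.velocities = apply_damping(state.velocities, params.damping, params.dt)
    state.velocities[state.pinned] = 0.0
    state.positions[free] += state.velocities[free] * params.dt
    state.force_accum[:] = 0.0
    if not np.isfinite(state.positions).all():
        bad = int(np.argmax(~np.isfinite(state.positions).all(axis=1)))
        raise FloatingPointError(
            f"non-finite position at vertex {bad} on step {step_index}"
        )
    return state


def kinetic_energy(state: SoftBodyState) -> float:
    """Total kinetic energy sum(m |v|^2) / 2, J."""
    return float(0.5 * np.sum(state.masses * np.einsum(
        "ij,ij->i", state.velocities, state.velocities)))
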