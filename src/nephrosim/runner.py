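"""Configuration, simulation driver, metrics logging and reporting.

One YAML config fully determines a run; (config, seed) determines every
output byte.  Each frame of the hybrid loop is: accumulate forces and
scripted interaction events -> integrate velocities (with damping) ->
PBD constraint projection of the predicted positions -> tearing check ->
metrics record.  Outputs are an OBJ frame sequence (at the configured
stride), a metrics CSV and a JSON run report.

Metrics CSV schema (version 1), one row per step::

    step, e_tot, volume, kinetic_energy, max_cstr, max_cbend,
    active_constraints, tear_events, contact_force

``e_tot`` is the weighted constraint energy sum(k C^2); ``contact_force``
is the magnitude of interaction force applied that step — together with
``tear_events`` it forms the haptic-event stream a hardware layer would
render as vibration.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .mesh import TriMesh, build_edge_topology, connected_components, \
    is_closed, load_mesh, mesh_volume, save_mesh
from .forces import ForceParams, SoftBodyState, add_force_to_vertex, \
    apply_damping, composite_force, kinetic_energy
from .pbd import ConstraintSet, PlaneCollider, SolverConfig, TriangleCollider, \
    eval_bend, eval_stretch, solve_step, tear_step, total_energy
from .interact import Ray, boundary_cut_samples, cast_ray, mark_cut_path, \
    apply_cut, resect
from .fixtures import CANCEROUS, PhantomSpec, make_grid_sheet, make_icosphere, \
    make_kidney_phantom

__all__ = ["SimConfig", "MetricsRecord", "run", "validate", "load_config",
           "hybrid_step", "cut_demo", "METRICS_COLUMNS"]

METRICS_SCHEMA_VERSION = 1
REPORT_SCHEMA_VERSION = 1
METRICS_COLUMNS = (
    "step", "e_tot", "volume", "kinetic_energy", "max_cstr", "max_cbend",
    "active_constraints", "tear_events", "contact_force",
)

_FIXTURE_KINDS = ("icosphere", "grid", "phantom")


@dataclass
class SimConfig:
    """Validated simulation configuration.  Unknown YAML keys are rejected."""

    fixture: dict = field(default_factory=lambda: {
        "kind": "icosphere", "subdivision": 3, "radius": 1.0})
    mesh_path: str | None = None
    forces: ForceParams = field(default_factory=ForceParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    constraints: dict = field(default_factory=lambda: {
        "breakable": False, "break_threshold": 0.4})
    colliders: list = field(default_factory=list)
    interaction_script: str | None = None
    steps: int = 100
    seed: int = 0
    frame_stride: int = 0
    output_dir: str = "out"

    def validate_config(self) -> list[str]:
        """All invariant checks; returns a list of failure messages."""
        problems: list[str] = []
        try:
            self.forces.validate()
        except (ValueError, Warning) as exc:
            problems.append(f"forces: {exc}")
        try:
            self.solver.validate()
        except ValueError as exc:
            problems.append(f"solver: {exc}")
        if self.steps < 0:
            problems.append("steps must be >= 0")
        if self.frame_stride < 0:
            problems.append("frame_stride must be >= 0")
        if self.forces.dt != self.solver.dt:
            problems.append("forces.dt and solver.dt must agree")
        if self.mesh_path is None:
            kind = self.fixture.get("kind")
            if kind not in _FIXTURE_KINDS:
                problems.append(
                    f"fixture.kind must be one of {_FIXTURE_KINDS}, got {kind!r}")
        for k, col in enumerate(self.colliders):
            if col.get("type") not in ("plane", "triangle"):
                problems.append(f"collider {k}: unknown type {col.get('type')!r}")
        thr = self.constraints.get("break_threshold", 0.0)
        if self.constraints.get("breakable") and thr <= 0:
            problems.append("constraints.break_threshold must be positive"
                            " when breakable")
        return problems

    def build_mesh(self) -> TriMesh:
        if self.mesh_path is not None:
            return load_mesh(self.mesh_path)
        fx = dict(self.fixture)
        kind = fx.pop("kind")
        if kind == "icosphere":
            return make_icosphere(fx.get("subdivision", 3), fx.get("radius", 1.0))
        if kind == "grid":
            return make_grid_sheet(fx.get("nx", 5), fx.get("ny", 5),
                                   fx.get("spacing", 0.1))
        if kind == "phantom":
            fx.setdefault("seed", self.seed)
            mesh, _ = make_kidney_phantom(PhantomSpec(**fx))
            return mesh
        raise ValueError(f"unknown fixture kind {kind!r}")

    def build_colliders(self) -> list:
        out = []
        for col in self.colliders:
            if col["type"] == "plane":
                out.append(PlaneCollider(col["point"], col["normal"]))
            else:
                out.append(TriangleCollider(col["p0"], col["p1"], col["p2"]))
        return out


_CONFIG_KEYS = {
    "fixture", "mesh_path", "forces", "solver", "constraints", "colliders",
    "interaction_script", "steps", "seed", "frame_stride", "output_dir",
}


def load_config(path: str | Path) -> SimConfig:
    """Parse a YAML config, rejecting unknown keys at every level."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(doc) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(doc)
    if "forces" in kwargs:
        bad = set(kwargs["forces"]) - set(ForceParams.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown forces keys: {sorted(bad)}")
        kwargs["forces"] = ForceParams(**kwargs["forces"])
    if "solver" in kwargs:
        bad = set(kwargs["solver"]) - set(SolverConfig.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown solver keys: {sorted(bad)}")
        kwargs["solver"] = SolverConfig(**kwargs["solver"])
    return SimConfig(**kwargs)


def validate(config_path: str | Path) -> dict:
    """Check a config file (and its mesh, if any) without simulating.

    Returns ``{"checks": [{"name", "passed", "detail"}, ...], "ok": bool}``.
    """
    checks = []
    try:
        cfg = load_config(config_path)
    except Exception as exc:
        return {"ok": False,
                "checks": [{"name": "parse", "passed": False,
                            "detail": str(exc)}]}
    checks.append({"name": "parse", "passed": True, "detail": ""})
    problems = cfg.validate_config()
    checks.append({"name": "parameter-invariants", "passed": not problems,
                   "detail": "; ".join(problems)})
    if not problems:
        try:
            mesh = cfg.build_mesh()
            build_edge_topology(mesh)  # raises on non-manifold
            checks.append({"name": "mesh-manifold", "passed": True,
                           "detail": f"{mesh.face_count} faces"})
        except Exception as exc:
            checks.append({"name": "mesh-manifold", "passed": False,
                           "detail": str(exc)})
    return {"ok": all(c["passed"] for c in checks), "checks": checks}


@dataclass
class MetricsRecord:
    step: int
    e_tot: float
    volume: float
    kinetic_energy: float
    max_cstr: float
    max_cbend: float
    active_constraints: int
    tear_events: int
    contact_force: float

    def row(self) -> str:
        return (
            f"{self.step},{self.e_tot:.12e},{self.volume:.12e},"
            f"{self.kinetic_energy:.12e},{self.max_cstr:.12e},"
            f"{self.max_cbend:.12e},{self.active_constraints},"
            f"{self.tear_events},{self.contact_force:.12e}"
        )


def _max_violations(positions: np.ndarray, cset: ConstraintSet
                    ) -> tuple[float, float]:
    mc = 0.0
    for row in np.nonzero(cset.stretch_alive)[0]:
        i, j = cset.stretch_ij[row]
        mc = max(mc, abs(eval_stretch(positions[i], positions[j],
                                      cset.stretch_rest[row])))
    mb = 0.0
    for row in np.nonzero(cset.bend_alive)[0]:
        q = cset.bend_verts[row]
        c = eval_bend(*(positions[k] for k in q), cset.bend_rest[row])
        if np.isfinite(c):
            mb = max(mb, abs(c))
    return mc, mb


def hybrid_step(mesh: TriMesh, topology, state: SoftBodyState,
                params: ForceParams, cset: ConstraintSet,
                solver: SolverConfig, colliders: list | None = None,
                tearing: bool = True, break_mode: str = "relative"
                ) -> list[int]:
    """One frame of the combined scheme: forces set tentative velocities,
    constraint projection corrects the predicted positions, then tearing.

    Returns the rows of any constraints torn this frame.
    """
    f = composite_force(mesh, topology, state, params)
    free = ~state.pinned
    state.velocities[free] += f[free] * params.dt / state.masses[free, None]
    state.velocities = apply_damping(state.velocities, params.damping, params.dt)
    state.velocities[state.pinned] = 0.0
    state.force_accum[:] = 0.0
    solve_step(state, cset, solver, colliders=colliders)
    if tearing:
        return tear_step(cset, state.positions, mode=break_mode)
    return []


def _load_interaction_events(path: str | Path) -> dict[int, list[dict]]:
    events = json.loads(Path(path).read_text())
    by_step: dict[int, list[dict]] = {}
    for ev in events:
        by_step.setdefault(int(ev.get("step", 0)), []).append(ev)
    return by_step


def run(config: SimConfig, out_dir: str | Path | None = None) -> dict:
    """Execute a configured simulation; write frames, metrics and report.

    Returns the run report dict (also written to ``report.json``).
    """
    problems = config.validate_config()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    mesh = config.build_mesh()
    topo = build_edge_topology(mesh)
    state = SoftBodyState.from_mesh(mesh)
    cset = ConstraintSet.from_topology(
        topo, k_str=config.solver.k_str, k_bend=config.solver.k_bend,
        breakable=config.constraints.get("breakable", False),
        break_threshold=config.constraints.get("break_threshold", 0.0),
    )
    colliders = config.build_colliders()
    closed = is_closed(mesh)
    events = (_load_interaction_events(config.interaction_script)
              if config.interaction_script else {})

    metrics_path = out / "metrics.csv"
    t0 = time.perf_counter()
    failure = None
    save_mesh(TriMesh(state.positions, mesh.faces, mesh.face_labels),
              out / "frame_000000.obj")
    with open(metrics_path, "w") as mf:
        mf.write("# nephrosim metrics schema v%d\n" % METRICS_SCHEMA_VERSION)
        mf.write(",".join(METRICS_COLUMNS) + "\n")
        for step_i in range(1, config.steps + 1):
            contact = 0.0
            for ev in events.get(step_i, []):
                contact += _apply_event(ev, mesh, state, config)
            try:
                torn = hybrid_step(
                    mesh, topo, state, config.forces, cset, config.solver,
                    colliders=colliders,
                    break_mode=config.solver.break_mode)
            except FloatingPointError as exc:
                failure = {"step": step_i, "error": str(exc)}
                break
            mc, mb = _max_violations(state.positions, cset)
            rec = MetricsRecord(
                step=step_i,
                e_tot=total_energy(state.positions, cset),
                volume=mesh_volume(mesh, state.positions) if closed else 0.0,
                kinetic_energy=kinetic_energy(state),
                max_cstr=mc,
                max_cbend=mb,
                active_constraints=cset.n_alive,
                tear_events=len(torn),
                contact_force=contact,
            )
            mf.write(rec.row() + "\n")
            if config.frame_stride and step_i % config.frame_stride == 0:
                save_mesh(TriMesh(state.positions, mesh.faces, mesh.face_labels),
                          out / f"frame_{step_i:06d}.obj")

    report = {
        "schema": REPORT_SCHEMA_VERSION,
        "version": __version__,
        "config": _config_dict(config),
        "wall_time_s": round(time.perf_counter() - t0, 6),
        "steps_completed": failure["step"] - 1 if failure else config.steps,
        "final_constraint_graph_components":
            cset.alive_stretch_graph_components(mesh.vertex_count),
        "active_constraints": cset.n_alive,
        "failure": failure,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _apply_event(ev: dict, mesh: TriMesh, state: SoftBodyState,
                 config: SimConfig) -> float:
    """Apply one scripted interaction event; returns the contact-force
    magnitude for the haptic stream."""
    kind = ev.get("type")
    if kind == "poke":
        ray = Ray(ev["origin"], np.asarray(ev["direction"], float)
                  / np.linalg.norm(ev["direction"]))
        hit = cast_ray(mesh, ray, positions=state.positions)
        if hit is None:
            return 0.0
        _, point = hit
        fvec = np.asarray(ev["force"], float)
        add_force_to_vertex(
            state, mesh, point, fvec, radius=float(ev.get("radius", 0.0)),
            offset_magnitude=config.forces.offset_magnitude,
            offset_mode=config.forces.offset_mode,
            offset_direction=config.forces.offset_direction)
        return float(np.linalg.norm(fvec))
    if kind == "force_at":
        fvec = np.asarray(ev["force"], float)
        add_force_to_vertex(state, mesh, np.asarray(ev["point"], float), fvec,
                            radius=float(ev.get("radius", 0.0)))
        return float(np.linalg.norm(fvec))
    raise ValueError(f"unknown interaction event type {kind!r}")


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["forces"] = asdict(config.forces)
    d["solver"] = asdict(config.solver)
    return d


# ---------------------------------------------------------------------------
# Scripted mark -> cut -> resect session
# ---------------------------------------------------------------------------

def cut_demo(spec: PhantomSpec | None = None, out_dir: str | Path | None = None,
             settle_steps: int = 0, params: ForceParams | None = None,
             solver: SolverConfig | None = None) -> dict:
    """The training task, headless: mark the tumor boundary, cut along it,
    resect the cancerous lobe; returns (and optionally writes) the report.

    The report carries the resection quality metrics a trainer would score:
    excised face count, label purity of the specimen, healthy-face damage,
    and the final component count.
    """
    spec = spec or PhantomSpec()
    mesh, regions = make_kidney_phantom(spec)
    topo = build_edge_topology(mesh)
    params = params or ForceParams()
    solver = solver or SolverConfig()
    cset = ConstraintSet.from_topology(topo, k_str=solver.k_str,
                                       k_bend=solver.k_bend)
    state = SoftBodyState.from_mesh(mesh)
    for k in range(settle_steps):
        hybrid_step(mesh, topo, state, params, cset, solver, tearing=False)

    samples = boundary_cut_samples(mesh, CANCEROUS)
    path = mark_cut_path(mesh, samples)
    comps_before = cset.alive_stretch_graph_components(mesh.vertex_count)
    apply_cut(cset, path, mode="sever")
    remaining, excised = resect(mesh, path, CANCEROUS)

    cancer = regions.get(CANCEROUS, set())
    excised_count = excised.face_count
    purity = (sum(1 for v in (excised.face_labels or {}).values()
                  if v == CANCEROUS) / excised_count if excised_count else 0.0)
    healthy_damage = sum(1 for v in (excised.face_labels or {}).values()
                         if v != CANCEROUS)
    cancer_left_behind = sum(1 for v in (remaining.face_labels or {}).values()
                             if v == CANCEROUS)
    report = {
        "schema": REPORT_SCHEMA_VERSION,
        "phantom": asdict(spec),
        "total_faces": mesh.face_count,
        "cancerous_faces": len(cancer),
        "crossed_edges": len(path.crossed_edges),
        "path_closed": bool(path.closed),
        "components": (len(connected_components(remaining))
                       + len(connected_components(excised))),
        "excised_faces": excised_count,
        "excised_label_purity": purity,
        "healthy_faces_excised": healthy_damage,
        "cancerous_faces_remaining": cancer_left_behind,
        "constraint_graph_components_before": comps_before,
        "constraint_graph_components_after":
            cset.alive_stretch_graph_components(mesh.vertex_count),
        "face_conservation":
            remaining.face_count + excised.face_count == mesh.face_count,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_mesh(mesh, out / "phantom.obj")
        save_mesh(remaining, out / "remaining.obj")
        save_mesh(excised, out / "excised.obj")
        (out / "resection_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
    return report
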