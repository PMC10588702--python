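# Methods

## Scope and architecture

nephrosim simulates a single-layer deformable surface — a closed triangle
mesh standing in for the kidney capsule with an attached tumor lobe — and
the interactions needed for a resection rehearsal: poking, marking a cut,
tearing, and separating the labelled region.  There is deliberately no
volumetric (tetrahedral) interior, no fascia or multilayer tissue, no
vasculature, and no re-meshing at the cut: cutting severs constraints
along existing edges, so the vertex count is constant throughout a
session.

Modules follow the pipeline order: `mesh` (data model, OBJ/PLY/STL I/O,
normals/areas/volume/topology), `forces` (mass–spring–pressure model),
`pbd` (constraint solver and tearing), `interact` (rays, cut paths,
resection), `fixtures` (procedural geometry), `runner`/`cli` (config,
batch driver, metrics).

## Force model

Each vertex is a particle of mass 1 kg by default.  Per frame:

1. accumulate forces: edge springs (linear in extension, along the edge),
   per-face pressure `P · area · n̂` split in equal thirds to the face's
   vertices, and any scripted interaction forces;
2. `v += F Δt / m` (semi-implicit Euler velocity update);
3. `v ← v (1 − d Δt)` (damping as a velocity rescale, not an additive
   force — this matches the governing formula exactly and is
   unconditionally stable for `d Δt ≤ 1`);
4. `p += v Δt`; pinned vertices (infinite mass) never move.

Equal-thirds pressure distribution was chosen over angle-weighted
distribution as the simplest rule consistent with a per-face force
statement; for a closed surface the net pressure force still cancels to
machine precision (divergence theorem), which the tests assert.

Interactive pokes spread over vertices within a radius of the contact
point, attenuated by `1/(1 + d²)` so the contact vertex receives full
strength at distance zero.  An optional *offset* component additionally
drives contacted vertices along the inward vertex normal (or a fixed
direction), emulating an instrument pressing into tissue.

Parameter defaults (all configurable, none hard-coded in the driver):

| parameter | default | unit | why |
|---|---|---|---|
| `k_spring` | 200 | N/m | firm but stable at the default Δt (`k Δt²/m = 0.02`) |
| `damping` | 20 | 1/s | heavily damped, tissue-like; `d Δt = 0.2` |
| `pressure` | 5 | N/m² | a few-tenths-percent inflation against the constraints |
| `dt` | 0.01 | s | interactive frame scale; explicit-integration guard warns if `k Δt²/m > 1`, rejects `d Δt > 1` |
| mass | 1 | kg | unit-mass convention |

## Constraint solver

Position-based dynamics: predict `p = x + v Δt`, generate collision
constraints from predicted positions against static colliders
(half-spaces and single triangles; colliders are never moved, and
self-collision is out of scope), then run a fixed number of Gauss–Seidel
sweeps projecting constraints in place, in the documented order
stretch → bend → collision; finally `v = (p − x)/Δt`, `x = p`.

* Stretch projection is the standard mass-weighted split
  `Δp_i = −(w_i/(w_i+w_j)) C n̂`, exact in one projection at stiffness 1.
* Bend constraints use the dihedral form `arccos(n1·n2) − φ12` with the
  normal convention: for interior edge (x1, x2) oriented so the first
  face traverses x1→x2, the two normals are those of triangles
  (x1, x3, x2) and (x1, x2, x4).  A flat, consistently wound pair gives
  φ12 = 0.  The arccos argument is clamped to [−1, 1]; degenerate
  triangles and vanishing gradients skip the constraint for that sweep.
  The analytic gradient is validated against finite differences in the
  tests.  The rest angle is recorded from the rest geometry, but the
  normals must be evaluated at current positions — evaluating both at
  rest would make the constraint identically zero and inert.
* Stiffness `k ∈ [0, 1]` is applied per sweep as
  `k′ = 1 − (1−k)^(1/iterations)` so the total correction is independent
  of the iteration count.
* Sweeps are sequential and in place by definition; they are compiled
  with numba for speed, and the test suite asserts the compiled sweeps
  reproduce the scalar reference projections exactly.

Breakable stretch constraints tear when the relative extension
`|p_i − p_j|/d12 − 1` exceeds their threshold (an absolute-extension mode
exists); removal is permanent and logged.  Tearing is the only mesh
"destruction" mechanism — no stochastic face deletion.

### Hybrid loop

Per frame: the force model updates velocities (step 1–3 above, no
position move), then the constraint solver predicts, projects and moves.
This ordering — forces propose, constraints dispose — is a design choice;
the two schemes do not prescribe an interleaving, and this one keeps the
constraint solver's stability guarantees as the last word each frame.
Its long-horizon behavior is tested directly: 5,000 pressurized steps on
a subdivision-3 icosphere stay bounded, hold the volume above rest, and
after pressure release the kinetic energy decays to ~10⁻²² of its peak.

A note on "kinetic energy non-increasing after release": a damped elastic
body released from a loaded equilibrium must transiently *gain* kinetic
energy (velocity is near zero while the spring recoil is not), so
instantaneous per-step monotonicity from the release instant is not a
property any such simulator can have.  The meaningful stability property,
and the one asserted, is that the recoil transient peaks within ~100
steps and the energy then decays monotonically (sampled every 100 steps,
within double-precision noise) to a negligible fraction of the peak.

## Interaction and resection

Rays use watertight parametric (Möller–Trumbore) intersection; picking
scans all faces and keeps the smallest positive hit (ties to the lower
face index), which is exact and fast enough at the mesh sizes used
(an independent all-faces linear-system solver cross-checks it in tests).

A cut path is an ordered list of surface samples (point + face).
Consecutive samples are connected by the shortest face-adjacency walk,
and every edge separating successive faces on that walk is recorded as
*crossed*.  `apply_cut` either severs the stretch (and spanning bend)
constraints on crossed edges immediately, or marks them breakable so load
tears them.  It never adds constraints.

`resect` requires a closed path and separates faces by the crossed-edge
set, trying two rules that correspond to the two ways a closed path can
encode a cut: (1) the crossed edges are the seam — face adjacency across
them is severed and faces are grouped by the remaining connectivity;
(2) the crossed edges are the rungs bridging the two sides (a zigzag
path) — the vertex graph splits when they are removed and each face
follows its majority vertex side.  If neither rule separates the surface
the cut is rejected as non-separating.  The component with the best
match to the requested label is the specimen; all other components merge
into the remaining organ.  Seam vertices are duplicated, one copy per
side, so both outputs are independent meshes; face conservation is exact
by construction.

The scripted "ideal trainee" cut (`boundary_cut_samples`) zigzags across
every label-boundary edge in loop order, connecting consecutive zigzags
by walks over healthy faces only.  Its crossed set therefore contains the
entire boundary loop and never enters the tumor interior, which is what
makes the demo resection exact (100 % specimen purity, zero healthy
damage).

## Procedural phantom

`make_kidney_phantom` builds, on a unit icosphere: a smooth radial
indentation (the hilum concavity; depth jittered by the seed), a smooth
exophytic bulge around a configurable axis, face labels from the
spherical-cap footprint of the tumor sphere, and finally anisotropic
scaling to organ half-extents (default 5.5 × 3.5 × 2.5 cm, a ~25 %
radius-fraction lesion — a 3–5 cm-class peripheral mass on an adult
kidney).  Labels are cleaned to a single edge-connected region with a
smooth boundary so the boundary is one simple edge loop.  The default
resolution (subdivision 3, 1,280 faces) keeps interactive CPU rates while
remaining fine enough for stable dihedral constraints; the cap-area
fraction of the labelled region is checked against the analytic
spherical-cap value in tests.

What the phantom does *not* emulate: patient-specific shape, tissue
heterogeneity, vasculature, perinephric fat, or contact with surrounding
organs.  Passing tests on the phantom therefore demonstrate correctness
of the geometry/physics machinery and of the cut/resect logic under
clean labels — not clinical realism of the deformation.

## Determinism and logging

Everything is a pure function of (config, seed): the only random source
is the phantom's seeded jitter, metrics are written with fixed formatting,
and repeated runs are byte-identical (asserted in tests and measured by
the acceptance script).  The metrics CSV logs, per step: constraint
energy `E_tot`, enclosed volume, kinetic energy, worst stretch/bend
violations, live constraint count, tear events and contact-force
magnitude — the last two forming the haptic-event stream a hardware layer
would render as vibration.

## Problem sizes

Default test and acceptance workloads use icospheres at subdivision 0–3
(20–1,280 faces) and the 1,280-face phantom; the long-horizon stability
check runs 5,000 + 2,000 frames at 642 vertices.  These sizes were chosen
as the smallest that exercise every code path meaningfully while keeping
the full suite comfortably fast on one CPU.

## Known limitations

* Single surface layer: post-tear flaps look geometrically crude
  (no fascia), exactly as expected for a constraint-removal cut.
* No self-collision; colliders are static primitives.
* Cuts follow existing edges; accuracy of a marked path is limited by
  mesh resolution (no re-meshing).
* The bend constraint can stall at exactly antiparallel normals
  (gradient undefined); the solver skips such configurations for the
  sweep rather than regularizing them.
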