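# nephrosim

Headless soft-body physics for rehearsing laparoscopic partial nephrectomy
(LPN) — the keyhole removal of a kidney tumor while sparing the organ.
The package reproduces the physics core of a VR training simulator as a
deterministic, scriptable library: a triangle-mesh kidney deforms under
programmable forces, a constraint solver keeps the deformation stable, and
scripted "controller" gestures mark a cut around a labelled tumor lobe,
tear its connections, and resect it.  It is aimed at researchers studying
surgical-simulation physics and at anyone who needs a reproducible,
display-free testbed for mesh cutting and tearing algorithms.

## The model

The soft body is a closed triangle surface whose vertices are unit-mass
particles.  Two complementary schemes act on it each frame.

**Force model.**  Every vertex j accumulates a composite force

    F_j = F_spring,j + F_damping,j + F_pressure,j + F_offset,j

where springs along mesh edges follow Hooke's law `k (|x_i − x_j| − d12)`,
pressure acts per face as `P · ΔA` along the outward normal (inflating a
closed surface — the volumetric effect), interactive pokes attenuate with
distance as `F / (1 + d²)`, and the damping term is the velocity rescale
`v ← v (1 − d Δt)`.  Integration is semi-implicit Euler:
`Δv = F Δt / m`, then `Δp = v Δt`.

**Constraint solver (position-based dynamics).**  Predicted positions are
projected onto stretch constraints `C_str = |x1 − x2| − d12`, dihedral
bend constraints `C_bend = arccos(n1·n2) − φ12`, and collision
inequalities, with a fixed number of Gauss–Seidel sweeps minimizing the
total energy `E_tot = Σ (k_str C_str² + k_bend C_bend²)`; the velocity is
then re-derived from the realized position change.  Stretch constraints
may be breakable: past a relative-extension threshold they are removed
permanently, which is how a marked cut — or a pulled tumor lobe — tears
free.

No scanned anatomy ships with the package.  A procedural phantom
(`make_kidney_phantom`) generates a bean-shaped kidney with an exophytic
lobe whose faces are labelled `"cancerous"`, so the whole
mark → cut → resect task runs offline and bit-reproducibly.

## Worked example

Run the scripted resection task on the default phantom:

```bash
nephrosim cut-demo --out demo_out
```

Key lines of the printed report (also written to
`demo_out/resection_report.json`, next to the phantom and both resected
meshes as OBJ):

```
total_faces: 1280
cancerous_faces: 24
crossed_edges: 42
components: 2
excised_faces: 24
excised_label_purity: 1.0
healthy_faces_excised: 0
cancerous_faces_remaining: 0
face_conservation: True
```

Read: the 1280-face phantom carries a 24-face tumor lobe; the scripted cut
crossed 42 mesh edges while encircling it; resection produced exactly two
pieces; the 24-face specimen is 100 % tumor, zero healthy faces were
damaged, no tumor was left behind, and no face was lost or invented — the
ideal score a trainee's cut is measured against.

A plain deformation run uses a YAML config (see
`src/nephrosim/configs/default.yaml` for all defaults):

```bash
nephrosim simulate --config src/nephrosim/configs/default.yaml --out run_out
```

which writes `metrics.csv` (per-step constraint energy, enclosed volume,
kinetic energy, worst constraint violations, tear events and contact
forces — the haptic-event stream) plus OBJ frames and a JSON run report.
`nephrosim validate --config …` checks a config without simulating.

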