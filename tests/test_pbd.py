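"""Constraint evaluation, Gauss-Seidel projection, energy, tearing."""

import numpy as np
import pytest

from nephrosim import (
    BendConstraint,
    ConstraintSet,
    PlaneCollider,
    SoftBodyState,
    SolverConfig,
    StretchConstraint,
    TriMesh,
    build_edge_topology,
    eval_bend,
    eval_stretch,
    generate_collision_constraints,
    make_icosphere,
    project_bend,
    project_stretch,
    solve_step,
    tear_step,
    total_energy,
)
from nephrosim.pbd import bend_gradients, _per_iteration_stiffness
from nephrosim import _kernels


def two_particle_state(p0, p1):
    mesh = TriMesh(np.array([p0, p1], dtype=float),
                   np.empty((0, 3), dtype=int))
    return SoftBodyState.from_mesh(mesh)


class TestStretch:
    def test_eval_at_rest_is_zero(self):
        assert eval_stretch([0, 0, 0], [1, 0, 0], 1.0) == 0.0

    def test_eval_stretched(self):
        assert eval_stretch([0, 0, 0], [2, 0, 0], 1.0) == pytest.approx(1.0)

    def test_eval_compressed_negative(self):
        assert eval_stretch([0, 0, 0], [0.5, 0, 0], 1.0) < 0.0

    def test_symmetric_split_equal_masses(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        c = StretchConstraint(0, 1, d12=1.0, k_str=1.0)
        w = np.ones(2)
        out = project_stretch(pos, c, w)
        np.testing.assert_allclose(out[0], [0.5, 0, 0], atol=1e-12)
        np.testing.assert_allclose(out[1], [1.5, 0, 0], atol=1e-12)
        assert abs(eval_stretch(out[0], out[1], 1.0)) < 1e-12

    def test_pinned_endpoint_takes_no_correction(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        c = StretchConstraint(0, 1, d12=1.0, k_str=1.0)
        w = np.array([0.0, 1.0])  # vertex 0 pinned
        out = project_stretch(pos, c, w)
        np.testing.assert_array_equal(out[0], pos[0])
        np.testing.assert_allclose(out[1], [1.0, 0, 0], atol=1e-12)

    def test_zero_stiffness_no_movement(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        c = StretchConstraint(0, 1, d12=1.0, k_str=0.0)
        out = project_stretch(pos, c, np.ones(2))
        np.testing.assert_array_equal(out, pos)

    def test_center_of_mass_preserved(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            pos = rng.standard_normal((2, 3))
            c = StretchConstraint(0, 1, d12=0.7, k_str=0.8)
            out = project_stretch(pos, c, np.ones(2))
            np.testing.assert_allclose(out.mean(axis=0), pos.mean(axis=0),
                                       atol=1e-12)

    def test_coincident_points_skipped_with_warning(self):
        pos = np.zeros((2, 3))
        c = StretchConstraint(0, 1, d12=1.0)
        with pytest.warns(RuntimeWarning):
            out = project_stretch(pos, c, np.ones(2))
        np.testing.assert_array_equal(out, pos)

    def test_per_iteration_stiffness_is_total(self):
        """n applications of k' leave the same residual fraction as one
        application of k."""
        k, n = 0.6, 7
        kp = _per_iteration_stiffness(k, n)
        assert (1 - kp) ** n == pytest.approx(1 - k, abs=1e-12)


class TestBend:
    def test_coplanar_zero(self):
        c = eval_bend([0, 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, -1, 0], 0.0)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_normals(self):
        # fold the second triangle 90 degrees out of plane
        c = eval_bend([0, 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, 0, 1], 0.0)
        assert c == pytest.approx(np.pi / 2, abs=1e-12)

    def test_arccos_argument_clamped(self):
        # numerically parallel normals: dot may exceed 1 by rounding
        c = eval_bend([0, 0, 0], [1, 0, 0], [0.3, 1, 0], [0.7, -1, 0], 0.0)
        assert np.isfinite(c)

    def test_degenerate_triangle_flagged_nan(self):
        c = eval_bend([0, 0, 0], [1, 0, 0], [0.5, 0, 0], [0.5, -1, 0], 0.0)
        assert np.isnan(c)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pts = rng.standard_normal((4, 3))
            res = bend_gradients(*pts)
            if res is None:
                continue
            _, grads = res
            eps = 1e-6
            for k in range(4):
                for d in range(3):
                    pp = pts.copy()
                    pp[k, d] += eps
                    pm = pts.copy()
                    pm[k, d] -= eps
                    num = (eval_bend(*pp, 0.0) - eval_bend(*pm, 0.0)) / (2 * eps)
                    assert abs(num - grads[k][d]) < 1e-6

    def test_at_rest_angle_zero_displacement(self, folded_quad):
        topo = build_edge_topology(folded_quad)
        phi = float(topo.rest_angles[0])
        q = topo.dihedral_vertices[0]
        c = BendConstraint(*map(int, q), phi12=phi, k_bend=1.0)
        out = project_bend(folded_quad.vertices, c, np.ones(4))
        np.testing.assert_allclose(out, folded_quad.vertices, atol=1e-12)

    def test_mirror_symmetric_displacements(self):
        # quad symmetric about the y = 0 plane, folded symmetrically
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0],
                        [0.5, 1.0, 0.5], [0.5, -1.0, 0.5]])
        c = BendConstraint(0, 1, 2, 3, phi12=0.0, k_bend=1.0)
        out = project_bend(pts, c, np.ones(4))
        d2 = out[2] - pts[2]
        d3 = out[3] - pts[3]
        # wing displacements mirror: y components opposite, x/z equal
        assert d2[1] == pytest.approx(-d3[1], abs=1e-12)
        assert d2[0] == pytest.approx(d3[0], abs=1e-12)
        assert d2[2] == pytest.approx(d3[2], abs=1e-12)

    def test_folded_quad_converges_to_rest_angle(self, folded_quad):
        """50 stiffness-1 sweeps drive the dihedral to its target within
        1e-3 rad (angle recomputed directly each sweep)."""
        target = 0.4
        topo = build_edge_topology(folded_quad)
        q = tuple(map(int, topo.dihedral_vertices[0]))
        c = BendConstraint(*q, phi12=target, k_bend=1.0)
        pos = folded_quad.vertices.copy()
        w = np.ones(4)
        for _ in range(50):
            pos = project_bend(pos, c, w)
        residual = eval_bend(*(pos[k] for k in q), target)
        assert abs(residual) < 1e-3


class TestCollision:
    def test_vertex_below_ground_gets_constraint(self):
        pred = np.array([[0.0, 0.0, -0.1], [0.0, 0.0, 0.5]])
        cons = generate_collision_constraints(
            pred, [PlaneCollider([0, 0, 0], [0, 0, 1])])
        assert len(cons) == 1 and cons[0].vertex == 0
        np.testing.assert_allclose(cons[0].normal, [0, 0, 1])

    def test_all_above_plane_empty(self):
        pred = np.ones((5, 3))
        cons = generate_collision_constraints(
            pred, [PlaneCollider([0, 0, 0], [0, 0, 1])])
        assert cons == []

    def test_solve_step_enforces_ground_plane(self, icosphere2):
        state = SoftBodyState.from_mesh(icosphere2)
        state.velocities[:, 2] = -5.0  # drive the body into the floor
        cset = ConstraintSet()
        cfg = SolverConfig(iterations=5, dt=0.05)
        ground = PlaneCollider([0, 0, -1.0], [0, 0, 1])
        for _ in range(10):
            solve_step(state, cset, cfg, colliders=[ground])
        assert state.positions[:, 2].min() >= -1.0 - 1e-9


class TestSolveStep:
    def test_empty_constraints_is_free_flight(self, icosphere2):
        state = SoftBodyState.from_mesh(icosphere2)
        state.velocities[:] = [1.0, 0.0, 0.0]
        cfg = SolverConfig(iterations=3, dt=0.01)
        solve_step(state, ConstraintSet(), cfg)
        np.testing.assert_allclose(
            state.positions, icosphere2.vertices + [0.01, 0, 0], atol=1e-14)

    def test_all_pinned_unchanged(self, icosphere2):
        state = SoftBodyState.from_mesh(icosphere2)
        state.pinned[:] = True
        topo = build_edge_topology(icosphere2)
        cset = ConstraintSet.from_topology(topo)
        cfg = SolverConfig(iterations=5, dt=0.01)
        solve_step(state, cset, cfg,
                   external_accel=np.tile([0, 0, -9.8],
                                          (icosphere2.vertex_count, 1)))
        np.testing.assert_array_equal(state.positions, icosphere2.vertices)
        assert not state.velocities.any()

    def test_two_particle_against_hand_rolled_reference(self):
        """Stretched single edge: compare to an explicit scalar PBD solver."""
        dt, iters, k = 0.01, 10, 1.0
        state = two_particle_state([0.0, 0, 0], [2.0, 0, 0])
        state.velocities[:] = [[0.1, 0, 0], [-0.2, 0.3, 0]]
        cset = ConstraintSet([StretchConstraint(0, 1, d12=1.0, k_str=k)])
        x_old = state.positions.copy()

        # reference: predict, project iters times, update velocity
        p = state.positions + state.velocities * dt
        kp = 1.0 - (1.0 - k) ** (1.0 / iters)
        for _ in range(iters):
            d = p[0] - p[1]
            dist = np.linalg.norm(d)
            corr = kp * (dist - 1.0) / (2.0 * dist) * d
            p[0] -= corr
            p[1] += corr
        v_ref = (p - x_old) / dt

        solve_step(state, cset, SolverConfig(iterations=iters, dt=dt))
        np.testing.assert_allclose(state.positions, p, atol=1e-10)
        np.testing.assert_allclose(state.velocities, v_ref, atol=1e-10)
        d = state.positions[0] - state.positions[1]
        assert abs(np.linalg.norm(d) - 1.0) < 1e-6

    def test_velocity_equals_position_change_over_dt(self, icosphere2):
        topo = build_edge_topology(icosphere2)
        state = SoftBodyState.from_mesh(icosphere2)
        rng = np.random.default_rng(0)
        state.velocities[:] = 0.2 * rng.standard_normal(state.velocities.shape)
        cset = ConstraintSet.from_topology(topo, k_str=1.0, k_bend=0.5)
        x_old = state.positions.copy()
        cfg = SolverConfig(iterations=4, dt=0.02)
        solve_step(state, cset, cfg)
        np.testing.assert_allclose(
            state.velocities, (state.positions - x_old) / cfg.dt, atol=1e-12)

    def test_kernel_sweep_matches_scalar_projection(self):
        """The compiled stretch sweep reproduces sequential scalar
        projections exactly."""
        rng = np.random.default_rng(5)
        mesh = make_icosphere(1)
        topo = build_edge_topology(mesh)
        pos = mesh.vertices + 0.2 * rng.standard_normal(mesh.vertices.shape)
        w = np.ones(mesh.vertex_count)
        cons = [StretchConstraint(int(i), int(j), float(r), 0.7)
                for (i, j), r in zip(topo.edges, topo.rest_lengths)]
        ref = pos.copy()
        for c in cons:
            ref = project_stretch(ref, c, w, iterations=3)
        cset = ConstraintSet(cons)
        got = pos.copy()
        kp = np.full(len(cons), _per_iteration_stiffness(0.7, 3))
        _kernels.sweep_stretch(got, w, cset.stretch_ij, cset.stretch_rest,
                               kp, cset.stretch_alive)
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_bend_kernel_matches_scalar_projection(self):
        rng = np.random.default_rng(6)
        mesh = make_icosphere(1)
        topo = build_edge_topology(mesh)
        pos = mesh.vertices + 0.1 * rng.standard_normal(mesh.vertices.shape)
        w = np.ones(mesh.vertex_count)
        cons = [BendConstraint(*map(int, q), phi12=float(phi), k_bend=0.5)
                for q, phi in zip(topo.dihedral_vertices, topo.rest_angles)]
        ref = pos.copy()
        for c in cons:
            ref = project_bend(ref, c, w, iterations=2)
        cset = ConstraintSet(bend=cons)
        got = pos.copy()
        kp = np.full(len(cons), _per_iteration_stiffness(0.5, 2))
        _kernels.sweep_bend(got, w, cset.bend_verts, cset.bend_rest, kp,
                            cset.bend_alive)
        np.testing.assert_allclose(got, ref, atol=1e-10)


class TestTotalEnergy:
    def test_rest_configuration_zero(self, icosphere2):
        topo = build_edge_topology(icosphere2)
        cset = ConstraintSet.from_topology(topo)
        assert total_energy(icosphere2.vertices, cset) == pytest.approx(
            0.0, abs=1e-18)

    def test_single_constraint_k_c_squared(self):
        cset = ConstraintSet([StretchConstraint(0, 1, d12=1.0, k_str=1.0)])
        cset.stretch_k[0] = 2.0  # weighted energy term beyond the PBD range
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert total_energy(pos, cset) == pytest.approx(2.0, abs=1e-14)

    def test_non_increasing_across_sweeps(self):
        """Stiffness-1 Gauss-Seidel sweeps never raise the constraint
        energy on a 20-constraint fixture."""
        rng = np.random.default_rng(9)
        mesh = make_icosphere(0)  # 30 edges; use the first 20
        topo = build_edge_topology(mesh)
        cons = [StretchConstraint(int(i), int(j), float(r), 1.0)
                for (i, j), r in list(zip(topo.edges,
                                          topo.rest_lengths))[:20]]
        cset = ConstraintSet(cons)
        pos = mesh.vertices + 0.3 * rng.standard_normal(mesh.vertices.shape)
        w = np.ones(mesh.vertex_count)
        kp = np.ones(len(cons))
        energies = [total_energy(pos, cset)]
        for _ in range(15):
            _kernels.sweep_stretch(pos, w, cset.stretch_ij, cset.stretch_rest,
                                   kp, cset.stretch_alive)
            energies.append(total_energy(pos, cset))
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))
        assert energies[-1] < energies[0]


class TestTearing:
    def test_past_threshold_removed(self):
        cset = ConstraintSet([StretchConstraint(0, 1, 1.0, breakable=True,
                                                break_threshold=0.4)])
        removed = tear_step(cset, np.array([[0.0, 0, 0], [2.5, 0, 0]]))
        assert removed == [0] and cset.n_stretch_alive == 0

    def test_below_threshold_retained(self):
        cset = ConstraintSet([StretchConstraint(0, 1, 1.0, breakable=True,
                                                break_threshold=0.4)])
        removed = tear_step(cset, np.array([[0.0, 0, 0], [1.2, 0, 0]]))
        assert removed == [] and cset.n_stretch_alive == 1

    def test_unbreakable_never_removed(self):
        cset = ConstraintSet([StretchConstraint(0, 1, 1.0)])
        assert tear_step(cset, np.array([[0.0, 0, 0], [9.0, 0, 0]])) == []

    def test_absolute_mode(self):
        cset = ConstraintSet([StretchConstraint(0, 1, 2.0, breakable=True,
                                                break_threshold=0.5)])
        # extension 0.6 m: breaks in absolute mode, survives relative
        # (ratio 0.3)
        pos = np.array([[0.0, 0, 0], [2.6, 0, 0]])
        assert tear_step(cset, pos, mode="relative") == []
        assert tear_step(cset, pos, mode="absolute") == [0]

    def test_tearing_is_monotone(self):
        rng = np.random.default_rng(12)
        mesh = make_icosphere(1)
        topo = build_edge_topology(mesh)
        cset = ConstraintSet.from_topology(topo, breakable=True,
                                           break_threshold=0.3)
        counts = [cset.n_stretch_alive]
        pos = mesh.vertices.copy()
        for _ in range(10):
            pos += 0.05 * rng.standard_normal(pos.shape)
            tear_step(cset, pos)
            counts.append(cset.n_stretch_alive)
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_pulled_lobe_detaches_into_second_component(self, phantom):
        """Stretching every bridge between the tumor vertices and the rest
        past threshold splits the constraint graph in two."""
        mesh, regions = phantom
        topo = build_edge_topology(mesh)
        cancer_faces = regions["cancerous"]
        cancer_verts = {int(v) for f in cancer_faces for v in mesh.faces[f]}
        interior = cancer_verts - {
            int(v) for fi in range(mesh.face_count) if fi not in cancer_faces
            for v in mesh.faces[fi]}
        bridges = {tuple(e) for e in map(tuple, topo.edges)
                   if (int(e[0]) in interior) != (int(e[1]) in interior)}
        assert bridges
        cset = ConstraintSet.from_topology(
            topo, break_threshold=0.2, breakable_edges=bridges)
        assert int(cset.stretch_breakable.sum()) == len(bridges)
        before = cset.alive_stretch_graph_components(mesh.vertex_count)
        # pull the interior lobe vertices far out along +x
        pos = mesh.vertices.copy()
        pos[sorted(interior)] += [1.0, 0.0, 0.0]
        removed = tear_step(cset, pos)
        assert len(removed) == len(bridges)
        after = cset.alive_stretch_graph_components(mesh.vertex_count)
        assert before == 1 and after == 2


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        cons = [StretchConstraint(0, 1, 1.0, 0.9, breakable=True,
                                  break_threshold=0.4),
                StretchConstraint(1, 2, 0.5, 0.7)]
        bends = [BendConstraint(0, 1, 2, 3, phi12=0.3, k_bend=0.5)]
        cset = ConstraintSet(cons, bends)
        path = tmp_path / "c.json"
        cset.to_json(path)
        back = ConstraintSet.from_json(path)
        np.testing.assert_array_equal(back.stretch_ij, cset.stretch_ij)
        np.testing.assert_allclose(back.stretch_rest, cset.stretch_rest)
        np.testing.assert_allclose(back.bend_rest, cset.bend_rest)
        assert back.stretch_breakable.tolist() == [True, False]

    def test_dead_constraints_not_serialized(self):
        cset = ConstraintSet([StretchConstraint(0, 1, 1.0),
                              StretchConstraint(1, 2, 1.0)])
        cset.remove_stretch([0])
        doc = cset.to_json()
        assert len(doc["stretch"]) == 1 and doc["stretch"][0]["i"] == 1
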