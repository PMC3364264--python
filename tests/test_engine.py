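"""Shape-matching engine: weights, rotation fit, goals, integration,
volume preservation and whole-step properties."""
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from kinheart.activation import ContractionCurve, ContractionSchedule
from kinheart.engine import (
    EngineError, Simulation, apply_stiffness_iterations,
    compute_goal_positions, compute_region_weights, fit_rotation,
    integrate_step, preserve_global_volume,
)
from kinheart.experiments import build_cylinder_sim, sheet_sag
from kinheart.fibers import FiberField
from kinheart.generators import CylinderSpec, SheetSpec
from kinheart.mesh import SimState, TetMesh, build_local_regions, total_volume

from conftest import UNIT_TET_VERTS


def _const_fibers(n, direction=(0.0, 0.0, 1.0)):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return FiberField(np.tile(d, (n, 1)), np.full(n, "ventricular", dtype=object))


def _const_schedule(c=0.0, a_mc=0.5):
    return ContractionSchedule(
        curves={"ventricular": ContractionCurve(((0.0, c),))},
        cycle_T=1.0, a_mc=a_mc,
    )


class TestRegionWeights:
    def test_uniform_five_members(self):
        rel = np.random.default_rng(0).normal(size=(5, 3))
        np.testing.assert_allclose(
            compute_region_weights(rel, mode="uniform"), 0.2)

    def test_along_fiber_members_weigh_more(self):
        rel = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]])
        w = compute_region_weights(rel, fiber=np.array([1.0, 0, 0]))
        assert w[0] == w[1] and w[2] == w[3]
        assert w[0] > w[2]
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w > 0).all()

    def test_central_member_gets_mean_weight(self):
        rel = np.array([[0.0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0]])
        w = compute_region_weights(rel, fiber=np.array([1.0, 0, 0]))
        unnorm = w / w.sum()  # already normalized; compare ratios instead
        assert w[0] == pytest.approx((w[1] + w[2] + w[3]) / 3.0, rel=1e-9)

    def test_degenerate_region_rejected(self):
        with pytest.raises(EngineError):
            compute_region_weights(np.zeros((3, 3)), fiber=np.array([1.0, 0, 0]))


class TestFitRotation:
    def test_exact_recovery_and_identity(self, rng):
        p = rng.normal(size=(6, 3))
        w = np.full(6, 1 / 6)
        r0 = Rotation.random(random_state=11).as_matrix()
        assert np.abs(fit_rotation(p, p @ r0.T, w) - r0).max() < 1e-9
        assert np.abs(fit_rotation(p, p, w) - np.eye(3)).max() < 1e-12

    def test_matches_brute_force_minimizer(self, rng):
        """SVD polar solution vs direct minimization over rotation vectors."""
        p = rng.normal(size=(6, 3))
        q = p @ Rotation.random(random_state=3).as_matrix().T \
            + 0.05 * rng.normal(size=(6, 3))
        w = rng.uniform(0.5, 1.5, size=6)
        w /= w.sum()

        def objective(rotvec):
            m = Rotation.from_rotvec(rotvec).as_matrix()
            return float((w[:, None] * (p @ m.T - q) ** 2).sum())

        best = min(
            (minimize(objective, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
             for x0 in rng.normal(size=(8, 3))),
            key=lambda res: res.fun,
        )
        ours = objective(Rotation.from_matrix(fit_rotation(p, q, w)).as_rotvec())
        assert ours <= best.fun + 1e-4

    def test_coincident_points_give_identity(self):
        p = np.zeros((4, 3))
        r = fit_rotation(p, p, np.full(4, 0.25))
        np.testing.assert_allclose(r, np.eye(3))

    def test_reflection_repaired(self, rng):
        """A mirrored target must still produce a proper rotation."""
        p = rng.normal(size=(5, 3))
        q = p * np.array([1.0, 1.0, -1.0])
        r = fit_rotation(p, q, np.full(5, 0.2))
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)


@pytest.fixture
def tet_context(unit_tet):
    fibers = _const_fibers(4)
    regions = build_local_regions(unit_tet, fibers, "uniform")
    return unit_tet, regions, fibers


class TestGoals:
    def test_rest_is_fixed_point_without_activation(self, tet_context):
        mesh, regions, fibers = tet_context
        g = compute_goal_positions(mesh.vertices, regions, fibers,
                                   _const_schedule(0.0), 0.0)
        assert np.abs(g - mesh.vertices).max() < 1e-10

    def test_translation_equivariance(self, tet_context):
        mesh, regions, fibers = tet_context
        shift = np.array([3.0, -2.0, 5.0])
        g = compute_goal_positions(mesh.vertices + shift, regions, fibers,
                                   _const_schedule(0.0), 0.0)
        np.testing.assert_allclose(g, mesh.vertices + shift, atol=1e-10)

    def test_single_region_hand_oracle(self, tet_context):
        """Independent recomputation: contraction matrix, weighted
        covariance, SVD polar rotation, goal blending, done longhand for
        the single-tet mesh (all four 1-ring regions coincide)."""
        mesh, regions, fibers = tet_context
        sched = _const_schedule(1.0, a_mc=0.1)  # s_f = 0.9, fiber = z
        g = compute_goal_positions(mesh.vertices, regions, fibers, sched, 0.0)

        s_f = 0.9
        t_mat = np.diag([1 / np.sqrt(s_f), 1 / np.sqrt(s_f), s_f])
        w = np.full(4, 0.25)
        centroid = UNIT_TET_VERTS.mean(axis=0)
        q_rel = UNIT_TET_VERTS - centroid
        p_scaled = q_rel @ t_mat.T
        a = (w[:, None] * q_rel).T @ p_scaled
        u, _, vt = np.linalg.svd(a)
        r = u @ vt
        if np.linalg.det(r) < 0:
            u[:, 2] *= -1
            r = u @ vt
        expected = centroid + p_scaled @ r.T
        np.testing.assert_allclose(g, expected, atol=1e-12)

    def test_stiffness_one_iteration_equals_goal_computation(self, tet_context):
        mesh, regions, fibers = tet_context
        sched = _const_schedule(1.0, a_mc=0.3)
        g1 = compute_goal_positions(mesh.vertices, regions, fibers, sched, 0.0)
        gm = apply_stiffness_iterations(mesh.vertices, regions, fibers, sched,
                                        0.0, M=1)
        np.testing.assert_allclose(gm, g1)

    def test_rest_fixed_point_for_any_m(self, tet_context):
        mesh, regions, fibers = tet_context
        gm = apply_stiffness_iterations(mesh.vertices, regions, fibers,
                                        _const_schedule(0.0), 0.0, M=7)
        assert np.abs(gm - mesh.vertices).max() < 1e-9


def test_larger_m_is_stiffer_under_gravity():
    """Hanging-plate tip sag is non-increasing in the stiffness iteration
    count."""
    spec = SheetSpec(x_len=100.0, y_len=20.0, z_len=100.0, n_x=6, n_y=2, n_z=6)
    sags = [sheet_sag((1.0, 0.0, 0.0), spec=spec, stiffness_M=m, n_steps=400)
            for m in (1, 3, 10)]
    assert sags[0] >= sags[1] >= sags[2]
    assert sags[2] < sags[0]  # strictly stiffer overall


class TestIntegrateStep:
    def _state(self, x, v=None, f=None, m=None):
        n = len(x)
        return SimState(
            positions=np.asarray(x, float),
            velocities=np.zeros((n, 3)) if v is None else np.asarray(v, float),
            time=0.0,
            masses=np.ones(n) if m is None else np.asarray(m, float),
            ext_forces=np.zeros((n, 3)) if f is None else np.asarray(f, float),
        )

    def test_at_goal_at_rest_is_stationary(self):
        x = np.array([[1.0, 2.0, 3.0]])
        new = integrate_step(self._state(x), x.copy(), h=0.01)
        np.testing.assert_array_equal(new.positions, x)
        np.testing.assert_array_equal(new.velocities, 0.0)

    def test_goal_reached_in_one_step(self):
        x = np.array([[0.0, 0.0, 0.0]])
        d = np.array([[0.5, -1.0, 2.0]])
        new = integrate_step(self._state(x), x + d, h=0.02, damping=1.0)
        np.testing.assert_allclose(new.positions, x + d, atol=1e-12)

    def test_force_term_isolation(self):
        x = np.array([[0.0, 0.0, 0.0]])
        a = np.array([[0.0, 0.0, -9800.0]])
        m = np.array([2.5])
        new = integrate_step(self._state(x, f=m[:, None] * a, m=m), x.copy(),
                             h=0.01)
        np.testing.assert_allclose(new.velocities, 0.01 * a, atol=1e-12)

    def test_nonpositive_h_rejected(self):
        x = np.array([[0.0, 0.0, 0.0]])
        with pytest.raises(EngineError):
            integrate_step(self._state(x), x, h=0.0)


class TestVolumePreservation:
    def test_identity_at_target(self, small_cylinder):
        mesh = small_cylinder.mesh
        out = preserve_global_volume(mesh, mesh.vertices, total_volume(mesh))
        np.testing.assert_array_equal(out, mesh.vertices)

    def test_corrects_uniformly_scaled_mesh(self, small_cylinder):
        mesh = small_cylinder.mesh
        target = total_volume(mesh)
        out = preserve_global_volume(mesh, 1.1 * mesh.vertices, target)
        assert total_volume(mesh, out) == pytest.approx(target, rel=1e-6)

    def test_systole_correction_keeps_tets_uninverted(self):
        from kinheart.mesh import signed_tet_volumes

        gen, sim = build_cylinder_sim(
            a_mc=0.5, spec=CylinderSpec(n_radial=2, n_circumferential=12,
                                        n_axial=4))
        sim.run(int(round(0.6 * 1.1 / 0.01)))  # into full activation
        vols = signed_tet_volumes(sim.state.positions, gen.mesh.tets)
        assert (vols > 0).all()


def _small_sim(**kwargs):
    return build_cylinder_sim(
        spec=CylinderSpec(n_radial=2, n_circumferential=12, n_axial=4),
        **kwargs)


class TestStep:
    def test_rest_state_stationary_without_activation(self):
        gen, sim = _small_sim(a_mc=0.0)
        sim.run(100)
        drift = np.abs(sim.state.positions - gen.mesh.vertices).max()
        assert drift < 1e-8

    def test_rigid_motion_equivariance(self):
        rot = Rotation.from_euler("xyz", [20.0, -35.0, 50.0],
                                  degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 12.0])
        states = []
        for transform in (False, True):
            gen, sim = _small_sim(a_mc=0.5)
            sim.state.time = 0.45  # mid-ramp, so the step actually contracts
            if transform:
                sim.state.positions = sim.state.positions @ rot.T + shift
            sim.step()
            states.append(sim.state.positions)
        np.testing.assert_allclose(states[0] @ rot.T + shift, states[1],
                                   atol=1e-6)

    def test_translation_moves_goals_exactly(self):
        gen, sim = _small_sim(a_mc=0.5)
        shift = np.array([7.0, 1.0, -4.0])
        g0 = apply_stiffness_iterations(sim.state.positions, sim.regions,
                                        sim.fibers, sim.schedule, 0.6, 10)
        g1 = apply_stiffness_iterations(sim.state.positions + shift,
                                        sim.regions, sim.fibers, sim.schedule,
                                        0.6, 10)
        np.testing.assert_allclose(g1, g0 + shift, atol=1e-9)

    def test_volume_drift_below_tolerance_every_frame(self):
        gen, sim = _small_sim(a_mc=0.5)
        v0 = total_volume(gen.mesh)
        for _ in range(40):
            sim.step()
            drift = abs(total_volume(gen.mesh, sim.state.positions) - v0) / v0
            assert drift < 1e-6

    def test_fitted_rotations_stay_proper_during_systole(self):
        from kinheart.engine import _fit_rotations, _region_matrices

        gen, sim = _small_sim(a_mc=0.5)
        sim.run(50)
        regions = sim.regions
        tmats = _region_matrices(regions, sim.fibers, sim.schedule,
                                 sim.state.time)
        p = np.einsum("eij,ej->ei", tmats[regions.region_of_entry],
                      regions.rest_rel)
        roe = regions.region_of_entry
        cent = regions.centroids(sim.state.positions)
        q = sim.state.positions[regions.members] - cent[roe]
        a = np.add.reduceat(
            (regions.weights[:, None] * q)[:, :, None] * p[:, None, :],
            regions.ptr[:-1], axis=0)
        r = _fit_rotations(a)
        np.testing.assert_allclose(
            np.einsum("rij,rik->rjk", r, r), np.tile(np.eye(3), (len(r), 1, 1)),
            atol=1e-8)
        np.testing.assert_allclose(np.linalg.det(r), 1.0, atol=1e-8)

    def test_finite_under_extreme_forces(self):
        """10^6 x body-weight dragging forces never produce non-finite
        coordinates."""
        gen, sim = _small_sim(a_mc=0.5)
        m = sim.state.masses
        sim.state.ext_forces[:4] = 1e6 * m[:4, None] * 9800.0
        for _ in range(10):
            sim.step()
        assert np.isfinite(sim.state.positions).all()
        assert np.isfinite(sim.state.velocities).all()

    def test_pinned_vertices_hold_position(self):
        gen, sim = _small_sim(a_mc=0.5)
        sim.pins = gen.labels["top"]
        sim.run(30)
        np.testing.assert_array_equal(sim.state.positions[sim.pins],
                                      gen.mesh.vertices[sim.pins])

    def test_snapshot_restore_roundtrip(self, tmp_path):
        gen, sim = _small_sim(a_mc=0.5)
        sim.run(10)
        sim.snapshot(tmp_path / "state.npz")
        pos = sim.state.positions.copy()
        sim.run(5)
        sim.restore(tmp_path / "state.npz")
        np.testing.assert_array_equal(sim.state.positions, pos)
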