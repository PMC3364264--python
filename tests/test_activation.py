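"""Time-contraction curves, fiber scaling, contraction matrices, phase field."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinheart.activation import (
    ContractionCurve, ContractionSchedule, build_contraction_matrix,
    build_phase_shift_field, contraction_matrices, eval_curve, fiber_scale,
)
from kinheart.mesh import MeshError


@pytest.fixture
def trapezoid():
    return ContractionCurve()  # ramp 0.25-0.5, plateau 0.5-0.75, ramp down


class TestCurve:
    @pytest.mark.parametrize(
        "phase, expected",
        [(0.6, 1.0), (0.1, 0.0), (0.375, 0.5), (0.25, 0.0), (0.875, 0.5)],
    )
    def test_trapezoid_values(self, trapezoid, phase, expected):
        assert eval_curve(trapezoid, phase * 2.0, 2.0) == pytest.approx(expected)

    def test_periodicity(self, trapezoid):
        # up to fp rounding in the phase computation
        for t in np.linspace(0.0, 1.1, 23):
            assert eval_curve(trapezoid, t, 1.1) == pytest.approx(
                eval_curve(trapezoid, t + 1.1, 1.1), abs=1e-9)

    def test_delay_shifts_phase(self, trapezoid):
        assert eval_curve(trapezoid, 0.7, 1.0, delay=0.1) == pytest.approx(
            eval_curve(trapezoid, 0.6, 1.0))

    def test_knot_validation(self):
        with pytest.raises(ValueError):
            ContractionCurve(((0.5, 0.0), (0.2, 1.0)))  # not increasing
        with pytest.raises(ValueError):
            ContractionCurve(((0.0, 1.5),))  # c out of range
        with pytest.raises(ValueError):
            ContractionCurve(())


class TestFiberScale:
    def test_worked_value(self):
        """20% maximum contraction at full activation scales the fiber to
        exactly 0.8."""
        assert fiber_scale(1.0, 0.2) == 0.8

    @pytest.mark.parametrize("c, a_mc, expected",
                             [(0.0, 0.7, 1.0), (0.5, 0.5, 0.75)])
    def test_linear_formula(self, c, a_mc, expected):
        assert fiber_scale(c, a_mc) == pytest.approx(expected)

    @given(c=st.floats(0.0, 1.0), a_mc=st.floats(0.0, 0.99),
           dc=st.floats(0.0, 1.0), da=st.floats(0.0, 0.99))
    @settings(derandomize=True, max_examples=200)
    def test_monotone_decreasing_in_both_arguments(self, c, a_mc, dc, da):
        base = fiber_scale(c, a_mc)
        assert fiber_scale(min(c + dc, 1.0), a_mc) <= base
        assert fiber_scale(c, min(a_mc + da, 0.99)) <= base
        assert 0.0 < base <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fiber_scale(1.5, 0.2)
        with pytest.raises(ValueError):
            fiber_scale(0.5, 1.0)


class TestContractionMatrix:
    def test_identity_at_unit_scale(self):
        cm = build_contraction_matrix(np.array([0.0, 0.0, 1.0]), 1.0)
        np.testing.assert_allclose(cm.matrix, np.eye(3), atol=1e-15)

    def test_eigenstructure_for_axis_fiber(self):
        cm = build_contraction_matrix(np.array([0.0, 0.0, 1.0]), 0.8)
        eig = np.sort(np.linalg.eigvalsh(cm.matrix))
        s_t = 1.0 / np.sqrt(0.8)  # = 1.1180339887...
        np.testing.assert_allclose(eig, [0.8, s_t, s_t], atol=1e-12)
        assert np.linalg.det(cm.matrix) == pytest.approx(1.0, abs=1e-12)
        # fiber is an eigenvector with eigenvalue s_f
        np.testing.assert_allclose(cm.matrix @ cm.fiber, 0.8 * cm.fiber,
                                   atol=1e-12)

    def test_determinant_one_on_random_draws(self, rng):
        f = rng.normal(size=(1000, 3))
        f /= np.linalg.norm(f, axis=1, keepdims=True)
        s = rng.uniform(0.05, 1.0, size=1000)
        mats = contraction_matrices(f, s)
        np.testing.assert_allclose(np.linalg.det(mats), 1.0, atol=1e-9)
        # symmetric positive-definite
        np.testing.assert_allclose(mats, np.swapaxes(mats, 1, 2), atol=1e-12)
        assert (np.linalg.eigvalsh(mats) > 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_contraction_matrix(np.array([0.0, 0.0, 2.0]), 0.8)
        with pytest.raises(ValueError):
            build_contraction_matrix(np.array([0.0, 0.0, 1.0]), 0.0)


class TestSchedule:
    def test_excluded_regions_never_contract(self, trapezoid):
        sched = ContractionSchedule(curves={"ventricular": trapezoid},
                                    cycle_T=1.0, a_mc=0.5)
        labels = np.array(["ventricular", "excluded"], dtype=object)
        c = sched.contraction(labels, 0.6)
        assert c[0] == pytest.approx(1.0)
        assert c[1] == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            ContractionSchedule(a_mc=1.2)
        with pytest.raises(ValueError):
            ContractionSchedule(cycle_T=0.0)


class TestPhaseShiftField:
    def test_unit_tet_distances(self, unit_tet):
        delays = build_phase_shift_field(unit_tet, [0], speed=1.0)
        # direct unit edges from the right-angle corner to each other vertex
        np.testing.assert_allclose(delays, [0.0, 1.0, 1.0, 1.0], atol=1e-12)

    def test_speed_scales_delays(self, unit_tet):
        d1 = build_phase_shift_field(unit_tet, [0], speed=1.0)
        d2 = build_phase_shift_field(unit_tet, [0], speed=500.0)
        np.testing.assert_allclose(d2, d1 / 500.0)

    def test_triangle_inequality_along_edges(self, small_cylinder):
        mesh = small_cylinder.mesh
        delays = build_phase_shift_field(mesh, [0], speed=1.0)
        assert (delays >= 0).all()
        assert delays[0] == 0.0
        e = mesh.edges()
        lengths = np.linalg.norm(
            mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
        assert (np.abs(delays[e[:, 0]] - delays[e[:, 1]]) <= lengths + 1e-9).all()

    def test_no_sources_is_an_error(self, unit_tet):
        with pytest.raises(MeshError):
            build_phase_shift_field(unit_tet, [], speed=1.0)
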