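import numpy as np
import pytest

from drivenrnn import (
    classify_stationary_point,
    continue_fixed_points,
    jacobian,
    random_restart_search,
    rotation_plane,
    solve_fixed_point,
)
from drivenrnn.fixedpoints import FixedPointFailure

from conftest import reservoir_from_arrays


class TestSolveFixedPoint:
    def test_trivial_solution_at_zero_input(self, stable_small):
        fp = solve_fixed_point(stable_small, 0.0)
        assert isinstance(fp, type(fp)) and not isinstance(fp, FixedPointFailure)
        assert fp.residual_max == 0.0
        np.testing.assert_array_equal(fp.location, np.zeros(stable_small.n))

    def test_single_neuron_closed_form(self, single_neuron):
        # -x + w s = 0 -> phi = s for w = 1
        fp = solve_fixed_point(single_neuron, 0.5)
        assert fp.location[0] == pytest.approx(0.5, abs=1e-12)
        assert fp.label == "sink"

    def test_residual_meets_tolerance(self, stable_n200):
        fp = solve_fixed_point(stable_n200, 1.0, tol=1e-13)
        assert fp.residual_max < 1e-13
        assert fp.label == "sink"
        # rotational local dynamics: complex pairs with negative real parts
        complex_eigs = fp.eigenvalues[fp.eigenvalues.imag > 0]
        assert complex_eigs.size > 0
        assert np.all(complex_eigs.real < 0)

    def test_failure_carries_best_residual(self, stable_small):
        # an absurdly tight tolerance cannot be met; the failure object
        # still reports the best candidate instead of silently passing
        out = solve_fixed_point(stable_small, 0.7, tol=1e-30)
        assert isinstance(out, FixedPointFailure)
        assert out.residual_max > 0

    def test_warm_and_cold_starts_agree_in_stable_regime(self, stable_small):
        rng = np.random.default_rng(0)
        ref = solve_fixed_point(stable_small, 0.4)
        for _ in range(3):
            x0 = rng.uniform(-1, 1, stable_small.n)
            other = solve_fixed_point(stable_small, 0.4, x0)
            assert np.max(np.abs(other.location - ref.location)) < 1e-8


class TestContinuation:
    def test_grid_covers_interval_including_zero(self, stable_small):
        cont = continue_fixed_points(stable_small, s_max=1.0, delta=0.01)
        assert len(cont.grid) == 201
        assert 0.0 in cont.grid
        assert cont.grid.min() == pytest.approx(-1.0)
        assert cont.grid.max() == pytest.approx(1.0)
        assert not cont.failed

    def test_single_neuron_branch_is_identity(self, single_neuron):
        cont = continue_fixed_points(single_neuron, s_max=1.0, delta=0.1)
        np.testing.assert_allclose(
            cont.locations()[:, 0], cont.grid, atol=1e-12
        )

    def test_odd_symmetry_of_stationary_points(self, stable_small):
        # tanh and the drive are odd, so phi(-s) = -phi(s)
        cont = continue_fixed_points(stable_small, s_max=0.5, delta=0.05)
        locs = cont.locations()
        np.testing.assert_allclose(locs, -locs[::-1], atol=1e-10)

    def test_stable_gain_yields_smooth_sink_curve(self, stable_small):
        cont = continue_fixed_points(stable_small, s_max=1.0, delta=0.05)
        assert all(p.label == "sink" for p in cont.points)
        steps = np.linalg.norm(np.diff(cont.locations(), axis=0), axis=1)
        # consecutive solutions shift smoothly: no jumps relative to the
        # typical step and slow variation between neighbouring steps
        assert steps.max() < 10 * np.median(steps)
        ratios = steps[1:] / steps[:-1]
        assert ratios.max() < 1.5 and ratios.min() > 1 / 1.5


class TestClassification:
    @pytest.mark.parametrize(
        "eig, label",
        [
            ([-1 + 2j, -1 - 2j, -0.3], "sink"),
            ([0.5, -0.3], "saddle"),
            ([0.2, 0.9 + 1j, 0.9 - 1j], "source"),
        ],
    )
    def test_label_examples(self, eig, label):
        got, n_unstable, marginal = classify_stationary_point(np.array(eig))
        assert got == label
        assert n_unstable == sum(1 for e in eig if np.real(e) > 0)
        assert not marginal

    def test_marginal_flag_on_zero_real_part(self):
        _, _, marginal = classify_stationary_point(np.array([0.0 + 1j, -1.0]))
        assert marginal

    def test_agrees_with_sign_census_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            eig = np.linalg.eigvals(rng.standard_normal((6, 6)))
            label, n_unstable, _ = classify_stationary_point(eig)
            pos = sum(1 for e in eig if e.real > 0)
            neg = sum(1 for e in eig if e.real < 0)
            if pos == 0:
                assert label == "sink"
            elif neg == 0:
                assert label == "source"
            else:
                assert label == "saddle"
            assert n_unstable == pos

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            classify_stationary_point(np.array([]))


class TestRandomRestarts:
    def test_stable_regime_has_unique_sink(self, stable_small):
        pts = random_restart_search(stable_small, 0.3, n_restarts=12, seed=0)
        assert len(pts) == 1
        assert pts[0].label == "sink"

    def test_strong_gain_spawns_saddles_at_zero_input(self):
        from drivenrnn import NetworkSpec, build_reservoir

        res = build_reservoir(NetworkSpec(60, 0.2, 2.0, 21))
        pts = random_restart_search(res, 0.0, n_restarts=40, seed=1)
        assert len(pts) > 1
        assert any(p.label == "saddle" for p in pts)

    def test_deduplication_merges_repeat_finds(self, stable_small):
        many = random_restart_search(stable_small, 0.0, n_restarts=25, seed=2)
        # every restart converges to the unique sink; one survivor
        assert len(many) == 1


class TestRotationPlane:
    def _point_at_origin(self, res):
        return solve_fixed_point(res, 0.0)

    def test_canonical_rotation_block_spans_full_plane(self):
        # jacobian at x=0 is W - I; choose W = J + I for J = [[a,-b],[b,a]]
        a, b = -0.5, 2.0
        J = np.array([[a, -b], [b, a]])
        res = reservoir_from_arrays(J + np.eye(2), [0.0, 0.0])
        u, v = rotation_plane(res, self._point_at_origin(res))
        basis = np.column_stack([u, v])
        assert np.allclose(basis.T @ basis, np.eye(2), atol=1e-12)
        # the plane is all of R^2
        assert np.linalg.matrix_rank(basis) == 2

    def test_block_diagonal_rotation_identifies_its_plane(self):
        J = np.zeros((3, 3))
        J[:2, :2] = [[-0.2, -1.5], [1.5, -0.2]]
        J[2, 2] = -2.0
        res = reservoir_from_arrays(J + np.eye(3), np.zeros(3))
        # the decoupled contraction along e3 has the largest modulus, so the
        # strict leading-pair check is relaxed to reach the rotation block
        u, v = rotation_plane(res, self._point_at_origin(res), strict=False)
        # the plane is the (e1, e2) coordinate plane
        assert abs(u[2]) < 1e-12 and abs(v[2]) < 1e-12

    def test_plane_is_invariant_under_jacobian(self, stable_n200):
        fp = solve_fixed_point(stable_n200, 0.2)
        u, v = rotation_plane(stable_n200, fp)
        J = jacobian(stable_n200, fp.location)
        P = np.column_stack([u, v])
        for vec in (u, v, 0.6 * u - 0.8 * v):
            img = J @ vec
            residual = img - P @ (P.T @ img)
            assert np.linalg.norm(residual) <= 1e-8

    def test_real_leading_eigenvalue_signals_no_plane(self):
        J = np.diag([-0.5, -1.0, -3.0])  # real spectrum, leading |.| real
        res = reservoir_from_arrays(J + np.eye(3), np.zeros(3))
        with pytest.raises(ValueError):
            rotation_plane(res, self._point_at_origin(res))
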