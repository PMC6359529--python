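"""SPD-manifold primitives: matrix functions, tangent maps, distance, mean."""

import numpy as np
import pytest
import scipy.linalg

from srmdrm.geometry import (
    NotSPDError,
    exp_map,
    log_map,
    matrix_exp,
    matrix_log,
    matrix_power,
    riemannian_distance,
    riemannian_mean,
)

from conftest import make_spd


class TestMatrixFunctions:
    def test_identity_inverse_sqrt(self):
        assert np.allclose(matrix_power(np.eye(4), -0.5), np.eye(4))

    def test_diagonal_sqrt(self):
        assert np.allclose(matrix_power(np.diag([4.0, 9.0]), 0.5), np.diag([2.0, 3.0]))

    def test_power_round_trip(self, rng):
        C = make_spd(rng, 5)
        R = matrix_power(C, 1.0 / 3.0)
        assert np.allclose(R @ R @ R, C, atol=1e-8)

    def test_log_trivials(self):
        assert np.allclose(matrix_log(np.eye(3)), np.zeros((3, 3)))
        assert np.allclose(
            matrix_log(np.diag([np.e, np.e**2])), np.diag([1.0, 2.0])
        )

    def test_exp_trivials(self):
        assert np.allclose(matrix_exp(np.zeros((3, 3))), np.eye(3))
        assert np.allclose(
            matrix_exp(np.diag([1.0, 2.0])), np.diag([np.e, np.e**2])
        )

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_log_exp_round_trips(self, rng, n):
        C = make_spd(rng, n)
        assert np.allclose(matrix_exp(matrix_log(C)), C, atol=1e-8)
        S = rng.standard_normal((n, n))
        S = (S + S.T) / 2
        assert np.allclose(matrix_log(matrix_exp(S)), S, atol=1e-8)

    def test_matches_schur_based_oracle(self, rng):
        # independent route: scipy's Schur/Pade logm and expm
        C = make_spd(rng, 6)
        assert np.allclose(matrix_log(C), scipy.linalg.logm(C), atol=1e-9)
        S = rng.standard_normal((6, 6))
        S = (S + S.T) / 2
        assert np.allclose(matrix_exp(S), scipy.linalg.expm(S), atol=1e-9)

    def test_non_spd_rejected(self):
        with pytest.raises(NotSPDError, match="eigenvalue"):
            matrix_power(np.diag([1.0, -2.0]), 0.5)
        with pytest.raises(ValueError, match="symmetric"):
            matrix_exp(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestTangentMaps:
    def test_log_map_at_self_is_zero(self, rng):
        C = make_spd(rng, 4)
        assert np.allclose(log_map(C, C), np.zeros((4, 4)), atol=1e-10)

    def test_log_map_at_identity_is_matrix_log(self, rng):
        C = make_spd(rng, 4)
        assert np.allclose(log_map(np.eye(4), C), matrix_log(C), atol=1e-10)

    def test_exp_map_trivials(self, rng):
        C = make_spd(rng, 4)
        assert np.allclose(exp_map(C, np.zeros((4, 4))), C, atol=1e-10)
        S = rng.standard_normal((4, 4))
        S = (S + S.T) / 2
        assert np.allclose(exp_map(np.eye(4), S), matrix_exp(S), atol=1e-9)

    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_exp_log_round_trip_at_arbitrary_reference(self, rng, n):
        C_ref, Ci = make_spd(rng, n), make_spd(rng, n)
        assert np.allclose(exp_map(C_ref, log_map(C_ref, Ci)), Ci, atol=1e-8)
        S = 0.3 * (lambda A: (A + A.T) / 2)(rng.standard_normal((n, n)))
        assert np.allclose(log_map(C_ref, exp_map(C_ref, S)), S, atol=1e-8)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            log_map(make_spd(rng, 3), make_spd(rng, 4))


class TestRiemannianDistance:
    def test_self_distance_zero(self, rng):
        C = make_spd(rng, 5)
        assert riemannian_distance(C, C) < 1e-10

    @pytest.mark.parametrize("n,lam", [(3, 2.0), (5, 0.1), (7, 10.0)])
    def test_scaled_identity_closed_form(self, n, lam):
        d = riemannian_distance(np.eye(n), lam * np.eye(n))
        assert d == pytest.approx(np.sqrt(n) * abs(np.log(lam)), abs=1e-10)

    def test_congruence_invariance(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 17))
            C1, C2 = make_spd(rng, n), make_spd(rng, n)
            A = rng.standard_normal((n, n))
            d = riemannian_distance(C1, C2)
            dT = riemannian_distance(A.T @ C1 @ A, A.T @ C2 @ A)
            assert abs(d - dT) <= 1e-8 * (1 + d)

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(20):
            C1, C2, C3 = (make_spd(rng, 4) for _ in range(3))
            d12 = riemannian_distance(C1, C2)
            assert d12 == pytest.approx(riemannian_distance(C2, C1), abs=1e-9)
            assert d12 <= (
                riemannian_distance(C1, C3) + riemannian_distance(C3, C2) + 1e-9
            )

    def test_matches_logm_oracle(self, rng):
        C1, C2 = make_spd(rng, 6), make_spd(rng, 6)
        isq = scipy.linalg.fractional_matrix_power(C1, -0.5)
        expected = np.linalg.norm(scipy.linalg.logm(isq @ C2 @ isq), "fro")
        assert riemannian_distance(C1, C2) == pytest.approx(expected.real, abs=1e-9)


class TestRiemannianMean:
    def test_singleton(self, rng):
        C = make_spd(rng, 4)
        assert np.allclose(riemannian_mean([C]), C, atol=1e-12)

    def test_commuting_elementwise_geometric_mean(self):
        a = np.array([1.0, 4.0, 0.5])
        b = np.array([9.0, 1.0, 2.0])
        M = riemannian_mean([np.diag(a), np.diag(b)])
        assert np.allclose(M, np.diag(np.sqrt(a * b)), atol=1e-8)

    def test_two_point_geodesic_midpoint(self, rng):
        C1, C2 = make_spd(rng, 5), make_spd(rng, 5)
        isq = scipy.linalg.fractional_matrix_power(C1, -0.5)
        sq = scipy.linalg.fractional_matrix_power(C1, 0.5)
        mid = sq @ scipy.linalg.fractional_matrix_power(isq @ C2 @ isq, 0.5) @ sq
        assert np.allclose(riemannian_mean([C1, C2]), mid.real, atol=1e-6)

    def test_mean_minimizes_sum_of_squared_distances(self, rng):
        Cs = [make_spd(rng, 4) for _ in range(6)]
        M = riemannian_mean(Cs, tol=1e-12, max_iter=200)
        base = sum(riemannian_distance(C, M) ** 2 for C in Cs)
        for _ in range(20):
            S = rng.standard_normal((4, 4))
            S = (S + S.T) / 2
            S *= 1e-3 / np.linalg.norm(S, "fro")
            Mp = exp_map(M, S)
            perturbed = sum(riemannian_distance(C, Mp) ** 2 for C in Cs)
            assert perturbed >= base - 1e-9

    def test_congruence_equivariance(self, rng):
        Cs = [make_spd(rng, 4) for _ in range(5)]
        A = rng.standard_normal((4, 4))
        M = riemannian_mean(Cs)
        MT = riemannian_mean([A.T @ C @ A for C in Cs])
        assert np.allclose(MT, A.T @ M @ A, atol=1e-6)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            riemannian_mean(np.empty((0, 3, 3)))

    def test_non_convergence_warns(self, rng):
        Cs = [make_spd(rng, 4, cond=100.0) for _ in range(5)]
        with pytest.warns(RuntimeWarning, match="did not converge"):
            riemannian_mean(Cs, tol=1e-15, max_iter=2)
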