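"""CSP / spatially regularized CSP filters and the Laplacian penalty."""

import numpy as np
import pytest
import scipy.linalg

from srmdrm.containers import ElectrodeMontage, TrialSet
from srmdrm.simulate import make_montage
from srmdrm.spatial import (
    apply_filters,
    csp_filters,
    gaussian_adjacency,
    laplacian_penalty,
    srcsp_filters,
)

from conftest import make_spd


def _montage(coords):
    coords = np.asarray(coords, dtype=float)
    return ElectrodeMontage(
        labels=[f"e{i}" for i in range(len(coords))], coords=coords
    )


class TestGaussianAdjacency:
    def test_coincident_electrodes(self):
        G = gaussian_adjacency(_montage([[0, 0, 1], [0, 0, 1]]), r=0.5)
        assert G[0, 1] == pytest.approx(1.0)

    def test_half_value_distance(self):
        # G = 0.5 exactly when distance = r * sqrt(2 ln 2)
        r = 0.3
        d = r * np.sqrt(2 * np.log(2))
        G = gaussian_adjacency(_montage([[0, 0, 0], [d, 0, 0]]), r=r)
        assert G[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_elementwise_brute_force(self, rng):
        coords = rng.standard_normal((10, 3))
        r = 0.7
        G = gaussian_adjacency(_montage(coords), r)
        for i in range(10):
            for j in range(10):
                d2 = np.sum((coords[i] - coords[j]) ** 2)
                assert G[i, j] == pytest.approx(np.exp(-0.5 * d2 / r**2), abs=1e-12)
        assert np.allclose(np.diag(G), 1.0)

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gaussian_adjacency(_montage([[0, 0, 0], [1, 0, 0]]), r=0.0)


class TestLaplacianPenalty:
    def test_constant_filter_has_zero_penalty(self, rng):
        G = gaussian_adjacency(_montage(rng.standard_normal((6, 3))), 0.5)
        K = laplacian_penalty(G)
        w = np.ones(6)
        assert abs(w @ K @ w) < 1e-10
        assert np.abs(K.sum(axis=1)).max() < 1e-10

    def test_two_electrode_hand_computation(self):
        g = 0.42
        G = np.array([[1.0, g], [g, 1.0]])
        K = laplacian_penalty(G)
        assert np.allclose(K, [[g, -g], [-g, g]], atol=1e-14)

    def test_quadratic_form_is_half_double_sum(self, rng):
        G = gaussian_adjacency(_montage(rng.standard_normal((8, 3))), 0.6)
        K = laplacian_penalty(G)
        w = rng.standard_normal(8)
        brute = 0.5 * sum(
            G[i, j] * (w[i] - w[j]) ** 2 for i in range(8) for j in range(8)
        )
        assert w @ K @ w == pytest.approx(brute, abs=1e-10)

    def test_psd_on_random_montages(self):
        for seed in range(20):
            mont = make_montage(12, seed=seed)
            K = laplacian_penalty(gaussian_adjacency(mont, 0.4))
            assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            laplacian_penalty(np.array([[1.0, 0.2], [0.3, 1.0]]))


class TestCSP:
    def test_diagonal_closed_form(self):
        bank = csp_filters(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]), k=1)
        # largest ratio along e1 (lambda=4), smallest along e2 (lambda=1/4)
        assert np.allclose(np.abs(bank.W[0]), [1.0, 0.0], atol=1e-12)
        assert np.allclose(np.abs(bank.W[1]), [0.0, 1.0], atol=1e-12)
        assert bank.eigenvalues == pytest.approx([4.0, 0.25])

    def test_equal_covariances_deterministic(self, rng):
        C = make_spd(rng, 6)
        b1 = csp_filters(C, C, k=2)
        b2 = csp_filters(C.copy(), C.copy(), k=2)
        assert np.allclose(b1.eigenvalues, 1.0)
        assert np.array_equal(b1.W, b2.W)

    def test_generalized_eigen_residuals(self, rng):
        C1, C2 = make_spd(rng, 8), make_spd(rng, 8)
        bank = csp_filters(C1, C2, k=3)
        for w, lam in zip(bank.W, bank.eigenvalues):
            assert np.linalg.norm(C1 @ w - lam * (C2 @ w)) <= 1e-8

    def test_too_many_pairs_rejected(self, rng):
        C = make_spd(rng, 4)
        with pytest.raises(ValueError, match="2k"):
            csp_filters(C, C, k=3)


class TestSRCSP:
    def _problem(self, rng, n=8):
        C1, C2 = make_spd(rng, n), make_spd(rng, n)
        mont = make_montage(n, seed=3)
        K = laplacian_penalty(gaussian_adjacency(mont, 0.4))
        return C1, C2, K

    def test_alpha_zero_reproduces_csp_subspace(self, rng):
        C1, C2, K = self._problem(rng)
        plain = csp_filters(C1, C2, k=3)
        reg = srcsp_filters(C1, C2, K, alpha=0.0, k=3)
        angles = scipy.linalg.subspace_angles(plain.W.T, reg.W.T)
        assert np.max(angles) < 1e-6

    def test_eigen_residuals_per_block(self, rng):
        C1, C2, K = self._problem(rng)
        alpha = 0.05
        bank = srcsp_filters(C1, C2, K, alpha=alpha, k=3)
        for i, (w, lam) in enumerate(zip(bank.W, bank.eigenvalues)):
            if i < bank.k:  # leading eigenvectors of (C2+aK)^-1 C1
                r = C1 @ w - lam * ((C2 + alpha * K) @ w)
            else:  # leading eigenvectors of (C1+aK)^-1 C2
                r = C2 @ w - lam * ((C1 + alpha * K) @ w)
            assert np.linalg.norm(r) <= 1e-8

    def test_large_alpha_prefers_smooth_filters(self, rng):
        # with a huge penalty the leading filters approach the constant
        # vector, the only direction K does not penalize
        C1, C2, K = self._problem(rng, n=6)
        bank = srcsp_filters(C1, C2, K, alpha=1e6, k=1)
        ones = np.ones(6) / np.sqrt(6)
        for w in bank.W:
            assert abs(w @ ones) > 0.99

    def test_small_r_recovers_plain_csp(self, rng):
        C1, C2 = make_spd(rng, 6), make_spd(rng, 6)
        mont = make_montage(6, seed=1)
        K = laplacian_penalty(gaussian_adjacency(mont, r=1e-4))  # G -> I, K -> 0
        assert np.abs(K).max() < 1e-12
        plain = csp_filters(C1, C2, k=2)
        reg = srcsp_filters(C1, C2, K, alpha=1.0, k=2)
        assert np.max(scipy.linalg.subspace_angles(plain.W.T, reg.W.T)) < 1e-6

    def test_large_r_gives_complete_graph_laplacian(self):
        mont = make_montage(7, seed=0)
        K = laplacian_penalty(gaussian_adjacency(mont, r=1e6))
        n = 7
        assert np.allclose(K, n * np.eye(n) - np.ones((n, n)), atol=1e-8)

    def test_leading_filter_maximizes_penalized_objective(self, rng):
        # J_P1(w) = w'C1w / (w'C2w + alpha w'Kw); the returned leading
        # filter must beat 1000 random unit vectors
        C1, C2 = make_spd(rng, 6), make_spd(rng, 6)
        mont = make_montage(6, seed=5)
        K = laplacian_penalty(gaussian_adjacency(mont, 0.4))
        alpha = 0.1
        bank = srcsp_filters(C1, C2, K, alpha=alpha, k=1)

        def J(w):
            return (w @ C1 @ w) / (w @ C2 @ w + alpha * (w @ K @ w))

        best = J(bank.W[0])
        W = rng.standard_normal((1000, 6))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        assert all(J(w) <= best + 1e-10 for w in W)

    def test_determinism(self, rng):
        C1, C2, K = self._problem(rng)
        b1 = srcsp_filters(C1, C2, K, 0.01, k=2)
        b2 = srcsp_filters(C1.copy(), C2.copy(), K.copy(), 0.01, k=2)
        assert np.array_equal(b1.W, b2.W)

    def test_negative_alpha_rejected(self, rng):
        C1, C2, K = self._problem(rng)
        with pytest.raises(ValueError, match="alpha"):
            srcsp_filters(C1, C2, K, alpha=-1.0, k=2)


class TestApplyFilters:
    def test_identity_rows_select_channels(self, rng):
        from srmdrm.spatial import SpatialFilterBank

        W = np.eye(4)[[0, 2]]
        bank = SpatialFilterBank(W=W, k=1)
        X = rng.standard_normal((4, 20))
        assert np.allclose(apply_filters(bank, X), X[[0, 2]])

    def test_trialset_projection_matches_matmul(self, rng):
        from srmdrm.spatial import SpatialFilterBank

        W = rng.standard_normal((2, 5))
        bank = SpatialFilterBank(W=W, k=1)
        ts = TrialSet(
            data=rng.standard_normal((3, 5, 10)),
            labels=np.array([1, 2, 1]),
            sampling_rate=100.0,
        )
        out = apply_filters(bank, ts)
        assert out.data.shape == (3, 2, 10)
        assert np.array_equal(out.labels, ts.labels)
        for i in range(3):
            assert np.allclose(out.data[i], W @ ts.data[i], atol=1e-14)

    def test_channel_mismatch_rejected(self, rng):
        from srmdrm.spatial import SpatialFilterBank

        bank = SpatialFilterBank(W=rng.standard_normal((2, 5)), k=1)
        with pytest.raises(ValueError, match="channels"):
            apply_filters(bank, rng.standard_normal((4, 10)))
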