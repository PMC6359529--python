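"""Affine-invariant Riemannian geometry of symmetric positive-definite matrices.

EEG trial covariance matrices are SPD and live on a curved manifold; the
affine-invariant metric makes distances between them invariant to any common
linear mixing of the channels (re-referencing, spatial filtering).  This
module provides the primitives the classifier is built on: matrix powers,
log/exp, the tangent-space maps at an arbitrary reference point, the geodesic
distance and the Fréchet (geometric) mean.

All functions work on plain ``numpy`` arrays.  Inputs are symmetrized as
``(C + C.T) / 2`` before any decomposition and eigenvalues are clipped below
at a small fraction of the largest eigenvalue (with a warning) so that
rank-deficient sample covariances — unavoidable in the small-trial-count
regime — do not break the matrix logarithm.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg

__all__ = [
    "is_spd",
    "check_spd",
    "matrix_power",
    "matrix_log",
    "matrix_exp",
    "log_map",
    "exp_map",
    "riemannian_distance",
    "riemannian_mean",
]

#: relative eigenvalue floor applied before logs and negative powers
EIG_CLIP_REL = 1e-12


class NotSPDError(ValueError):
    """Raised when an input matrix is not symmetric positive-definite."""


def _symmetrize(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    return (C + np.swapaxes(C, -1, -2)) / 2.0


def _check_square(C: np.ndarray, name: str = "matrix") -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim < 2 or C.shape[-1] != C.shape[-2]:
        raise ValueError(f"{name} must be square, got shape {C.shape}")
    return C


def _check_symmetric(C: np.ndarray, name: str = "matrix") -> np.ndarray:
    C = _check_square(C, name)
    scale = max(np.abs(C).max(), 1.0)
    if np.abs(C - np.swapaxes(C, -1, -2)).max() > 1e-8 * scale:
        raise ValueError(f"{name} is not symmetric")
    return C


def _eigh_clipped(C: np.ndarray, clip: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a (nearly) symmetric matrix with an eigenvalue floor.

    Returns ``(eigenvalues, eigenvectors)``; eigenvalues below
    ``EIG_CLIP_REL * max(eigenvalue)`` are raised to that floor with a warning.
    """
    w, U = np.linalg.eigh(_symmetrize(C))
    if clip:
        lo = EIG_CLIP_REL * np.max(w, axis=-1, keepdims=True)
        if np.any(w < lo):
            warnings.warn(
                "eigenvalues clipped to maintain positive-definiteness "
                f"(smallest was {np.min(w):.3e})",
                RuntimeWarning,
                stacklevel=3,
            )
            w = np.maximum(w, lo)
    return w, U


def is_spd(C: np.ndarray, tol: float = 1e-10) -> bool:
    """True if ``C`` is symmetric and has strictly positive eigenvalues."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        return False
    if np.abs(C - C.T).max() > tol * max(np.abs(C).max(), 1.0):
        return False
    return float(np.linalg.eigvalsh(_symmetrize(C)).min()) > 0.0


def check_spd(C: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate that ``C`` is SPD; raise :class:`NotSPDError` otherwise."""
    C = _check_symmetric(C, name)
    wmin = float(np.linalg.eigvalsh(_symmetrize(C)).min())
    if wmin <= 0.0:
        raise NotSPDError(
            f"{name} is not positive definite: smallest eigenvalue {wmin:.3e} <= 0"
        )
    return _symmetrize(C)


def matrix_power(C: np.ndarray, p: float) -> np.ndarray:
    """Real power ``C**p`` of an SPD matrix via its eigendecomposition."""
    C = check_spd(C, "C")
    w, U = _eigh_clipped(C)
    return (U * w**p) @ U.T


def matrix_log(C: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm of an SPD matrix (a symmetric matrix)."""
    C = check_spd(C, "C")
    w, U = _eigh_clipped(C)
    return (U * np.log(w)) @ U.T


def matrix_exp(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (an SPD matrix)."""
    S = _check_symmetric(S, "S")
    w, U = _eigh_clipped(S, clip=False)
    return (U * np.exp(w)) @ U.T


def _invsqrt_sqrt(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, U = _eigh_clipped(C)
    s = np.sqrt(w)
    return (U / s) @ U.T, (U * s) @ U.T


def log_map(C_ref: np.ndarray, Ci: np.ndarray) -> np.ndarray:
    """Project ``Ci`` to the tangent space anchored at ``C_ref``.

    Returns the symmetric matrix
    ``C_ref^{1/2} logm(C_ref^{-1/2} Ci C_ref^{-1/2}) C_ref^{1/2}``.
    """
    C_ref = check_spd(C_ref, "C_ref")
    Ci = _check_symmetric(Ci, "Ci")
    if Ci.shape != C_ref.shape:
        raise ValueError(f"dimension mismatch: {C_ref.shape} vs {Ci.shape}")
    isq, sq = _invsqrt_sqrt(C_ref)
    inner = _symmetrize(isq @ Ci @ isq)
    w, U = _eigh_clipped(inner)
    return _symmetrize(sq @ (U * np.log(w)) @ U.T @ sq)


def exp_map(C_ref: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Map the tangent vector ``S`` at ``C_ref`` back onto the manifold."""
    C_ref = check_spd(C_ref, "C_ref")
    S = _check_symmetric(S, "S")
    if S.shape != C_ref.shape:
        raise ValueError(f"dimension mismatch: {C_ref.shape} vs {S.shape}")
    isq, sq = _invsqrt_sqrt(C_ref)
    inner = _symmetrize(isq @ S @ isq)
    w, U = np.linalg.eigh(inner)
    return _symmetrize(sq @ (U * np.exp(w)) @ U.T @ sq)


def riemannian_distance(C1: np.ndarray, C2: np.ndarray) -> float:
    """Affine-invariant geodesic distance between two SPD matrices.

    ``Rd(C1, C2) = || logm(C1^{-1/2} C2 C1^{-1/2}) ||_F = sqrt(sum log^2 l_i)``
    where ``l_i`` are the generalized eigenvalues of the pair ``(C2, C1)``.
    The distance is symmetric in its arguments and invariant under any common
    congruence ``C -> A.T C A`` with ``A`` invertible.
    """
    C1 = check_spd(C1, "C1")
    C2 = check_spd(C2, "C2")
    if C1.shape != C2.shape:
        raise ValueError(f"dimension mismatch: {C1.shape} vs {C2.shape}")
    lam = scipy.linalg.eigh(C2, C1, eigvals_only=True)
    lam = np.maximum(lam, EIG_CLIP_REL * lam.max())
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


# --- batched helpers used by the Fréchet mean (performance-critical in CV) ---


def _logm_whitened_batch(isq: np.ndarray, Cs: np.ndarray) -> np.ndarray:
    """logm(isq @ Ci @ isq) for a stack ``Cs`` of SPD matrices, batched."""
    inner = _symmetrize(isq @ Cs @ isq)
    w, U = np.linalg.eigh(inner)
    w = np.maximum(w, EIG_CLIP_REL * w.max(axis=-1, keepdims=True))
    return _symmetrize(U * np.log(w)[..., None, :] @ np.swapaxes(U, -1, -2))


def riemannian_mean(
    matrices,
    tol: float = 1e-8,
    max_iter: int = 120,
) -> np.ndarray:
    """Fréchet (geometric) mean of a set of SPD matrices.

    The mean minimizes the sum of squared geodesic distances to the set.  It
    is computed by the standard fixed-point iteration: project the members to
    the tangent space at the current estimate, take their arithmetic mean
    there, and map that mean back to the manifold; stop when the Frobenius
    norm of the tangent mean falls below ``tol``.

    Parameters
    ----------
    matrices : sequence of (n, n) arrays or (m, n, n) array
        Nonempty set of SPD matrices of common dimension.
    tol : float
        Convergence threshold on the Frobenius norm of the tangent-space mean.
    max_iter : int
        Maximum number of fixed-point iterations; a warning is emitted if the
        tolerance is not reached and the last iterate is returned.
    """
    Cs = np.asarray(matrices, dtype=float)
    if Cs.ndim == 2:
        Cs = Cs[None]
    if Cs.ndim != 3 or Cs.shape[0] == 0:
        raise ValueError("need a nonempty set of square matrices")
    if Cs.shape[-1] != Cs.shape[-2]:
        raise ValueError("matrices must be square")
    Cs = _symmetrize(Cs)
    if Cs.shape[0] == 1:
        return check_spd(Cs[0], "member")

    M = _symmetrize(Cs.mean(axis=0))  # Euclidean-mean initialization
    update = np.inf
    step = 1.0  # halved whenever the tangent-mean norm grows (widely
    # spread sets can make the full fixed-point step overshoot)
    prev = np.inf
    for _ in range(max_iter):
        w, U = _eigh_clipped(M)
        s = np.sqrt(w)
        isq = (U / s) @ U.T
        sq = (U * s) @ U.T
        # arithmetic mean in the whitened tangent space at M
        Smean = _logm_whitened_batch(isq, Cs).mean(axis=0)
        update = float(np.linalg.norm(Smean, "fro"))
        if update <= tol:
            break
        if update > prev:
            step = max(step / 2.0, 1e-3)
        else:
            step = min(step * 1.1, 1.0)
        prev = update
        w2, U2 = np.linalg.eigh(_symmetrize(step * Smean))
        M = _symmetrize(sq @ ((U2 * np.exp(w2)) @ U2.T) @ sq)
    else:
        warnings.warn(
            f"Riemannian mean did not converge in {max_iter} iterations "
            f"(last tangent-mean norm {update:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return M
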