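"""Fisher geodesic discriminant analysis (FGDA) and geodesic filtering.

Minimum-distance-to-mean classification on raw covariance matrices is
sensitive to noise directions that carry no class information.  FGDA fits a
Fisher discriminant in the tangent space anchored at the Riemannian mean of
the training covariances, and geodesic filtering projects every matrix onto
the span of the leading discriminant directions before mapping it back to
the manifold.  The operation is dimension-preserving (an n x n matrix in, an
n x n matrix out) and idempotent; it simply removes tangent-space variation
orthogonal to the discriminant span.

Tangent vectors (symmetric matrices) are vectorized as the upper triangle in
row-major order with off-diagonal entries weighted by sqrt(2), so that the
Euclidean norm of the vector equals the Frobenius norm of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .geometry import exp_map, log_map, riemannian_mean

__all__ = [
    "FGDAFilter",
    "tangent_vectorize",
    "tangent_devectorize",
    "fit_fgda",
    "geodesic_filter",
]


def _triu_indices(n: int):
    return np.triu_indices(n)


def sym_to_vec(S: np.ndarray) -> np.ndarray:
    """Vectorize a symmetric matrix (stack allowed): upper triangle, sqrt(2)
    weight off the diagonal."""
    S = np.asarray(S, dtype=float)
    n = S.shape[-1]
    iu, ju = _triu_indices(n)
    w = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return S[..., iu, ju] * w


def vec_to_sym(v: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`sym_to_vec`."""
    v = np.asarray(v, dtype=float)
    iu, ju = _triu_indices(n)
    w = np.where(iu == ju, 1.0, np.sqrt(2.0))
    S = np.zeros(v.shape[:-1] + (n, n))
    S[..., iu, ju] = v / w
    S[..., ju, iu] = S[..., iu, ju]
    return S


def tangent_vectorize(C_ref: np.ndarray, Ci: np.ndarray) -> np.ndarray:
    """Tangent-space coordinates of ``Ci`` at ``C_ref`` as a flat vector.

    The vector has length n(n+1)/2 and its Euclidean norm equals the
    Frobenius norm of ``log_map(C_ref, Ci)``.
    """
    return sym_to_vec(log_map(C_ref, Ci))


def tangent_devectorize(C_ref: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Map a tangent coordinate vector at ``C_ref`` back to an SPD matrix."""
    n = np.asarray(C_ref).shape[-1]
    return exp_map(C_ref, vec_to_sym(v, n))


@dataclass
class FGDAFilter:
    """Fitted geodesic filter: tangent anchor plus an orthogonal projector.

    ``projector`` acts on vectorized tangent vectors and is idempotent;
    ``reference`` is the Riemannian mean of the training covariances.
    """

    reference: np.ndarray
    projector: np.ndarray
    n_components: int
    shrinkage: float
    fisher_eigenvalues: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.reference.shape[0]


def fit_fgda(
    train: np.ndarray,
    labels,
    n_components: int = 1,
    shrinkage: float | str = "auto",
) -> FGDAFilter:
    """Fit the Fisher geodesic discriminant filter on training covariances.

    Parameters
    ----------
    train : (m, n, n) array
        Training SPD matrices.
    labels : (m,) array of class indices, at least 2 classes with >= 2
        samples each.
    n_components : int
        Number of discriminant directions kept; 1 suffices for binary
        problems (Fisher LDA has at most n_classes - 1 nontrivial
        directions), larger values keep extra tangent variance.
    shrinkage : float in [0, 1] or "auto"
        Convex shrinkage of the within-class scatter toward a scaled
        identity — needed because the tangent dimension n(n+1)/2 routinely
        exceeds the trial count in small calibration sets.  "auto" (default)
        picks the Ledoit-Wolf optimal intensity from the pooled
        within-class residuals; small calibration sets typically get strong
        shrinkage this way, large ones little.
    """
    train = np.asarray(train, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit FGDA")
    if any((labels == c).sum() < 2 for c in classes):
        raise ValueError("need at least 2 samples per class")
    auto = isinstance(shrinkage, str)
    if auto and shrinkage != "auto":
        raise ValueError(f"shrinkage must be a float in [0, 1] or 'auto', got {shrinkage!r}")
    if not auto and not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")

    ref = riemannian_mean(train)
    isq = _invsqrt(ref)
    V = _tangent_vectors_at(ref, isq, train)
    d = V.shape[1]
    if not 1 <= n_components <= d:
        raise ValueError(f"n_components must be in [1, {d}]")

    gmean = V.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    residuals = []
    for c in classes:
        Vc = V[labels == c]
        mc = Vc.mean(axis=0)
        R = Vc - mc
        residuals.append(R)
        Sw += R.T @ R
        Sb += Vc.shape[0] * np.outer(mc - gmean, mc - gmean)
    if auto:
        from sklearn.covariance import ledoit_wolf

        _, shrinkage = ledoit_wolf(np.vstack(residuals), assume_centered=True)
        shrinkage = float(shrinkage)
    Sw_reg = (1.0 - shrinkage) * Sw + shrinkage * (np.trace(Sw) / d) * np.eye(d)

    try:
        lam, W = scipy.linalg.eigh(Sb, Sw_reg)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as err:
        raise ValueError(
            "within-class scatter is singular; set shrinkage > 0"
        ) from err
    order = np.argsort(lam, kind="stable")[::-1][:n_components]
    Wd = W[:, order]
    # orthogonal projection onto span(Wd): W (W'W)^-1 W'
    P = Wd @ np.linalg.solve(Wd.T @ Wd, Wd.T)
    P = (P + P.T) / 2.0
    return FGDAFilter(
        reference=ref,
        projector=P,
        n_components=int(n_components),
        shrinkage=float(shrinkage),
        fisher_eigenvalues=lam[order],
    )


def _invsqrt(C: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh((C + C.T) / 2.0)
    w = np.maximum(w, 1e-12 * w.max())
    return (U / np.sqrt(w)) @ U.T


def _tangent_vectors_at(ref, isq, Cs) -> np.ndarray:
    """Vectorized tangent coordinates of a stack of SPD matrices at ``ref``."""
    from .geometry import _logm_whitened_batch, _symmetrize

    sq = np.linalg.inv(isq)
    S = _logm_whitened_batch(isq, np.asarray(Cs, float))
    S = _symmetrize(sq @ S @ sq)
    return sym_to_vec(S)


def geodesic_filter(F: FGDAFilter, C: np.ndarray) -> np.ndarray:
    """Apply the geodesic filter to one SPD matrix or a stack.

    The matrix is mapped to the tangent space at the filter's reference,
    its coordinates are projected onto the discriminant span, and the result
    is mapped back to the manifold.  Output dimension equals input dimension
    and the operation is idempotent.
    """
    C = np.asarray(C, dtype=float)
    if C.shape[-1] != F.dim:
        raise ValueError(f"expected {F.dim}x{F.dim} matrices, got {C.shape}")
    if C.ndim == 2:
        v = tangent_vectorize(F.reference, C)
        return tangent_devectorize(F.reference, F.projector @ v)
    isq = _invsqrt(F.reference)
    V = _tangent_vectors_at(F.reference, isq, C) @ F.projector.T
    S = vec_to_sym(V, F.dim)
    return np.stack([exp_map(F.reference, s) for s in S])
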