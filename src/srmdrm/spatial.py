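"""CSP and spatially regularized CSP spatial-filter learning.

Common spatial patterns (CSP) finds filters ``w`` extremizing the variance
ratio ``w' C1 w / w' C2 w`` between the two class covariances — a generalized
eigenproblem ``C1 w = lambda C2 w``.  The spatially regularized variant
penalizes rough filters with the quadratic form ``w' K w`` built from a graph
Laplacian ``K = D - G`` over the electrode positions, where ``G`` is a
Gaussian adjacency: neighboring electrodes measure similar cortical activity,
so informative filters should vary smoothly over the scalp.  The penalized
objectives lead to the eigenproblems of ``(C2 + alpha K)^{-1} C1`` and
``(C1 + alpha K)^{-1} C2``; the k leading eigenvectors of each form the
2k-filter bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.spatial.distance

from .containers import ElectrodeMontage, TrialSet
from .geometry import EIG_CLIP_REL, _symmetrize

__all__ = [
    "SpatialFilterBank",
    "gaussian_adjacency",
    "laplacian_penalty",
    "csp_filters",
    "srcsp_filters",
    "apply_filters",
]


@dataclass
class SpatialFilterBank:
    """Learned spatial filters, stored as the rows of ``W`` (shape 2k x N)."""

    W: np.ndarray
    k: int
    alpha: float = 0.0
    provenance: str = "csp"
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != 2 * self.k:
            raise ValueError(
                f"filter matrix must have 2k={2 * self.k} rows, got {self.W.shape}"
            )
        if not np.all(np.isfinite(self.W)):
            raise ValueError("filters must be finite")
        if np.any(np.linalg.norm(self.W, axis=1) == 0.0):
            raise ValueError("zero filter row")

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]


def gaussian_adjacency(montage: ElectrodeMontage, r: float) -> np.ndarray:
    """Gaussian adjacency over electrode positions.

    ``G_ij = exp(-||v_i - v_j||^2 / (2 r^2))``; the kernel width ``r`` (same
    units as the montage coordinates) sets how far apart two electrodes can
    be while still counting as neighbors.
    """
    if r <= 0:
        raise ValueError(f"kernel width r must be positive, got {r}")
    d2 = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(montage.coords, "sqeuclidean")
    )
    return np.exp(-0.5 * d2 / r**2)


def laplacian_penalty(G: np.ndarray) -> np.ndarray:
    """Graph-Laplacian penalty ``K = D - G`` with ``D_ii = sum_j G_ij``.

    ``K`` has zero row sums and is positive semidefinite for nonnegative
    ``G``; the quadratic form satisfies
    ``w' K w = 1/2 sum_ij G_ij (w_i - w_j)^2``, i.e. it measures the spatial
    roughness of a filter over the electrode graph.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError(f"adjacency must be square, got {G.shape}")
    if np.abs(G - G.T).max() > 1e-10 * max(np.abs(G).max(), 1.0):
        raise ValueError("adjacency matrix must be symmetric")
    return np.diag(G.sum(axis=1)) - G


def _pd_floor(C: np.ndarray) -> np.ndarray:
    """Return ``C`` with eigenvalues floored so Cholesky-based solvers succeed."""
    C = _symmetrize(np.asarray(C, dtype=float))
    w, U = np.linalg.eigh(C)
    top = w.max()
    if top <= 0:
        raise np.linalg.LinAlgError("matrix has no positive eigenvalues")
    lo = max(EIG_CLIP_REL * top, np.finfo(float).tiny)
    if w.min() < lo:
        C = (U * np.maximum(w, lo)) @ U.T
    return _symmetrize(C)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Deterministic per-row sign: first coefficient of nonnegligible size > 0."""
    W = W.copy()
    for i, w in enumerate(W):
        nz = np.nonzero(np.abs(w) > 1e-12 * np.abs(w).max())[0]
        if nz.size and w[nz[0]] < 0:
            W[i] = -w
    return W


def _leading_eigvecs(A: np.ndarray, B: np.ndarray, k: int):
    """k largest-eigenvalue eigenvectors of ``B^{-1} A`` (descending).

    Solved as the symmetric generalized problem ``A w = lambda B w`` so the
    eigenpairs are guaranteed real.
    """
    lam, V = scipy.linalg.eigh(_symmetrize(A), _pd_floor(B))
    order = np.argsort(lam, kind="stable")[::-1][:k]
    return lam[order], V[:, order].T


def csp_filters(C1: np.ndarray, C2: np.ndarray, k: int = 3) -> SpatialFilterBank:
    """Standard CSP filter bank from two class covariances.

    Returns the k eigenvectors of ``C2^{-1} C1`` with the largest eigenvalues
    (variance maximized for class 1) followed by the k with the smallest
    (variance maximized for class 2); rows are unit-norm with a fixed sign
    convention so identical inputs always give identical banks.
    """
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    n = C1.shape[0]
    if C1.shape != C2.shape:
        raise ValueError("class covariances must have the same shape")
    if 2 * k > n:
        raise ValueError(f"need 2k <= n_channels, got k={k}, n={n}")
    lam, V = scipy.linalg.eigh(_symmetrize(C1), _pd_floor(C2))
    order = np.argsort(lam, kind="stable")
    hi = order[::-1][:k]  # largest, descending
    lo = order[:k]  # smallest, ascending
    idx = np.concatenate([hi, lo])
    W = V[:, idx].T
    W = _fix_signs(W / np.linalg.norm(W, axis=1, keepdims=True))
    return SpatialFilterBank(W=W, k=k, alpha=0.0, provenance="csp", eigenvalues=lam[idx])


def srcsp_filters(
    C1: np.ndarray,
    C2: np.ndarray,
    K: np.ndarray,
    alpha: float,
    k: int = 3,
) -> SpatialFilterBank:
    """Spatially regularized CSP filter bank.

    Takes the k leading eigenvectors of ``(C2 + alpha K)^{-1} C1`` (class-1
    block) and the k leading of ``(C1 + alpha K)^{-1} C2`` (class-2 block),
    each block in descending eigenvalue order.  With ``alpha = 0`` the row
    space coincides with plain CSP.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    K = np.asarray(K, dtype=float)
    n = C1.shape[0]
    if not (C1.shape == C2.shape == K.shape):
        raise ValueError("C1, C2 and K must share one shape")
    if 2 * k > n:
        raise ValueError(f"need 2k <= n_channels, got k={k}, n={n}")
    try:
        lam1, W1 = _leading_eigvecs(C1, C2 + alpha * K, k)
        lam2, W2 = _leading_eigvecs(C2, C1 + alpha * K, k)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"(C + alpha*K) is singular ({err}); consider a larger eigenvalue clip"
        ) from err
    W = np.vstack([W1, W2])
    W = _fix_signs(W / np.linalg.norm(W, axis=1, keepdims=True))
    return SpatialFilterBank(
        W=W, k=k, alpha=float(alpha), provenance="srcsp",
        eigenvalues=np.concatenate([lam1, lam2]),
    )


def apply_filters(bank: SpatialFilterBank, trials: TrialSet | np.ndarray):
    """Project trials through the filter bank: ``Z = W X`` per trial.

    Accepts a single (channels x samples) trial or a TrialSet; labels,
    sampling rate and metadata are carried through.
    """
    W = bank.W
    if isinstance(trials, TrialSet):
        if trials.n_channels != W.shape[1]:
            raise ValueError(
                f"filter bank expects {W.shape[1]} channels, got {trials.n_channels}"
            )
        return TrialSet(
            data=np.einsum("fc,tcs->tfs", W, trials.data),
            labels=trials.labels,
            sampling_rate=trials.sampling_rate,
            channel_names=[f"csp{i:02d}" for i in range(W.shape[0])],
            metadata={**trials.metadata, "spatial_filter": bank.provenance},
        )
    X = np.asarray(trials, dtype=float)
    if X.shape[-2] != W.shape[1]:
        raise ValueError(
            f"filter bank expects {W.shape[1]} channels, got {X.shape[-2]}"
        )
    return W @ X
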