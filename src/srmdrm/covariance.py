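"""Trace-normalized sample covariance of EEG trials and per-class composites.

The covariance of a bandpassed trial ``X`` (channels x samples) is estimated
as ``C = X X.T / tr(X X.T)`` — the raw second-moment matrix, trace-normalized
so every trial contributes on the same scale regardless of overall amplitude.
No mean subtraction is applied: bandpassed EEG is zero-mean by construction
and the raw form keeps the estimator a single matrix product.
"""

from __future__ import annotations

import numpy as np

from .containers import TrialSet

__all__ = ["trial_covariance", "trial_covariances", "class_covariance"]


def trial_covariance(X: np.ndarray) -> np.ndarray:
    """Trace-normalized sample covariance of one trial.

    Parameters
    ----------
    X : (n_channels, n_samples) array
        A single trial with at least 2 samples.

    Returns
    -------
    (n_channels, n_channels) array with unit trace; symmetric positive
    semidefinite, strictly positive definite when ``X`` has full row rank.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"trial must be 2-D (channels x samples), got {X.shape}")
    if X.shape[1] < 2:
        raise ValueError("trial must have at least 2 time samples")
    C = X @ X.T
    t = np.trace(C)
    if t <= 0.0:
        raise ValueError("all-zero trial: covariance trace is zero")
    return C / t


def trial_covariances(trials: TrialSet | np.ndarray) -> np.ndarray:
    """Stack of trace-normalized covariances, one per trial."""
    data = trials.data if isinstance(trials, TrialSet) else np.asarray(trials, float)
    C = data @ np.swapaxes(data, -1, -2)
    tr = np.trace(C, axis1=-2, axis2=-1)
    if np.any(tr <= 0.0):
        bad = int(np.nonzero(tr <= 0.0)[0][0])
        raise ValueError(f"all-zero trial at index {bad}: covariance trace is zero")
    return C / tr[:, None, None]


def class_covariance(
    trials: TrialSet, class_id: int, mode: str = "mean"
) -> np.ndarray:
    """Composite covariance of all trials belonging to one class.

    ``mode="sum"`` accumulates the per-trial unit-trace covariances;
    ``mode="mean"`` (default) divides by the class trial count, which keeps
    the regularization weight of the spatially penalized filters comparable
    across training-set sizes.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    if trials.labels is None:
        raise ValueError("TrialSet must be labeled")
    mask = trials.labels == class_id
    if not np.any(mask):
        raise ValueError(f"no trials with class {class_id}")
    Cs = trial_covariances(trials.subset(np.nonzero(mask)[0]))
    total = Cs.sum(axis=0)
    return total if mode == "sum" else total / Cs.shape[0]
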