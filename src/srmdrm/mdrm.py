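"""Minimum-distance-to-Riemannian-mean (MDRM) classification and metrics.

MDRM fits one Riemannian (geometric) mean per class from labeled training
covariances and assigns a test covariance to the class whose mean is closest
in geodesic distance.  Because the affine-invariant distance is unchanged by
any common invertible congruence of all matrices, the classifier is immune
to linear channel mixing applied uniformly to train and test data.

Binary performance is summarized by accuracy and the kappa coefficient,
computed from the confusion counts (a, b, c, d) = (true positive, true
negative, false positive, false negative):

    accuracy = (a + b) / (a + b + c + d)
    randomAccuracy = ((b + c)(b + d) + (d + a)(c + a)) / (a + b + c + d)^2
    kappa = (accuracy - randomAccuracy) / (1 - randomAccuracy)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import riemannian_distance, riemannian_mean

__all__ = [
    "MDRMModel",
    "ConfusionCounts",
    "EvaluationResult",
    "fit_mdrm",
    "predict_mdrm",
    "evaluate",
]


@dataclass
class MDRMModel:
    """Per-class Riemannian means; ``classes`` is sorted ascending."""

    classes: np.ndarray
    class_means: dict

    @property
    def dim(self) -> int:
        return next(iter(self.class_means.values())).shape[0]


@dataclass
class ConfusionCounts:
    a: int  # true positives
    b: int  # true negatives
    c: int  # false positives
    d: int  # false negatives

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EvaluationResult:
    accuracy: float
    kappa: float  # NaN when chance accuracy is 1 (degenerate single outcome)
    counts: ConfusionCounts


def fit_mdrm(train: np.ndarray, labels, tol: float = 1e-8, max_iter: int = 120) -> MDRMModel:
    """Fit per-class Riemannian means from labeled SPD matrices."""
    train = np.asarray(train, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    means = {
        int(c): riemannian_mean(train[labels == c], tol=tol, max_iter=max_iter)
        for c in classes
    }
    return MDRMModel(classes=classes.astype(int), class_means=means)


def predict_mdrm(model: MDRMModel, C: np.ndarray, return_distances: bool = False):
    """Predict class labels for one SPD matrix or a stack.

    Ties at exactly equal distance go to the lowest class index (with a
    warning).  With ``return_distances=True`` also returns the per-class
    geodesic distance array (n_trials, n_classes) ordered like
    ``model.classes``.
    """
    C = np.asarray(C, dtype=float)
    single = C.ndim == 2
    Cs = C[None] if single else C
    if Cs.shape[-1] != model.dim:
        raise ValueError(f"expected {model.dim}x{model.dim} matrices, got {C.shape}")
    D = np.empty((Cs.shape[0], model.classes.size))
    for j, c in enumerate(model.classes):
        mean = model.class_means[int(c)]
        D[:, j] = [riemannian_distance(Ci, mean) for Ci in Cs]
    best = np.argmin(D, axis=1)  # argmin takes the first (lowest class) on ties
    n_min = (D == D[np.arange(len(best)), best][:, None]).sum(axis=1)
    if np.any(n_min > 1):
        warnings.warn(
            f"{int((n_min > 1).sum())} trial(s) equidistant from several class "
            "means; assigned the lowest class index",
            RuntimeWarning,
            stacklevel=2,
        )
    pred = model.classes[best]
    if single:
        return (int(pred[0]), D[0]) if return_distances else int(pred[0])
    return (pred, D) if return_distances else pred


def evaluate(pred, truth, positive_class: int | None = None) -> EvaluationResult:
    """Binary accuracy and kappa from predicted and true label sequences."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be nonempty and the same length")
    classes = np.unique(np.concatenate([truth, pred]))
    if classes.size > 2:
        raise ValueError("evaluation is defined for binary labels only")
    if positive_class is None:
        positive_class = int(classes[0])
    pos = truth == positive_class
    hit = pred == truth
    counts = ConfusionCounts(
        a=int(np.sum(pos & hit)),
        b=int(np.sum(~pos & hit)),
        c=int(np.sum(~pos & ~hit)),  # negatives called positive
        d=int(np.sum(pos & ~hit)),  # positives called negative
    )
    n = counts.total
    acc = (counts.a + counts.b) / n
    rand = (
        (counts.b + counts.c) * (counts.b + counts.d)
        + (counts.d + counts.a) * (counts.c + counts.a)
    ) / n**2
    if rand >= 1.0:
        kappa = float("nan")
    else:
        kappa = (acc - rand) / (1.0 - rand)
    return EvaluationResult(accuracy=acc, kappa=kappa, counts=counts)
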