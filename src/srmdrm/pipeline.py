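"""End-to-end spatially regularized Riemannian motor-imagery classification.

The full SR-MDRM pipeline chains: zero-phase Butterworth bandpass (7-30 Hz)
and epoch extraction; spatially regularized CSP projection of the trials to
2k virtual channels; trace-normalized covariance of the projected trials;
Fisher-geodesic filtering of those covariances; and minimum-distance-to-
Riemannian-mean classification.  Plain CSP (log-variance features + Fisher
LDA) and full-dimension MDRM baselines are provided for comparison, and the
two regularization hyperparameters (penalty weight ``alpha``, kernel width
``r``) are selected by stratified cross-validation on the training set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .containers import ElectrodeMontage, TrialSet
from .covariance import class_covariance, trial_covariances
from .fgda import FGDAFilter, fit_fgda, geodesic_filter
from .mdrm import EvaluationResult, MDRMModel, evaluate, fit_mdrm, predict_mdrm
from .spatial import (
    SpatialFilterBank,
    apply_filters,
    csp_filters,
    gaussian_adjacency,
    laplacian_penalty,
    srcsp_filters,
)

__all__ = [
    "PipelineConfig",
    "FittedPipeline",
    "bandpass_trials",
    "extract_epochs",
    "preprocess",
    "fit_srmdrm",
    "predict_srmdrm",
    "grid_search",
    "run_baselines",
]

DEFAULT_ALPHA_GRID = tuple(10.0 ** -e for e in range(10, 0, -1))  # 1e-10 .. 1e-1
DEFAULT_R_GRID = tuple(np.round(np.arange(1, 11) * 0.01, 2))  # 0.01 .. 0.10


@dataclass
class PipelineConfig:
    """Tunable settings of the pipeline.

    Defaults follow standard motor-imagery practice: 7-30 Hz fifth-order
    Butterworth band (alpha + beta rhythms), the [0.5, 2.5) s post-cue
    window, k = 3 filter pairs, and the 10 x 10 (alpha, r) search grids.
    """

    band: tuple = (7.0, 30.0)
    filter_order: int = 5
    epoch: tuple = (0.5, 2.5)
    k: int = 3
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    r_grid: tuple = DEFAULT_R_GRID
    cv_folds: int = 5
    seed: int = 0
    fgda_components: int | None = 1  # None disables geodesic filtering
    shrinkage: float | str = "auto"  # Ledoit-Wolf scatter shrinkage by default
    covariance_mode: str = "mean"
    zero_phase: bool = True
    loo_threshold: int = 10  # leave-one-out CV below this per-class count

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")
        if self.epoch[0] >= self.epoch[1]:
            raise ValueError("epoch start must precede end")
        if len(self.alpha_grid) == 0 or len(self.r_grid) == 0:
            raise ValueError("hyperparameter grids must be nonempty")


@dataclass
class FittedPipeline:
    """All fitted stages of one SR-MDRM model."""

    filters: SpatialFilterBank
    fgda_filter: FGDAFilter | None
    model: MDRMModel
    config: PipelineConfig
    alpha: float
    r: float


def _butter_sos(cfg: PipelineConfig, fs: float):
    lo, hi = cfg.band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz is not below Nyquist ({fs / 2} Hz)")
    return scipy.signal.butter(
        cfg.filter_order, (lo, hi), btype="bandpass", fs=fs, output="sos"
    )


def bandpass_trials(trials: TrialSet, cfg: PipelineConfig) -> TrialSet:
    """Bandpass every trial; zero-phase (forward-backward) by default."""
    sos = _butter_sos(cfg, trials.sampling_rate)
    if cfg.zero_phase:
        data = scipy.signal.sosfiltfilt(sos, trials.data, axis=-1)
    else:
        data = scipy.signal.sosfilt(sos, trials.data, axis=-1)
    return TrialSet(
        data=data,
        labels=trials.labels,
        sampling_rate=trials.sampling_rate,
        channel_names=trials.channel_names,
        metadata={**trials.metadata, "bandpass": cfg.band},
    )


def extract_epochs(
    raw: np.ndarray,
    cues: np.ndarray,
    sampling_rate: float,
    cfg: PipelineConfig,
    labels=None,
    channel_names=None,
) -> TrialSet:
    """Cut the post-cue window out of a continuous recording.

    The window is half-open, ``[cue + start, cue + end)`` seconds, so a
    2-second window at 100 Hz yields exactly 200 samples.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("continuous recording must be (channels, samples)")
    n_len = int(round((cfg.epoch[1] - cfg.epoch[0]) * sampling_rate))
    epochs = []
    for i, cue in enumerate(np.asarray(cues, dtype=float)):
        start = int(round((cue + cfg.epoch[0]) * sampling_rate))
        if start < 0 or start + n_len > raw.shape[1]:
            raise ValueError(
                f"epoch for cue #{i} at t={cue:g}s exceeds recording bounds"
            )
        epochs.append(raw[:, start : start + n_len])
    return TrialSet(
        data=np.stack(epochs),
        labels=labels,
        sampling_rate=sampling_rate,
        channel_names=channel_names,
    )


def preprocess(
    data,
    cfg: PipelineConfig,
    cues=None,
    sampling_rate: float | None = None,
    labels=None,
    channel_names=None,
) -> TrialSet:
    """Epoch (if a continuous recording with cues is given) and bandpass."""
    if isinstance(data, TrialSet):
        trials = data
    else:
        if cues is None or sampling_rate is None:
            raise ValueError("continuous input needs cue times and sampling_rate")
        trials = extract_epochs(data, cues, sampling_rate, cfg, labels, channel_names)
    return bandpass_trials(trials, cfg)


def _class_covs(train: TrialSet, cfg: PipelineConfig):
    classes = np.sort(train.classes())
    if classes.size != 2:
        raise ValueError(f"binary pipeline needs exactly 2 classes, got {classes}")
    C1 = class_covariance(train, int(classes[0]), mode=cfg.covariance_mode)
    C2 = class_covariance(train, int(classes[1]), mode=cfg.covariance_mode)
    return classes, C1, C2


def _fit_downstream(bank, train: TrialSet, cfg: PipelineConfig):
    """Projection -> SCMs -> geodesic filtering -> class means."""
    Z = apply_filters(bank, train)
    scms = trial_covariances(Z)
    if cfg.fgda_components is None:
        fg = None
    else:
        fg = fit_fgda(
            scms, train.labels,
            n_components=cfg.fgda_components, shrinkage=cfg.shrinkage,
        )
        scms = geodesic_filter(fg, scms)
    model = fit_mdrm(scms, train.labels)
    return fg, model


def fit_srmdrm(
    train: TrialSet,
    montage: ElectrodeMontage,
    alpha: float,
    r: float,
    cfg: PipelineConfig | None = None,
) -> FittedPipeline:
    """Fit the full SR-MDRM pipeline on preprocessed training trials."""
    cfg = cfg or PipelineConfig()
    if montage.n_channels != train.n_channels:
        raise ValueError(
            f"montage has {montage.n_channels} channels, trials have "
            f"{train.n_channels}"
        )
    _, C1, C2 = _class_covs(train, cfg)
    K = laplacian_penalty(gaussian_adjacency(montage, r))
    bank = srcsp_filters(C1, C2, K, alpha, cfg.k)
    fg, model = _fit_downstream(bank, train, cfg)
    return FittedPipeline(
        filters=bank, fgda_filter=fg, model=model, config=cfg,
        alpha=float(alpha), r=float(r),
    )


def predict_srmdrm(fp: FittedPipeline, test: TrialSet, return_distances: bool = False):
    """Classify preprocessed test trials with a fitted pipeline."""
    Z = apply_filters(fp.filters, test)
    scms = trial_covariances(Z)
    if fp.fgda_filter is not None:
        scms = geodesic_filter(fp.fgda_filter, scms)
    return predict_mdrm(fp.model, scms, return_distances=return_distances)


def _cv_splits(labels: np.ndarray, cfg: PipelineConfig):
    """Stratified folds; leave-one-out when a class has few trials."""
    counts = np.array([np.sum(labels == c) for c in np.unique(labels)])
    X = np.zeros((labels.size, 1))
    if counts.min() < cfg.loo_threshold:
        return list(LeaveOneOut().split(X))
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    return list(cv.split(X, labels))


def grid_search(
    train: TrialSet,
    montage: ElectrodeMontage,
    cfg: PipelineConfig | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Select (alpha, r) by cross-validated accuracy on the training set.

    Every grid point is scored by stratified k-fold (or leave-one-out for
    very small classes) cross-validation; ties are broken toward larger
    ``alpha`` then larger ``r`` (prefer smoother filters).  Returns the
    selected pair and the full CV table (columns alpha, r, cv_accuracy).
    """
    cfg = cfg or PipelineConfig()
    if train.labels is None:
        raise ValueError("grid search needs labeled training trials")
    splits = _cv_splits(train.labels, cfg)

    # per-fold quantities that do not depend on (alpha, r)
    folds = []
    for tr_idx, te_idx in splits:
        sub = train.subset(tr_idx)
        try:
            _, C1, C2 = _class_covs(sub, cfg)
        except ValueError as err:
            raise ValueError(
                f"a CV fold lost a class ({err}); use fewer folds"
            ) from err
        folds.append((sub, train.subset(te_idx), C1, C2))

    Ks = {r: laplacian_penalty(gaussian_adjacency(montage, r)) for r in cfg.r_grid}

    rows = []
    for alpha in cfg.alpha_grid:
        for r in cfg.r_grid:
            accs = []
            for sub, held, C1, C2 in folds:
                bank = srcsp_filters(C1, C2, Ks[r], alpha, cfg.k)
                fg, model = _fit_downstream(bank, sub, cfg)
                fp = FittedPipeline(
                    filters=bank, fgda_filter=fg, model=model, config=cfg,
                    alpha=alpha, r=r,
                )
                pred = predict_srmdrm(fp, held)
                pred = np.atleast_1d(pred)
                accs.append(float(np.mean(pred == held.labels)))
            rows.append((float(alpha), float(r), float(np.mean(accs))))
    table = pd.DataFrame(rows, columns=["alpha", "r", "cv_accuracy"])
    # argmax with ties toward larger alpha, then larger r
    best = (
        table.sort_values(["cv_accuracy", "alpha", "r"]).iloc[-1]
    )
    return float(best["alpha"]), float(best["r"]), table


def _log_variance_features(bank: SpatialFilterBank, trials: TrialSet) -> np.ndarray:
    Z = apply_filters(bank, trials)
    return np.log(Z.data.var(axis=-1))


def run_baselines(
    train: TrialSet,
    test: TrialSet,
    montage: ElectrodeMontage | None = None,
    cfg: PipelineConfig | None = None,
) -> dict[str, EvaluationResult]:
    """Plain-CSP and full-dimension MDRM reference methods.

    CSP: k filter pairs, log-variance features, Fisher linear discriminant.
    MDRM: per-class Riemannian means of the full-dimension trial
    covariances, nearest-mean assignment.  Both use the same preprocessed
    trials as the regularized pipeline.
    """
    cfg = cfg or PipelineConfig()
    _, C1, C2 = _class_covs(train, cfg)

    bank = csp_filters(C1, C2, cfg.k)
    lda = LinearDiscriminantAnalysis()
    lda.fit(_log_variance_features(bank, train), train.labels)
    csp_pred = lda.predict(_log_variance_features(bank, test))

    model = fit_mdrm(trial_covariances(train), train.labels)
    mdrm_pred = predict_mdrm(model, trial_covariances(test))

    return {
        "csp": evaluate(csp_pred, test.labels),
        "mdrm": evaluate(mdrm_pred, test.labels),
    }
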