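"""Data containers shared across the package: labeled EEG trials and montages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrialSet", "ElectrodeMontage"]


@dataclass
class TrialSet:
    """A set of same-shape EEG trials with optional binary class labels.

    Attributes
    ----------
    data : (n_trials, n_channels, n_samples) float array
        Trial signals, in whatever amplitude units the recording uses.
    labels : (n_trials,) int array or None
        Class indices (1 or 2 for binary motor imagery); None for unlabeled
        test sets.
    sampling_rate : float
        Sampling frequency in Hz.
    channel_names : list of str or None
    metadata : dict
        Free-form provenance (generator seed, preprocessing applied, ...).
    """

    data: np.ndarray
    labels: np.ndarray | None = None
    sampling_rate: float = 250.0
    channel_names: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples), got shape {self.data.shape}"
            )
        if self.data.shape[2] < 2:
            raise ValueError("trials need at least 2 time samples")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.data.shape[0],):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match "
                    f"{self.data.shape[0]} trials"
                )
        if self.channel_names is not None:
            if len(self.channel_names) != self.data.shape[1]:
                raise ValueError("channel_names length does not match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def __len__(self) -> int:
        return self.n_trials

    def subset(self, idx) -> "TrialSet":
        """Return a new TrialSet restricted to trial indices ``idx``."""
        idx = np.asarray(idx)
        return TrialSet(
            data=self.data[idx],
            labels=None if self.labels is None else self.labels[idx],
            sampling_rate=self.sampling_rate,
            channel_names=self.channel_names,
            metadata=dict(self.metadata),
        )

    def classes(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("TrialSet is unlabeled")
        return np.unique(self.labels)


@dataclass
class ElectrodeMontage:
    """Channel labels with 3D electrode positions.

    Coordinates are in consistent length units (conventionally a normalized
    head radius of 1); the spatial-smoothness penalty is built from pairwise
    Euclidean distances between them, so only relative geometry matters.
    """

    labels: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("labels and coords length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels in montage")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("montage coordinates must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return self.n_channels
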