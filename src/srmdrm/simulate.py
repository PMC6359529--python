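"""Synthetic two-class motor-imagery EEG with known ground truth.

The generator emulates the second-order structure the classifier exploits:
band-limited (7-30 Hz) oscillatory sources mixed into the channels through
spatially smooth patterns, where a few "discriminative" sources change power
between the two classes (the ERD/ERS analogue), plus spatially correlated
broadband sensor noise.  Because the classification pipeline consumes only
trial covariances, matching the covariance structure is what matters;
sources are bandpassed Gaussian noise rather than parametric oscillators.

Montages are quasi-uniform point sets on an upper unit hemisphere, so all
spatial scales (pattern smoothness, penalty kernel width ``r``) are in units
of the head radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .containers import ElectrodeMontage, TrialSet

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "make_montage",
    "simulate_trials",
    "simulate_split",
    "dataset_preset",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class SimulationSpec:
    """Parameters of one synthetic recording session.

    ``class_variance_ratio`` is the source-power ratio between class 1 and
    class 2 on the discriminative sources; 1 means the classes are
    distributionally identical, larger values mean easier problems.
    ``n_train_trials``/``n_test_trials`` (totals, balanced) drive
    :func:`simulate_split`; their sum must equal ``2 * n_trials_per_class``.
    """

    n_channels: int = 60
    sampling_rate: float = 250.0
    n_trials_per_class: int = 50
    epoch_length: float = 2.0
    n_sources: int = 10
    n_discriminative: int = 3
    pattern_smoothness: float = 0.6
    class_variance_ratio: float = 4.0
    noise_power: float = 0.2
    seed: int = 0
    band: tuple = (7.0, 30.0)
    n_train_trials: int | None = None
    n_test_trials: int | None = None

    def __post_init__(self) -> None:
        if self.n_channels < 2 or self.n_trials_per_class < 1 or self.n_sources < 1:
            raise ValueError("channel, trial and source counts must be positive")
        if not 1 <= self.n_discriminative <= self.n_sources:
            raise ValueError("n_discriminative must be in [1, n_sources]")
        if self.class_variance_ratio < 1.0:
            raise ValueError("class_variance_ratio must be >= 1")
        if self.noise_power < 0.0:
            raise ValueError("noise_power must be nonnegative")
        if self.epoch_length <= 0 or self.sampling_rate <= 2 * self.band[1]:
            raise ValueError("epoch_length must be > 0 and band below Nyquist")


@dataclass
class GroundTruth:
    """Planted structure of a simulated session."""

    mixing: np.ndarray  # channels x sources, unit-norm columns
    discriminative_source_indices: np.ndarray
    class_powers: np.ndarray  # 2 x sources source variances (class 1 row first)
    montage: ElectrodeMontage

    @property
    def discriminative_patterns(self) -> np.ndarray:
        return self.mixing[:, self.discriminative_source_indices]


def make_montage(n_channels: int, seed: int = 0) -> ElectrodeMontage:
    """Quasi-uniform electrode layout on the upper unit hemisphere.

    Uses a golden-angle (Fibonacci) spiral, rotated by a seed-dependent
    azimuth so different seeds give distinct but equally uniform layouts.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 electrodes")
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(n_channels)
    z = (i + 0.5) / n_channels  # heights in (0, 1): upper hemisphere
    rho = np.sqrt(1.0 - z**2)
    phi = _GOLDEN_ANGLE * i + offset
    coords = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    labels = [f"ch{j + 1:03d}" for j in i]
    return ElectrodeMontage(labels=labels, coords=coords)


def _smooth_mixing(
    coords: np.ndarray, n_sources: int, length: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample spatially smooth mixing columns from a Gaussian process.

    Columns are draws from a GP over the montage with squared-exponential
    kernel of correlation length ``length``, normalized to unit norm.
    """
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    Kgp = np.exp(-0.5 * d2 / max(length, 1e-6) ** 2)
    Kgp += 1e-8 * np.eye(len(coords))
    L = np.linalg.cholesky(Kgp)
    A = L @ rng.standard_normal((len(coords), n_sources))
    return A / np.linalg.norm(A, axis=0, keepdims=True)


def _bandpassed_noise(
    shape: tuple, band: tuple, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise bandpassed to ``band`` (zero-phase)."""
    sos = scipy.signal.butter(5, band, btype="bandpass", fs=fs, output="sos")
    pad = int(fs)  # discard filter warm-up
    x = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    x = scipy.signal.sosfiltfilt(sos, x, axis=-1)[..., pad:-pad]
    return x / x.std(axis=-1, keepdims=True)


def simulate_trials(spec: SimulationSpec) -> tuple[TrialSet, GroundTruth]:
    """Generate a balanced labeled TrialSet plus its ground truth.

    Class 1 trials carry ``class_variance_ratio`` times the source power of
    class 2 trials on the discriminative sources; all other sources are
    common background.  Sensor noise is spatially correlated broadband
    Gaussian noise with per-channel variance ``noise_power`` (relative to the
    unit total source variance scale).
    """
    rng = np.random.default_rng(spec.seed)
    montage = make_montage(spec.n_channels, spec.seed)
    A = _smooth_mixing(montage.coords, spec.n_sources, spec.pattern_smoothness, rng)
    disc = np.arange(spec.n_discriminative)
    powers = np.ones((2, spec.n_sources))
    powers[0, disc] = spec.class_variance_ratio  # ERS analogue in class 1

    T = int(round(spec.epoch_length * spec.sampling_rate))
    m = spec.n_trials_per_class
    labels = np.repeat([1, 2], m)
    order = rng.permutation(2 * m)
    labels = labels[order]

    # spatially correlated sensor-noise mixer (fixed per session)
    noise_mix = _smooth_mixing(montage.coords, spec.n_channels, 0.3, rng)

    data = np.empty((2 * m, spec.n_channels, T))
    for t, lab in enumerate(labels):
        S = _bandpassed_noise(
            (spec.n_sources, T), spec.band, spec.sampling_rate, rng
        ) * np.sqrt(powers[lab - 1])[:, None]
        X = A @ S
        if spec.noise_power > 0:
            E = noise_mix @ rng.standard_normal((spec.n_channels, T))
            E /= E.std(axis=-1, keepdims=True).mean()
            X = X + np.sqrt(spec.noise_power) * E
        data[t] = X

    trials = TrialSet(
        data=data,
        labels=labels,
        sampling_rate=spec.sampling_rate,
        channel_names=montage.labels,
        metadata={"generator": "srmdrm.simulate", "seed": spec.seed},
    )
    truth = GroundTruth(
        mixing=A,
        discriminative_source_indices=disc,
        class_powers=powers,
        montage=montage,
    )
    return trials, truth


def simulate_split(spec: SimulationSpec) -> tuple[TrialSet, TrialSet, GroundTruth]:
    """Generate calibration (train) and evaluation (test) sets of one session.

    Uses ``spec.n_train_trials`` / ``spec.n_test_trials`` (balanced totals);
    both sets share the same mixing, montage and noise statistics.
    """
    if spec.n_train_trials is None or spec.n_test_trials is None:
        raise ValueError("spec must define n_train_trials and n_test_trials")
    if spec.n_train_trials % 2 or spec.n_test_trials % 2:
        raise ValueError("train/test totals must be even (balanced classes)")
    per_class = (spec.n_train_trials + spec.n_test_trials) // 2
    full, truth = simulate_trials(replace(spec, n_trials_per_class=per_class))
    tr_idx, te_idx = [], []
    want = spec.n_train_trials // 2
    taken = {1: 0, 2: 0}
    for i, lab in enumerate(full.labels):
        if taken[int(lab)] < want:
            tr_idx.append(i)
            taken[int(lab)] += 1
        else:
            te_idx.append(i)
    return full.subset(tr_idx), full.subset(te_idx), truth


#: dataset-scale presets: channel counts, sampling rates and train/test
#: splits mirroring the three public BCI-competition benchmarks (the IVa
#: preset uses the hardest subject's 28-train / 252-test split).
_PRESETS = {
    "iva": dict(
        n_channels=118, sampling_rate=100.0, epoch_length=2.0,
        n_train_trials=28, n_test_trials=252,
    ),
    "iiia": dict(
        n_channels=60, sampling_rate=250.0, epoch_length=2.0,
        n_train_trials=60, n_test_trials=60,
    ),
    "iia": dict(
        n_channels=22, sampling_rate=250.0, epoch_length=2.0,
        n_train_trials=144, n_test_trials=144,
    ),
}


def dataset_preset(name: str, seed: int = 0, **overrides) -> SimulationSpec:
    """SimulationSpec at the scale of one of the benchmark datasets."""
    key = name.lower()
    if key not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        )
    params = dict(_PRESETS[key])
    params["n_trials_per_class"] = (
        params["n_train_trials"] + params["n_test_trials"]
    ) // 2
    params.update(overrides)
    return SimulationSpec(seed=seed, **params)
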