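"""File formats: trial containers, montage files, fitted models, results.

Trials travel as NumPy ``.npz`` archives with named arrays ``data``
(trials x channels x samples), ``sfreq`` (scalar Hz), optional ``labels``
and optional ``channels`` (channel-name strings).  Montages are plain text,
one channel per line, ``label x y z`` whitespace-separated, ``#`` comments
allowed — compatible with common electrode-position exports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
from pathlib import Path

import numpy as np

from .containers import ElectrodeMontage, TrialSet

__all__ = [
    "read_trials",
    "write_trials",
    "read_trials_mat",
    "read_montage",
    "write_montage",
    "save_pipeline",
    "load_pipeline",
    "ResultsRecord",
]


def write_trials(trials: TrialSet, path) -> None:
    """Write a TrialSet losslessly to an ``.npz`` archive."""
    arrays = {
        "data": trials.data,
        "sfreq": np.asarray(trials.sampling_rate, dtype=float),
    }
    if trials.labels is not None:
        arrays["labels"] = trials.labels
    if trials.channel_names is not None:
        arrays["channels"] = np.asarray(trials.channel_names)
    if trials.metadata:
        arrays["metadata_json"] = np.asarray(
            json.dumps(trials.metadata, sort_keys=True, default=str)
        )
    np.savez(path, **arrays)


def read_trials(path) -> TrialSet:
    """Read a TrialSet written by :func:`write_trials`."""
    with np.load(path, allow_pickle=False) as npz:
        for required in ("data", "sfreq"):
            if required not in npz:
                raise ValueError(f"trial container missing required field {required!r}")
        data = npz["data"]
        labels = npz["labels"] if "labels" in npz else None
        channels = (
            [str(c) for c in npz["channels"]] if "channels" in npz else None
        )
        meta = (
            json.loads(str(npz["metadata_json"])) if "metadata_json" in npz else {}
        )
        return TrialSet(
            data=data,
            labels=labels,
            sampling_rate=float(npz["sfreq"]),
            channel_names=channels,
            metadata=meta,
        )


def read_trials_mat(
    path,
    data_key: str = "data",
    label_key: str = "labels",
    sfreq_key: str = "sfreq",
) -> TrialSet:
    """Import shim for MATLAB-style trial exports (``.mat`` files).

    Expects a (trials x channels x samples) array under ``data_key``; labels
    and sampling rate are read when present.  Only simple numeric variables
    are supported — this is a convenience bridge, not a general EEG reader.
    """
    import scipy.io

    mat = scipy.io.loadmat(path, squeeze_me=True)
    if data_key not in mat:
        raise ValueError(f"mat file has no variable {data_key!r}")
    labels = mat.get(label_key)
    if labels is not None:
        labels = np.atleast_1d(labels).astype(int)
    sfreq = float(mat.get(sfreq_key, 250.0))
    return TrialSet(data=np.asarray(mat[data_key], dtype=float),
                    labels=labels, sampling_rate=sfreq)


def write_montage(montage: ElectrodeMontage, path) -> None:
    lines = ["# label x y z"]
    for lab, (x, y, z) in zip(montage.labels, montage.coords):
        lines.append(f"{lab} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_montage(path) -> ElectrodeMontage:
    """Parse a ``label x y z`` montage file; '#' lines are comments."""
    labels: list[str] = []
    coords: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        parts = text.split()
        if len(parts) != 4:
            raise ValueError(
                f"{path}:{lineno}: expected 'label x y z', got {text!r}"
            )
        label = parts[0]
        if label in labels:
            raise ValueError(f"{path}:{lineno}: duplicate channel label {label!r}")
        try:
            xyz = [float(p) for p in parts[1:]]
        except ValueError as err:
            raise ValueError(
                f"{path}:{lineno}: non-numeric coordinate in {text!r}"
            ) from err
        labels.append(label)
        coords.append(xyz)
    if not labels:
        raise ValueError(f"{path}: no channels found")
    return ElectrodeMontage(labels=labels, coords=np.asarray(coords))


def save_pipeline(fp, path) -> None:
    """Serialize a fitted pipeline (pickle)."""
    with open(path, "wb") as fh:
        pickle.dump(fp, fh)


def load_pipeline(path):
    with open(path, "rb") as fh:
        return pickle.load(fh)


def config_hash(cfg) -> str:
    """Short stable hash of a PipelineConfig, for traceable results records."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclasses.dataclass
class ResultsRecord:
    """One method's evaluation on one dataset, traceable to its config."""

    method: str
    dataset: str
    alpha: float | None
    r: float | None
    k: int
    accuracy: float
    kappa: float
    predictions: list
    distances: list
    seed: int
    config_hash: str

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @staticmethod
    def from_json(path) -> "ResultsRecord":
        return ResultsRecord(**json.loads(Path(path).read_text()))
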