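"""Persistence: HDF5 feature stores, WAV audio, delimited label tables, EDF.

Feature matrices travel with their per-column provenance as a JSON
attribute, so relevance back-projection works after a round trip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .audio import AudioFeatureMatrix
from .connectivity import EegFeatureMatrix, FeatureDescriptor
from .preprocess import EpochedEeg


def save_eeg_features(path: str | Path, feats: EegFeatureMatrix, labels: Sequence[str] | None = None) -> None:
    index = [
        {"measure": fd.measure, "band": fd.band, "window": fd.window, "pair": list(fd.pair)}
        for fd in feats.feature_index
    ]
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=feats.values)
        d.attrs["feature_index"] = json.dumps(index)
        if labels is not None:
            f.create_dataset("labels", data=np.array(labels, dtype="S"))


def load_eeg_features(path: str | Path) -> tuple[EegFeatureMatrix, list[str] | None]:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        index = [
            FeatureDescriptor(e["measure"], e["band"], e["window"], tuple(e["pair"]))
            for e in json.loads(f["values"].attrs["feature_index"])
        ]
        labels = [s.decode() for s in f["labels"][...]] if "labels" in f else None
    return EegFeatureMatrix(values, index), labels


def save_audio_features(path: str | Path, feats: AudioFeatureMatrix) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=feats.values)
        d.attrs["feature_index"] = json.dumps([[w, n] for w, n in feats.feature_index])


def load_audio_features(path: str | Path) -> AudioFeatureMatrix:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        index = [(int(w), str(n)) for w, n in json.loads(f["values"].attrs["feature_index"])]
    return AudioFeatureMatrix(values, index)


def save_epochs(path: str | Path, eeg: EpochedEeg) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=eeg.data)
        f.attrs["fs"] = eeg.fs
        f.attrs["subject_id"] = eeg.subject_id
        f.create_dataset("channel_names", data=np.array(eeg.channel_names, dtype="S"))
        f.create_dataset("labels", data=np.array(eeg.labels, dtype="S"))


def load_epochs(path: str | Path) -> EpochedEeg:
    with h5py.File(path, "r") as f:
        return EpochedEeg(
            f["data"][...],
            float(f.attrs["fs"]),
            [s.decode() for s in f["channel_names"][...]],
            [s.decode() for s in f["labels"][...]],
            subject_id=str(f.attrs["subject_id"]),
        )


def read_labels(path: str | Path) -> list[str]:
    """Per-trial label column from a delimited text table (column ``label``)."""
    df = pd.read_csv(path, sep=None, engine="python")
    col = "label" if "label" in df.columns else df.columns[0]
    return df[col].astype(str).tolist()


def write_wav(path: str | Path, wave: np.ndarray, fs: int = 44100) -> None:
    x = np.asarray(wave, dtype=float)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    wavfile.write(path, fs, (x * 32767).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read 16/24-bit PCM or float WAV, returning float64 in [-1, 1]."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        data = (data.astype(float) - 128.0) / 128.0
    if data.ndim > 1:
        data = data.mean(axis=1)
    return data.astype(float), int(fs)


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Continuous EEG from an EDF/BDF file via MNE: (channels x samples, fs, names)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def load_config(path: str | Path) -> dict:
    """YAML pipeline configuration (band, window set, montage preset, ...)."""
    with open(path) as f:
        return yaml.safe_load(f) or {}
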