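"""EEG conditioning chain: filter, montage edits, re-reference, resample, window.

The chain mirrors a standard affective music-listening pipeline: zero-phase
Butterworth bandpass of the raw channels, removal of artifact-prone
electrodes, common-average re-referencing, epoching on the stimulus onset,
downsampling, and Hann-tapered 50%-overlap windowing for piecewise-stationary
feature extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

#: 19-channel 10-20 montage in recording order.
STANDARD_1020_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Montage presets: channels removed from the 19-channel cap.
#: ``E17`` drops the occipital pair; ``E14`` additionally drops the
#: frontopolar pair and the midline parietal electrode.
MONTAGE_PRESETS = {
    "E17": ("O1", "O2"),
    "E14": ("O1", "O2", "Fp1", "Fp2", "Pz"),
}

#: Physiological bands (Hz) used for band-limited connectivity extraction.
BANDS = {
    "broadband": (1.0, 45.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}


@dataclass
class EpochedEeg:
    """Trials x channels x samples EEG array with labels and channel names.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Epoched EEG in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str
        One name per channel, 10-20 convention.
    labels : sequence of str
        Per-trial affective category (arousal-valence quadrant).
    subject_id : str
        Identifier of the recorded participant.
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    labels: Sequence[str]
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        self.channel_names = tuple(self.channel_names)
        self.labels = tuple(self.labels)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class WindowGrid:
    """Overlapping tapered analysis windows over a trial of length ``T``.

    ``n_windows(T)`` counts only full-length windows:
    ``floor((T - tau) / (tau * (1 - overlap))) + 1``.
    """

    tau: float
    overlap: float = 0.5
    taper: str = "hann"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")

    @property
    def hop(self) -> float:
        """Window hop in seconds."""
        return self.tau * (1.0 - self.overlap)

    def n_windows(self, trial_length: float) -> int:
        if self.tau > trial_length + 1e-12:
            raise ValueError(f"tau={self.tau} exceeds trial length {trial_length}")
        return int(math.floor((trial_length - self.tau) / self.hop + 1e-9)) + 1

    def starts(self, trial_length: float) -> np.ndarray:
        """Window start times in seconds."""
        return np.arange(self.n_windows(trial_length)) * self.hop


#: Window lengths (s) evaluated for 12 s trials, from the whole trial down.
DEFAULT_TAU_GRID = (12.0, 6.0, 3.0, 1.5, 0.75, 0.375)


def bandpass(
    x: np.ndarray,
    fs: float,
    low: float = 1.0,
    high: float = 45.0,
    order: int = 3,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth bandpass along the last axis.

    With ``zero_phase`` the filter runs forward and backward (`sosfiltfilt`),
    doubling the effective magnitude order and cancelling the phase response.
    """
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band edges must satisfy 0 < {low} < {high} < fs/2={nyq}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def bandpass_eeg(eeg: EpochedEeg, band: str | tuple[float, float] = "broadband",
                 order: int = 3) -> EpochedEeg:
    """Apply :func:`bandpass` to every trial; ``band`` may be a name or (low, high)."""
    low, high = BANDS[band] if isinstance(band, str) else band
    return replace(eeg, data=bandpass(eeg.data, eeg.fs, low, high, order=order))


def drop_channels(eeg: EpochedEeg, names: Sequence[str] | str) -> EpochedEeg:
    """Remove channels by name, or apply a montage preset (``"E17"``, ``"E14"``)."""
    if isinstance(names, str):
        try:
            names = MONTAGE_PRESETS[names]
        except KeyError:
            raise KeyError(f"unknown montage preset {names!r}; "
                           f"options: {sorted(MONTAGE_PRESETS)}") from None
    unknown = set(names) - set(eeg.channel_names)
    if unknown:
        raise KeyError(f"channels not in montage: {sorted(unknown)}")
    keep = [i for i, ch in enumerate(eeg.channel_names) if ch not in set(names)]
    return replace(
        eeg,
        data=eeg.data[:, keep, :],
        channel_names=tuple(eeg.channel_names[i] for i in keep),
    )


def common_average_reference(eeg: EpochedEeg) -> EpochedEeg:
    """Subtract the per-sample mean across channels from every channel."""
    if eeg.n_channels < 2:
        raise ValueError("common-average reference requires >= 2 channels")
    return replace(eeg, data=eeg.data - eeg.data.mean(axis=1, keepdims=True))


def resample_epochs(eeg: EpochedEeg, fs_new: float) -> EpochedEeg:
    """Anti-aliased polyphase downsampling of every trial to ``fs_new`` Hz."""
    if fs_new >= eeg.fs:
        raise ValueError(f"fs_new={fs_new} must be below fs={eeg.fs}")
    frac = Fraction(fs_new / eeg.fs).limit_denominator(1000)
    data = signal.resample_poly(eeg.data, frac.numerator, frac.denominator, axis=-1)
    return replace(eeg, data=data, fs=fs_new)


def window_segments(
    epoch: np.ndarray, grid: WindowGrid, fs: float
) -> list[np.ndarray]:
    """Cut one trial into Hann-tapered overlapping segments.

    ``epoch`` is ``(..., samples)``; each returned segment has the same
    leading shape and ``round(tau * fs)`` samples, multiplied by the taper.
    Only full-length windows are produced.
    """
    epoch = np.asarray(epoch, dtype=float)
    n = epoch.shape[-1]
    trial_length = n / fs
    win_len = int(round(grid.tau * fs))
    n_win = grid.n_windows(trial_length)
    taper = signal.get_window(grid.taper, win_len, fftbins=False)
    hop = grid.hop * fs
    out = []
    for m in range(n_win):
        start = int(round(m * hop))
        seg = epoch[..., start : start + win_len]
        out.append(seg * taper)
    return out


def preprocess(
    eeg: EpochedEeg,
    band: tuple[float, float] = (1.0, 45.0),
    montage: str | Sequence[str] | None = "E17",
    fs_new: float | None = 80.0,
) -> EpochedEeg:
    """Full conditioning chain: bandpass, drop channels, re-reference, resample.

    Steps run in that fixed order; windowing is left to the feature
    extractors, which need band-specific inputs.
    """
    low, high = BANDS[band] if isinstance(band, str) else band
    # epochs may arrive already downsampled; keep the band inside Nyquist
    high = min(high, 0.95 * eeg.fs / 2.0)
    out = bandpass_eeg(eeg, (low, high))
    if montage is not None:
        try:
            out = drop_channels(out, montage)
        except KeyError:
            # preset channels already absent (e.g. synthetic montage): skip
            if not isinstance(montage, str):
                raise
    out = common_average_reference(out)
    if fs_new is not None and fs_new < out.fs:
        out = resample_epochs(out, fs_new)
    return out
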