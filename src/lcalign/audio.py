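"""Windowed acoustic descriptors and the compressed auditory envelope.

Twenty music-analysis descriptors are computed per short frame inside each
analysis window (zero-crossing rate, high/low energy ratio, spectral
entropy/spread/roll-off/flatness, roughness, RMS, broadband and ten
octave-band spectral fluxes, spectral centroid); each window's frame
trajectory is reduced to one scalar per descriptor by its first principal
component.  The short-time auditory envelope is the squared signal smoothed
with a square window, downsampled to 64 Hz, and cube-root compressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .preprocess import WindowGrid

#: Column order of :func:`acoustic_descriptors`.
DESCRIPTOR_NAMES = (
    "zcr",
    "hl_energy_ratio",
    "spectral_entropy",
    "spectral_spread",
    "spectral_rolloff",
    "spectral_flatness",
    "roughness",
    "rms",
    "broadband_flux",
    "spectral_centroid",
) + tuple(f"octave_flux_{k}" for k in range(10))

#: Split frequency (Hz) for the high/low energy ratio.
HL_SPLIT_HZ = 1500.0
#: Lower edge (Hz) of the first of the ten octave-wide flux bands.
OCTAVE_ANCHOR_HZ = 31.25
#: Analysis frame length / hop (samples at 44.1 kHz) inside each window.
FRAME_SIZE = 2048

ENVELOPE_FS = 64.0


@dataclass
class AcousticEnvelope:
    """Nonnegative compressed amplitude envelope at ``fs`` Hz (default 64)."""

    values: np.ndarray
    fs: float = ENVELOPE_FS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class AudioFeatureMatrix:
    """Trials x features acoustic matrix with per-column provenance.

    ``feature_index`` entries are ``(window, name)`` where ``name`` is a
    descriptor name or ``"env_k"`` for the k-th envelope sample.
    """

    values: np.ndarray
    feature_index: list[tuple[int, str]]


def _spectrum(frame: np.ndarray) -> np.ndarray:
    """Hann-tapered magnitude spectrum."""
    w = sps.get_window("hann", len(frame), fftbins=False)
    return np.abs(np.fft.rfft(frame * w))


def _frame_descriptors(frame: np.ndarray, prev_mag: np.ndarray | None, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """20 descriptors of one frame; flux terms use the previous frame's spectrum."""
    n = len(frame)
    mag = _spectrum(frame)
    power = mag**2
    total = power.sum()
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    zcr = float(np.mean(np.signbit(frame[1:]) != np.signbit(frame[:-1])))
    rms = float(np.sqrt(np.mean(frame**2)))

    if total > 0:
        p = power / total
        hi = power[freqs >= HL_SPLIT_HZ].sum()
        lo = power[freqs < HL_SPLIT_HZ].sum()
        hl = float(hi / lo) if lo > 0 else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            entropy = float(-np.sum(p * np.log2(p, where=p > 0, out=np.zeros_like(p))))
        entropy /= np.log2(p.size)  # normalize to [0, 1]
        centroid = float(np.sum(freqs * p))
        spread = float(np.sqrt(np.sum(((freqs - centroid) ** 2) * p)))
        cum = np.cumsum(power)
        rolloff = float(freqs[int(np.searchsorted(cum, 0.85 * total))])
        eps = 1e-12
        flatness = float(np.exp(np.mean(np.log(power + eps))) / (np.mean(power) + eps))
        roughness = _roughness(mag, freqs)
    else:
        hl = entropy = centroid = spread = rolloff = flatness = roughness = 0.0

    if prev_mag is None:
        bb_flux = 0.0
        oct_flux = np.zeros(10)
    else:
        d = mag - prev_mag
        bb_flux = float(np.sqrt(np.sum(d**2)))
        oct_flux = np.empty(10)
        lo_edge = OCTAVE_ANCHOR_HZ
        for k in range(10):
            m = (freqs >= lo_edge) & (freqs < 2 * lo_edge)
            oct_flux[k] = float(np.sqrt(np.sum(d[m] ** 2))) if m.any() else 0.0
            lo_edge *= 2

    vec = np.array(
        [zcr, hl, entropy, spread, rolloff, flatness, roughness, rms, bb_flux, centroid]
        + list(oct_flux)
    )
    return vec, mag


def _roughness(mag: np.ndarray, freqs: np.ndarray, n_peaks: int = 12) -> float:
    """Sensory-dissonance dialect: summed pairwise interaction of spectral peaks.

    Interaction weight follows the Plomp-Levelt-style curve
    ``exp(-3.5 s df) - exp(-5.75 s df)`` with ``s = 0.24 / (0.021 fmin + 19)``,
    scaled by the product of peak amplitudes.
    """
    if mag.size < 3:
        return 0.0
    peaks, _ = sps.find_peaks(mag)
    if peaks.size == 0:
        return 0.0
    top = peaks[np.argsort(mag[peaks])[-n_peaks:]]
    f, a = freqs[top], mag[top]
    a = a / (a.max() + 1e-12)
    r = 0.0
    for i in range(len(top)):
        for j in range(i + 1, len(top)):
            fmin = min(f[i], f[j])
            s = 0.24 / (0.021 * fmin + 19.0)
            df = abs(f[i] - f[j])
            r += a[i] * a[j] * (np.exp(-3.5 * s * df) - np.exp(-5.75 * s * df))
    return float(r)


def descriptor_trajectory(
    segment: np.ndarray,
    fs: float,
    frame_size: int = FRAME_SIZE,
    hop: int | None = None,
) -> np.ndarray:
    """Frames x 20 descriptor matrix over one analysis window (50% hop default)."""
    segment = np.asarray(segment, dtype=float)
    if len(segment) < 256:
        raise ValueError("segment too short for acoustic descriptors (< 256 samples)")
    frame_size = min(frame_size, len(segment))
    hop = hop or frame_size // 2
    starts = range(0, len(segment) - frame_size + 1, hop)
    rows, prev = [], None
    for s in starts:
        vec, prev = _frame_descriptors(segment[s : s + frame_size], prev, fs)
        rows.append(vec)
    return np.vstack(rows)


def acoustic_descriptors(segment: np.ndarray, fs: float) -> np.ndarray:
    """Mean 20-descriptor vector of one audio segment (see DESCRIPTOR_NAMES)."""
    return descriptor_trajectory(segment, fs).mean(axis=0)


def envelope(
    audio: np.ndarray,
    fs_in: float,
    fs_out: float = ENVELOPE_FS,
    smooth_seconds: float = 0.125,
) -> AcousticEnvelope:
    """Compressed short-time amplitude envelope.

    Pipeline: square the waveform, convolve with a square (boxcar) window of
    ``smooth_seconds``, polyphase-resample to ``fs_out``, clip at zero, and
    apply cube-root compression.  For a sinusoid of amplitude A the output
    plateaus at ``(A^2 / 2)^(1/3)``.
    """
    if fs_in <= 128:
        raise ValueError("fs_in must exceed 128 Hz")
    x = np.asarray(audio, dtype=float) ** 2
    win = max(int(round(smooth_seconds * fs_in)), 1)
    x = np.convolve(x, np.ones(win) / win, mode="same")
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    x = sps.resample_poly(x, frac.numerator, frac.denominator)
    return AcousticEnvelope(np.cbrt(np.clip(x, 0.0, None)), fs_out)


def pca_first_component(trajectory: np.ndarray) -> np.ndarray:
    """First-principal-component summary of a frames x d trajectory.

    Returns one scalar per descriptor: the first principal axis (sign fixed
    so its largest-magnitude loading is positive) scaled by the component's
    standard deviation over frames.  A constant trajectory has zero variance
    and returns the zero vector with a warning.
    """
    T = np.asarray(trajectory, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    if T.shape[0] < 2:
        raise ValueError("need at least 2 frames for a principal component")
    C = T - T.mean(axis=0)
    if not np.any(C):
        warnings.warn("constant descriptor trajectory: zero-variance component")
        return np.zeros(T.shape[1])
    _, s, vt = np.linalg.svd(C, full_matrices=False)
    v = vt[0]
    v = v * np.sign(v[np.argmax(np.abs(v))])
    score_sd = s[0] / np.sqrt(T.shape[0] - 1)
    return score_sd * v


def explained_variance_ratio(trajectory: np.ndarray) -> float:
    """Variance fraction captured by the first principal component."""
    C = np.asarray(trajectory, float) - np.mean(trajectory, axis=0)
    s = np.linalg.svd(C, compute_uv=False)
    tot = np.sum(s**2)
    return float(s[0] ** 2 / tot) if tot > 0 else 0.0


def assemble_audio_features(
    stimuli: Sequence[np.ndarray],
    grid: WindowGrid,
    n_phi: int,
    fs: float = 44100.0,
) -> AudioFeatureMatrix:
    """Per-trial acoustic feature matrix ``Y`` of width ``Ntau * (20 + Nphi - 1)``.

    For each trial and analysis window: the 20 PCA-reduced descriptors plus
    ``n_phi - 1`` samples drawn evenly from that window's stretch of the
    64 Hz compressed envelope.  ``n_phi`` is the EEG montage size, which
    ties the acoustic width to the connectivity feature width.
    """
    if not stimuli:
        raise ValueError("stimulus list must be non-empty")
    n_env = n_phi - 1
    rows, index = [], []
    first = True
    for wave in stimuli:
        wave = np.asarray(wave, dtype=float)
        duration = len(wave) / fs
        n_win = grid.n_windows(duration)  # raises if grid longer than stimulus
        env = envelope(wave, fs)
        feats = []
        for m in range(n_win):
            start = m * grid.hop
            seg = wave[int(round(start * fs)) : int(round((start + grid.tau) * fs))]
            traj = descriptor_trajectory(seg, fs)
            if traj.shape[0] >= 2:
                desc = pca_first_component(traj)
            else:
                desc = traj[0]
            e0 = int(round(start * env.fs))
            e1 = max(e0 + 1, int(round((start + grid.tau) * env.fs)))
            e1 = min(e1, len(env.values))
            idx = np.linspace(e0, e1 - 1, n_env).round().astype(int)
            feats.append(np.concatenate([desc, env.values[idx]]))
            if first:
                index.extend((m, name) for name in DESCRIPTOR_NAMES)
                index.extend((m, f"env_{k}") for k in range(n_env))
        first = False
        rows.append(np.concatenate(feats))
    return AudioFeatureMatrix(np.vstack(rows), index)
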