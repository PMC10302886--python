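"""Synthetic EEG, audio, and coupled feature sets with planted ground truth.

Every downstream estimator in the package can be exercised without any
recording: EEG trials carry label-dependent narrowband phase coupling and
label-dependent amplitude covariance, audio trials carry label-specific
amplitude-envelope templates, and abstract feature pairs carry a planted
first canonical correlation plus label-informative mean shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import EpochedEeg

#: Arousal-valence quadrant labels used throughout.
QUADRANT_LABELS = ("HAPV", "HANV", "LANV", "LAPV")


@dataclass
class CouplingSpec:
    """Ground-truth description of a synthetic EEG study.

    Attributes
    ----------
    n_subjects, n_trials_per_subject : int
        Study size; 40 trials per subject matches a typical affective
        music-listening session of four 10-trial runs.
    n_channels : int
        Montage size.
    fs_eeg : float
        EEG sampling rate (Hz).
    trial_length : float
        Trial duration in seconds (12 s stimuli).
    labels : sequence of str
        Category names cycled over trials.
    coupled_pairs : sequence of (int, int, str)
        Channel pairs sharing a narrowband oscillator with a fixed phase
        lag whenever the trial carries the given label.
    planted_rho : float
        Population first canonical correlation used by the coupled-feature
        generator built on top of this spec.
    relevant_feature_idx : sequence of int
        Feature columns that carry label information in abstract sets.
    noise_sd : float
        Standard deviation of the additive white noise (0 allowed for
        noise-free checks).
    osc_freq : float
        Oscillator frequency in Hz; 10 Hz sits mid-alpha.
    osc_amp : float
        Oscillator amplitude relative to unit-variance noise.
    amp_coupling : float
        Strength of the per-label channel mixing that plants
        label-dependent amplitude covariance.
    seed : int
        Seed for all randomness; identical seeds give identical output.
    """

    n_subjects: int = 1
    n_trials_per_subject: int = 40
    n_channels: int = 8
    fs_eeg: float = 80.0
    trial_length: float = 12.0
    labels: Sequence[str] = QUADRANT_LABELS
    coupled_pairs: Sequence[tuple[int, int, str]] = ()
    planted_rho: float = 0.8
    relevant_feature_idx: Sequence[int] = (0, 1, 2)
    noise_sd: float = 1.0
    osc_freq: float = 10.0
    osc_amp: float = 1.5
    amp_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_rho <= 1.0:
            raise ValueError("planted_rho must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_channels < 2:
            raise ValueError("need at least two channels")
        for c1, c2, lab in self.coupled_pairs:
            if not (0 <= c1 < self.n_channels and 0 <= c2 < self.n_channels):
                raise ValueError(f"coupled pair ({c1},{c2}) outside montage")
            if lab not in self.labels:
                raise ValueError(f"coupled-pair label {lab!r} not in labels")
        if not self.labels:
            raise ValueError("labels must be non-empty")


def _trial_labels(labels: Sequence[str], n_trials: int, rng: np.random.Generator) -> list[str]:
    """Balanced label sequence in randomized order."""
    reps = -(-n_trials // len(labels))
    seq = (list(labels) * reps)[:n_trials]
    rng.shuffle(seq)
    return seq


def gen_eeg_trials(spec: CouplingSpec) -> list[EpochedEeg]:
    """Generate one :class:`EpochedEeg` per subject from a :class:`CouplingSpec`.

    For trials of label ``lab``, the channel pairs listed for ``lab`` share a
    sinusoidal oscillator at ``osc_freq`` with random per-trial initial phase
    and a fixed quarter-cycle lag between the two channels; all other channel
    content is white noise.  When ``amp_coupling > 0``, a per-label channel
    mixing matrix additionally plants label-dependent amplitude covariance,
    visible to amplitude-based connectivity but not to phase locking.
    """
    rng = np.random.default_rng(spec.seed)
    n_samp = int(round(spec.trial_length * spec.fs_eeg))
    t = np.arange(n_samp) / spec.fs_eeg
    channel_names = tuple(f"CH{i:02d}" for i in range(spec.n_channels))

    # fixed per-label mixing matrices for amplitude covariance
    mixers = {}
    for lab in spec.labels:
        r = rng.standard_normal((spec.n_channels, spec.n_channels))
        mixers[lab] = np.eye(spec.n_channels) + spec.amp_coupling * r / np.sqrt(spec.n_channels)

    subjects = []
    for s in range(spec.n_subjects):
        labels = _trial_labels(spec.labels, spec.n_trials_per_subject, rng)
        data = np.empty((spec.n_trials_per_subject, spec.n_channels, n_samp))
        for k, lab in enumerate(labels):
            noise = spec.noise_sd * rng.standard_normal((spec.n_channels, n_samp))
            trial = mixers[lab] @ noise if spec.amp_coupling > 0 else noise
            phase0 = rng.uniform(0, 2 * np.pi)
            for c1, c2, pair_lab in spec.coupled_pairs:
                if pair_lab != lab:
                    continue
                osc = 2 * np.pi * spec.osc_freq * t + phase0
                trial[c1] += spec.osc_amp * np.sin(osc)
                trial[c2] += spec.osc_amp * np.sin(osc + np.pi / 2)
            data[k] = trial
        subjects.append(
            EpochedEeg(data, spec.fs_eeg, channel_names, labels, subject_id=f"S{s:02d}")
        )
    return subjects


# ---------------------------------------------------------------------------
# audio

#: Per-label (attack fraction, decay rate, fundamental Hz) envelope templates.
_LABEL_TEMPLATES = {
    0: (0.05, 0.5, 220.0),   # sharp attack, slow decay
    1: (0.30, 2.0, 330.0),   # slow attack, fast decay
    2: (0.10, 0.0, 165.0),   # near-sustained
    3: (0.50, 1.0, 262.0),   # symmetric swell
}


def label_envelope_template(label_idx: int, n: int) -> np.ndarray:
    """Deterministic nonnegative amplitude template for one label, length ``n``."""
    attack, decay, _ = _LABEL_TEMPLATES[label_idx % 4]
    t = np.linspace(0.0, 1.0, n)
    na = max(int(attack * n), 1)
    env = np.ones(n)
    env[:na] = np.linspace(0.0, 1.0, na)
    env[na:] = np.exp(-decay * (t[na:] - t[na - 1]))
    return env


def gen_audio_trials(
    labels: Sequence[str],
    fs: float = 44100.0,
    seed: int = 0,
    trial_length: float = 12.0,
    jitter: float = 0.05,
    label_names: Sequence[str] = QUADRANT_LABELS,
) -> list[np.ndarray]:
    """One waveform per trial: label-templated envelope on a harmonic carrier.

    Each label has a distinct attack/decay envelope shape and fundamental;
    within-label variation comes from multiplicative envelope jitter and a
    random carrier phase.
    """
    if not labels:
        raise ValueError("label list must be non-empty")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(trial_length * fs))
    t = np.arange(n) / fs
    index = {lab: i for i, lab in enumerate(label_names)}
    waves = []
    for lab in labels:
        li = index.get(lab, 0)
        _, _, f0 = _LABEL_TEMPLATES[li % 4]
        env = label_envelope_template(li, n)
        env = env * (1.0 + jitter * rng.standard_normal())
        env = np.clip(env, 0.0, None)
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.zeros(n)
        for h, w in ((1, 1.0), (2, 0.5), (3, 0.25)):
            carrier += w * np.sin(2 * np.pi * h * f0 * t + h * phase)
        carrier /= np.max(np.abs(carrier))
        waves.append(env * carrier)
    return waves


# ---------------------------------------------------------------------------
# abstract coupled features

@dataclass
class CoupledFeatures:
    """Abstract feature pair with planted canonical correlation and labels."""

    X: np.ndarray
    Y: np.ndarray
    labels: list[str]
    shared_x_col: int
    shared_y_col: int
    label_cols: tuple[int, ...]


def gen_coupled_features(
    n: int,
    P: int,
    Q: int,
    rho: float,
    label_sep: float = 0.0,
    seed: int = 0,
    n_labels: int = 4,
    label_corr: float = 0.0,
    pattern_seed: int | None = None,
    label_names: Sequence[str] = QUADRANT_LABELS,
) -> CoupledFeatures:
    """Feature pair (X: n x P, Y: n x Q) with planted structure.

    A shared unit-variance latent ``z`` enters column 0 of ``X`` unchanged
    and column 0 of ``Y`` as ``rho * z + sqrt(1 - rho^2) * e`` with
    independent ``e``, so the population first canonical correlation is
    exactly ``rho``.  A disjoint set of ``X`` columns carries per-label mean
    shifts of size ``label_sep``; every other column is isotropic noise.

    With ``label_corr > 0`` the shared latent itself is a normalized
    mixture of noise and a per-label offset, mimicking an affective state
    driving both modalities: the supervised weighting then retains the
    coupled columns instead of suppressing them, while the population
    canonical correlation stays exactly ``rho``.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if P < 1 or Q < 1:
        raise ValueError("P and Q must be >= 1")
    rng = np.random.default_rng(seed)
    # label-structure randomness is separable so multiple "subjects" can
    # share one labeling geometry while drawing independent noise
    prng = np.random.default_rng(seed if pattern_seed is None else pattern_seed)
    labels_idx = np.arange(n) % n_labels
    rng.shuffle(labels_idx)
    z = rng.standard_normal(n)
    if label_corr > 0:
        offsets = prng.standard_normal(n_labels)
        offsets -= offsets.mean()
        offsets /= np.sqrt(np.mean(offsets**2))
        z = (z + label_corr * offsets[labels_idx]) / np.sqrt(1.0 + label_corr**2)
    X = rng.standard_normal((n, P))
    Y = rng.standard_normal((n, Q))
    X[:, 0] = z
    Y[:, 0] = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)

    n_lab_cols = min(3, max(1, P - 1))
    label_cols = tuple(range(1, 1 + n_lab_cols)) if P > 1 else ()
    if label_sep > 0 and label_cols:
        # orthogonal-ish per-label shift patterns on the informative columns
        patterns = prng.standard_normal((n_labels, len(label_cols)))
        patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
        X[:, label_cols] += label_sep * patterns[labels_idx]
    labels = [label_names[i % len(label_names)] for i in labels_idx]
    return CoupledFeatures(X, Y, labels, 0, 0, label_cols)
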