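"""Functional-connectivity features: phase locking value and Gaussian connectivity.

Both measures are computed per trial on Hann-tapered overlapping windows of
band-limited EEG.  The phase locking value (PLV) is the modulus of the
time-averaged unit phasor of the instantaneous phase difference between two
channels; Gaussian functional connectivity (GFC) is the Gaussian-kernel
similarity ``exp(-||x - x'||^2 / (2 sigma^2))`` of the two windowed series.
The upper triangles of the per-window, per-band matrices are concatenated
into the trial-by-feature EEG matrix ``X``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .preprocess import BANDS, EpochedEeg, WindowGrid, bandpass, window_segments

MEASURES = ("plv", "gfc")

#: Fraction of samples discarded at each window edge before the PLV
#: expectation, to suppress analytic-signal edge distortion.
EDGE_FRACTION = 0.05


@dataclass
class ConnectivityMatrix:
    """Symmetric unit-diagonal connectivity matrix for one window and band."""

    values: np.ndarray
    measure: str
    window_index: int = 0
    band: str = "broadband"

    def vectorize(self) -> np.ndarray:
        """Strict upper triangle, row-major: length ``n*(n-1)/2``."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


@dataclass
class FeatureDescriptor:
    """Provenance of one EEG feature column."""

    measure: str
    band: str
    window: int
    pair: tuple[str, str]


@dataclass
class EegFeatureMatrix:
    """Trials x features connectivity matrix with per-column provenance."""

    values: np.ndarray
    feature_index: list[FeatureDescriptor]

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.feature_index):
            raise ValueError("feature_index length must match column count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Phase (radians) of the analytic signal along the last axis.

    Meaningful only for narrowband input; band-limit before calling.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 8:
        raise ValueError("need at least 8 samples for a phase estimate")
    if not np.any(x):
        raise ValueError("all-zero signal has no defined phase")
    return np.angle(hilbert(x, axis=-1))


def plv(xc: np.ndarray, xc2: np.ndarray, edge_fraction: float = EDGE_FRACTION) -> float:
    """Phase locking value ``|E[exp(j (phi_c - phi_c'))]|`` in [0, 1].

    The first and last ``edge_fraction`` of samples are excluded from the
    average to avoid Hilbert-transform edge effects.
    """
    xc, xc2 = np.asarray(xc, float), np.asarray(xc2, float)
    if xc.shape != xc2.shape:
        raise ValueError("signals must have equal length")
    dphi = instantaneous_phase(xc) - instantaneous_phase(xc2)
    n = dphi.shape[-1]
    k = int(edge_fraction * n)
    if k:
        dphi = dphi[k:-k]
    return float(np.abs(np.mean(np.exp(1j * dphi))))


def gfc(xc: np.ndarray, xc2: np.ndarray, sigma: float) -> float:
    """Gaussian functional connectivity ``exp(-||x - x'||^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    xc, xc2 = np.asarray(xc, float), np.asarray(xc2, float)
    if xc.shape != xc2.shape:
        raise ValueError("signals must have equal length")
    d2 = float(np.sum((xc - xc2) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _zscore(w: np.ndarray) -> np.ndarray:
    mu = w.mean(axis=-1, keepdims=True)
    sd = w.std(axis=-1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (w - mu) / sd


def _pair_distances(windows: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise channel distances (z-scored) pooled over windows."""
    dists = []
    for w in windows:
        z = _zscore(np.asarray(w, float))
        for i, j in combinations(range(z.shape[0]), 2):
            dists.append(np.linalg.norm(z[i] - z[j]))
    return np.asarray(dists)


def select_bandwidth(
    windows: Sequence[np.ndarray],
    grid: Sequence[float] | None = None,
    n_grid: int = 20,
) -> float:
    """Pick the GFC length scale maximizing the spread of connectivity values.

    For each candidate sigma the off-diagonal GFC values over all channel
    pairs and windows are computed; the sigma with the largest variance of
    those values is returned.  In the limits sigma -> 0 and sigma -> inf all
    values collapse to 0 or 1 and the variance vanishes, so the selected
    sigma is interior.  The default grid is 20 log-spaced values around the
    median pairwise distance.  With fewer than two distinct pairs the
    variance is degenerate everywhere and the grid median is returned with a
    warning.
    """
    d = _pair_distances(windows)
    if grid is None:
        med = float(np.median(d)) if d.size and np.median(d) > 0 else 1.0
        grid = np.geomspace(med / 10.0, med * 10.0, n_grid)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("sigma grid must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("sigma candidates must be positive")
    if d.size < 2:
        warnings.warn("degenerate pair set: returning grid median sigma")
        return float(np.median(grid))
    variances = [np.var(np.exp(-(d**2) / (2.0 * s**2))) for s in grid]
    if np.max(variances) <= 0:
        warnings.warn("GFC value variance degenerate on grid: returning median sigma")
        return float(np.median(grid))
    return float(grid[int(np.argmax(variances))])


def connectivity_matrix(
    window: np.ndarray,
    measure: str,
    sigma: float | None = None,
    standardize: bool = True,
) -> ConnectivityMatrix:
    """All-pairs connectivity of one ``channels x samples`` window.

    GFC distances are computed on per-channel z-scored series by default so
    that residual amplitude offsets do not dominate; PLV is amplitude
    invariant by construction.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 2:
        raise ValueError("window must be (channels >= 2, samples)")
    measure = measure.lower()
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; options: {MEASURES}")
    nc = window.shape[0]
    values = np.eye(nc)
    if measure == "plv":
        phi = instantaneous_phase(window)
        n = phi.shape[-1]
        k = int(EDGE_FRACTION * n)
        sl = slice(k, n - k) if k else slice(None)
        phasor = np.exp(1j * phi[:, sl])
        for i, j in combinations(range(nc), 2):
            values[i, j] = values[j, i] = np.abs(np.mean(phasor[i] * np.conj(phasor[j])))
    else:
        if sigma is None:
            raise ValueError("GFC requires a sigma (see select_bandwidth)")
        w = _zscore(window) if standardize else window
        for i, j in combinations(range(nc), 2):
            values[i, j] = values[j, i] = gfc(w[i], w[j], sigma)
    return ConnectivityMatrix(values, measure)


def extract_fc_features(
    eeg: EpochedEeg,
    grid: WindowGrid,
    bands: Sequence[str] = ("broadband",),
    measures: Sequence[str] = ("plv", "gfc"),
    sigma: float | None = None,
    sigma_grid: Sequence[float] | None = None,
) -> EegFeatureMatrix:
    """Per-trial vectorized connectivity over windows, bands, and measures.

    Columns are ordered (measure, band, window, pair) with pairs in
    row-major upper-triangle order; ``feature_index`` records the provenance
    of every column.  The GFC bandwidth, if not supplied, is selected once
    per band from the pooled tapered windows of all trials.
    """
    if not bands or not measures:
        raise ValueError("bands and measures must be non-empty")
    measures = tuple(m.lower() for m in measures)
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}")
    nc = eeg.n_channels
    pairs = list(combinations(range(nc), 2))
    pair_names = [(eeg.channel_names[i], eeg.channel_names[j]) for i, j in pairs]
    n_win = grid.n_windows(eeg.duration)

    # band-filter once, window once
    band_windows: dict[str, list[list[np.ndarray]]] = {}
    for band in bands:
        low, high = BANDS[band]
        # the broadband edge may exceed Nyquist after the 80 Hz downsample;
        # the wideband content is then already whatever survived resampling
        high = min(high, 0.95 * eeg.fs / 2.0)
        filtered = bandpass(eeg.data, eeg.fs, low, high)
        band_windows[band] = [
            window_segments(filtered[k], grid, eeg.fs) for k in range(eeg.n_trials)
        ]

    sigmas: dict[str, float] = {}
    if "gfc" in measures:
        for band in bands:
            if sigma is not None:
                sigmas[band] = sigma
            else:
                pooled = [w for trial in band_windows[band] for w in trial]
                # cap the pool for bandwidth selection; statistics saturate fast
                sigmas[band] = select_bandwidth(pooled[: max(8, n_win * 4)], sigma_grid)

    columns: list[np.ndarray] = []
    index: list[FeatureDescriptor] = []
    for measure in measures:
        for band in bands:
            for m in range(n_win):
                block = np.empty((eeg.n_trials, len(pairs)))
                for k in range(eeg.n_trials):
                    cm = connectivity_matrix(
                        band_windows[band][k][m], measure, sigma=sigmas.get(band)
                    )
                    block[k] = cm.vectorize()
                columns.append(block)
                index.extend(
                    FeatureDescriptor(measure, band, m, pn) for pn in pair_names
                )
    return EegFeatureMatrix(np.hstack(columns), index)
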