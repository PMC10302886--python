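"""Partition quality, cross-validated correlation, and configuration sweeps.

The partition-quality statistic ``gamma`` combines a silhouette-style
between/within distance term with the mean squared distance of samples to
their group centers.  Leave-one-subject-out (LOSO) cross-validation reports
the spread of the canonical correlation across held-out participants, and
``sweep`` re-runs extraction plus alignment across window lengths, bands,
electrode sets, or subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .audio import assemble_audio_features
from .connectivity import extract_fc_features
from .lca import LabeledCorrelationAlignment
from .preprocess import EpochedEeg, WindowGrid, drop_channels


@dataclass
class GammaResult:
    """Partition-quality statistic and its two components.

    ``gamma = silhouette_term + scatter_term``: the first term is the mean
    per-sample silhouette ``(xi1 - xi0) / max(xi0, xi1)`` (between-group
    minus within-group mean distance over their max), the second the mean
    squared distance of samples to their own group center.  The two terms
    pull in different directions for diffuse clusters, so both are exposed;
    ``variant="silhouette"`` drops the scatter term.
    """

    gamma: float
    silhouette_term: float
    scatter_term: float
    n_groups: int


def clustering_gamma(
    samples: np.ndarray, groups: Sequence, variant: str = "full"
) -> GammaResult:
    """Partition quality of labeled samples; higher = cleaner separation.

    ``samples`` is n x d; ``groups`` the per-sample labels (>= 2 distinct).
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    groups = np.asarray(list(groups))
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if variant not in ("full", "silhouette"):
        raise ValueError("variant must be 'full' or 'silhouette'")
    D = cdist(X, X)
    sil = np.empty(len(X))
    for i in range(len(X)):
        same = (groups == groups[i])
        same[i] = False
        xi0 = D[i, same].mean() if same.any() else 0.0
        xi1 = min(D[i, groups == g].mean() for g in uniq if g != groups[i])
        denom = max(xi0, xi1)
        sil[i] = (xi1 - xi0) / denom if denom > 0 else 0.0
    silhouette_term = float(sil.mean())

    centers = {g: X[groups == g].mean(axis=0) for g in uniq}
    sq = [float(np.sum((x - centers[g]) ** 2)) for x, g in zip(X, groups)]
    scatter_term = float(np.mean(sq))

    gamma = silhouette_term + (scatter_term if variant == "full" else 0.0)
    return GammaResult(gamma, silhouette_term, scatter_term, int(uniq.size))


def dynamic_resolution(r_series: Sequence[float]) -> float:
    """Mean absolute difference between neighboring windowed correlations."""
    r = np.asarray(list(r_series), dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 values")
    return float(np.mean(np.abs(np.diff(r))))


def loso_correlation(
    per_subject: Sequence[tuple[np.ndarray, np.ndarray, Sequence]],
    d: int | None = None,
    regularization: float = 1e-3,
    seed: int = 0,
    single_step: bool = False,
) -> tuple[float, float, list[float]]:
    """Leave-one-subject-out confidence of the canonical correlation.

    Each element of ``per_subject`` is ``(X, Y, labels)`` for one
    participant.  For every fold the model is fitted on the pooled other
    subjects and the squared Pearson correlation of the held-out subject's
    canonical variates is recorded.  Returns ``(mean, std, per-fold r^2)``.
    """
    if len(per_subject) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    fold_r2 = []
    for k in range(len(per_subject)):
        X_tr = np.vstack([s[0] for i, s in enumerate(per_subject) if i != k])
        Y_tr = np.vstack([s[1] for i, s in enumerate(per_subject) if i != k])
        lab_tr = [l for i, s in enumerate(per_subject) if i != k for l in s[2]]
        model = LabeledCorrelationAlignment(X_tr, Y_tr, lab_tr, d=d, regularization=regularization)
        res = model.fit(single_step=single_step, seed=seed)
        u, v = res.transform(per_subject[k][0], per_subject[k][1])
        if np.std(u) == 0 or np.std(v) == 0:
            fold_r2.append(0.0)
        else:
            fold_r2.append(float(np.corrcoef(u, v)[0, 1] ** 2))
    return float(np.mean(fold_r2)), float(np.std(fold_r2)), fold_r2


@dataclass
class SweepResult:
    """Per-setting aggregation of canonical correlation and partition quality."""

    axis: str
    values: dict = field(default_factory=dict)  # setting -> (r2_mean, r2_std, gamma)


SWEEP_AXES = ("window", "band", "electrode_set", "subject")


def _fit_r2_gamma(X, Y, labels, feature_index, d, seed):
    model = LabeledCorrelationAlignment(X, Y, labels, feature_index=feature_index, d=d)
    res = model.fit(seed=seed)
    # per-label r^2 of the canonical variates, averaged across the label set
    u, v = res.canonical_scores()
    labs = np.asarray(labels)
    r2s = []
    for g in np.unique(labs):
        m = labs == g
        if m.sum() > 2 and np.std(u[m]) > 0 and np.std(v[m]) > 0:
            r2s.append(np.corrcoef(u[m], v[m])[0, 1] ** 2)
    r2s = np.asarray(r2s) if r2s else np.asarray([res.r_squared])
    return float(r2s.mean()), float(r2s.std()), float(res.gamma().gamma)


def sweep(
    axis: str,
    settings: Sequence,
    eeg: EpochedEeg | Sequence[EpochedEeg],
    stimuli: Sequence[np.ndarray],
    fs_audio: float = 44100.0,
    grid: WindowGrid | None = None,
    bands: Sequence[str] = ("broadband",),
    measures: Sequence[str] = ("plv", "gfc"),
    d: int | None = 8,
    seed: int = 0,
) -> SweepResult:
    """Re-run extraction + alignment for each setting of one axis.

    Axes: ``window`` (settings are tau values in seconds), ``band``
    (band names), ``electrode_set`` (channel-name lists or montage
    presets), ``subject`` (indices into a list of per-subject
    :class:`EpochedEeg`).  Stimuli are the per-trial waveforms shared by
    all settings.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; options: {SWEEP_AXES}")
    result = SweepResult(axis)
    base_grid = grid or WindowGrid(tau=3.0)

    def one(eeg_k: EpochedEeg, g: WindowGrid, bds, label):
        fx = extract_fc_features(eeg_k, g, bands=bds, measures=measures)
        fy = assemble_audio_features(stimuli, g, n_phi=eeg_k.n_channels, fs=fs_audio)
        result.values[label] = _fit_r2_gamma(
            fx.values, fy.values, eeg_k.labels, fx.feature_index, d, seed
        )

    if axis == "subject":
        for s in settings:
            one(eeg[s], base_grid, bands, s)
        return result
    if not isinstance(eeg, EpochedEeg):
        raise ValueError(f"axis {axis!r} expects a single EpochedEeg")
    for s in settings:
        if axis == "window":
            one(eeg, WindowGrid(tau=float(s)), bands, s)
        elif axis == "band":
            one(eeg, base_grid, (s,), s)
        else:  # electrode_set
            one(drop_channels(eeg, s), base_grid, bands, s)
    return result
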