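"""Kernel utilities for supervised centered kernel alignment.

The label kernel is the delta kernel on categorical labels; the feature
kernel is a Gaussian kernel with a learned linear weighting ``W`` acting as
the square root of the inverse covariance.  Alignment is the normalized
Frobenius inner product of the two double-centered kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class KernelMatrix:
    """Symmetric PSD kernel matrix with a centering flag."""

    values: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def delta_kernel(labels: Sequence) -> KernelMatrix:
    """Delta kernel on categorical labels: 1 where labels match, else 0."""
    labels = list(labels)
    if not labels:
        raise ValueError("label list must be non-empty")
    arr = np.asarray(labels)
    return KernelMatrix((arr[:, None] == arr[None, :]).astype(float))


def center_kernel(K: KernelMatrix | np.ndarray) -> KernelMatrix:
    """Double centering ``H K H`` with ``H = I - 1 1^T / n``; idempotent."""
    vals = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("kernel matrix must be square")
    row = vals.mean(axis=1, keepdims=True)
    col = vals.mean(axis=0, keepdims=True)
    return KernelMatrix(vals - row - col + vals.mean(), centered=True)


def weighted_gaussian_kernel(features: np.ndarray, W: np.ndarray) -> KernelMatrix:
    """Gaussian kernel ``exp(-||(xi - xj) W||^2 / 2)`` of projected features."""
    X = np.asarray(features, dtype=float)
    W = np.asarray(W, dtype=float)
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"feature dim {X.shape[1]} != W rows {W.shape[0]}")
    Z = X @ W
    sq = np.sum(Z**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-d2 / 2.0)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K)


def cka_alignment(Ka: KernelMatrix, Kb: KernelMatrix) -> float:
    """Centered kernel alignment ``<Ka, Kb>_F / (||Ka||_F ||Kb||_F)``.

    Both inputs must already be centered; the value lies in [0, 1] for
    positive-semidefinite kernels.  If either norm vanishes the alignment is
    undefined and 0 is returned with a warning.
    """
    if not (Ka.centered and Kb.centered):
        raise ValueError("cka_alignment expects centered kernels (see center_kernel)")
    if Ka.n != Kb.n:
        raise ValueError("kernel size mismatch")
    na = np.linalg.norm(Ka.values)
    nb = np.linalg.norm(Kb.values)
    if na == 0 or nb == 0:
        warnings.warn("zero-norm centered kernel: alignment undefined, returning 0")
        return 0.0
    return float(np.sum(Ka.values * Kb.values) / (na * nb))
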