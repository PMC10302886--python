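"""Compact vector-quantized variational autoencoder over acoustic envelopes.

The encoder cuts an envelope into equal patches and maps each patch through
a small strided-convolutional (patch-shared) network to a D-dimensional
latent; each latent is snapped to its nearest entry of a finite codebook,
and the decoder maps the quantized sequence back to patches with a softplus
head keeping outputs nonnegative.  Training minimizes the sum of a
reconstruction term, a codebook term on stop-gradient latents, and a
beta-weighted commitment term on stop-gradient code vectors; gradients pass
the quantizer by the straight-through estimator.  Everything is plain numpy
with hand-written backpropagation and Adam, deterministic under a fixed
seed.

Sonification feeds the encoder with EEG-derived vectors of the same length
and spectral bandwidth as the training envelopes (the transfer-compatibility
check); the decoder then emits envelope-like nonnegative sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .audio import AcousticEnvelope


@dataclass
class Codebook:
    """Finite set of K latent code vectors of dimension D."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2 or self.entries.shape[0] < 2:
            raise ValueError("codebook must be (K >= 2, D)")

    @property
    def K(self) -> int:
        return self.entries.shape[0]

    @property
    def D(self) -> int:
        return self.entries.shape[1]


@dataclass
class VqVaeConfig:
    """Hyperparameters of the envelope autoencoder.

    ``patch_size`` is the encoder stride/kernel in samples (the latent
    sequence has ``L // patch_size`` steps); ``beta`` weights the
    commitment term and must lie in [0, 1].
    """

    hidden: int = 32
    K: int = 64
    D: int = 16
    patch_size: int = 16
    beta: float = 0.25
    learning_rate: float = 5e-3
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def quantize(h: np.ndarray, codebook: Codebook) -> tuple[np.ndarray, np.ndarray]:
    """Snap each latent vector to its nearest codebook entry (Euclidean).

    ``h`` is (..., D).  Ties break toward the lowest index (argmin
    semantics).  Returns ``(indices, quantized)``.
    """
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != codebook.D:
        raise ValueError(f"latent dim {h.shape[-1]} != codebook dim {codebook.D}")
    flat = h.reshape(-1, codebook.D)
    d2 = (
        np.sum(flat**2, axis=1, keepdims=True)
        - 2.0 * flat @ codebook.entries.T
        + np.sum(codebook.entries**2, axis=1)
    )
    idx = np.argmin(d2, axis=1)
    q = codebook.entries[idx].reshape(h.shape)
    return idx.reshape(h.shape[:-1]), q


def vqvae_loss(
    inputs: np.ndarray,
    reconstruction: np.ndarray,
    latents: np.ndarray,
    quantized: np.ndarray,
    beta: float,
) -> tuple[float, float, float, float]:
    """Three-term quantized-autoencoder loss: ``(total, recon, codebook, commit)``.

    ``recon`` is the mean squared reconstruction error; the codebook term is
    the mean squared error between stop-gradient latents and their code
    vectors (it moves only the codebook); the commitment term is the same
    distance with the stop-gradient on the code vectors, weighted by
    ``beta`` (it moves only the encoder).  ``total = recon + codebook +
    beta * commit_mse``; the returned ``commit`` is already beta-weighted.
    """
    inputs, reconstruction = np.asarray(inputs, float), np.asarray(reconstruction, float)
    latents, quantized = np.asarray(latents, float), np.asarray(quantized, float)
    if inputs.shape != reconstruction.shape or latents.shape != quantized.shape:
        raise ValueError("shape mismatch between paired arguments")
    recon = float(np.mean((inputs - reconstruction) ** 2))
    code = float(np.mean((latents - quantized) ** 2))
    commit = beta * code
    return recon + code + commit, recon, code, commit


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


class VqVae:
    """Patch-strided envelope autoencoder with a learned finite codebook."""

    def __init__(self, input_length: int, config: VqVaeConfig | None = None) -> None:
        self.config = config or VqVaeConfig()
        c = self.config
        if input_length % c.patch_size != 0:
            raise ValueError(
                f"input length {input_length} not divisible by patch_size {c.patch_size}"
            )
        self.input_length = input_length
        self.n_patches = input_length // c.patch_size
        rng = np.random.default_rng(c.seed)
        p, hdim, D = c.patch_size, c.hidden, c.D

        def glorot(a, b):
            return rng.standard_normal((a, b)) * np.sqrt(2.0 / (a + b))

        # encoder: patch -> hidden -> D (shared across patches = strided conv)
        self.We1, self.be1 = glorot(p, hdim), np.zeros(hdim)
        self.We2, self.be2 = glorot(hdim, D), np.zeros(D)
        # decoder: D -> hidden -> patch, softplus head
        self.Wd1, self.bd1 = glorot(D, hdim), np.zeros(hdim)
        self.Wd2, self.bd2 = glorot(hdim, p), np.zeros(p)
        self.codebook = Codebook(0.5 * rng.standard_normal((c.K, D)))
        self.loss_history: list[tuple[float, float, float, float]] = []
        self.train_bandwidth: float | None = None
        self.train_fs: float = 64.0

    # -- forward pieces -----------------------------------------------------

    def _patches(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        return x.reshape(n * self.n_patches, self.config.patch_size)

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Latent sequence (n, S, D) of envelopes (n, L)."""
        P = self._patches(np.asarray(x, float))
        H1 = np.tanh(P @ self.We1 + self.be1)
        H = H1 @ self.We2 + self.be2
        return H.reshape(x.shape[0], self.n_patches, self.config.D)

    def decode(self, q: np.ndarray) -> np.ndarray:
        """Nonnegative envelopes (n, L) from a quantized sequence (n, S, D)."""
        flat = q.reshape(-1, self.config.D)
        G1 = np.tanh(flat @ self.Wd1 + self.bd1)
        out = _softplus(G1 @ self.Wd2 + self.bd2)
        return out.reshape(q.shape[0], self.input_length)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        _, q = quantize(self.encode(x), self.codebook)
        return self.decode(q)

    # -- training -----------------------------------------------------------

    def fit(self, envelopes: np.ndarray, epochs: int | None = None) -> "VqVae":
        """Full-batch training of encoder, decoder, and codebook."""
        X = np.asarray(envelopes, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_length:
            raise ValueError("envelopes must be (n, input_length)")
        if X.shape[0] < 8:
            raise ValueError("need at least 8 envelopes to train")
        c = self.config
        epochs = c.epochs if epochs is None else epochs
        n = X.shape[0]
        N = n * self.input_length
        S = n * self.n_patches

        params = [self.We1, self.be1, self.We2, self.be2,
                  self.Wd1, self.bd1, self.Wd2, self.bd2, self.codebook.entries]
        opt = _Adam([p.shape for p in params], c.learning_rate)

        P = self._patches(X)
        for _ in range(epochs):
            # forward
            H1 = np.tanh(P @ self.We1 + self.be1)
            H = H1 @ self.We2 + self.be2                     # (S, D) latents
            idx, Q = quantize(H, self.codebook)
            G1 = np.tanh(Q @ self.Wd1 + self.bd1)
            Z = G1 @ self.Wd2 + self.bd2
            out = _softplus(Z)

            losses = vqvae_loss(P, out, H, Q, c.beta)
            if not np.isfinite(losses[0]):
                raise RuntimeError(
                    f"training diverged at epoch {len(self.loss_history)}: "
                    f"loss={losses[0]}; lower the learning rate"
                )
            self.loss_history.append(losses)

            # backward: reconstruction path (straight-through at the quantizer)
            dout = 2.0 * (out - P) / N
            dZ = dout * _sigmoid(Z)
            gWd2 = G1.T @ dZ
            gbd2 = dZ.sum(axis=0)
            dG1 = dZ @ self.Wd2.T
            dQpre = dG1 * (1.0 - G1**2)
            gWd1 = Q.T @ dQpre
            gbd1 = dQpre.sum(axis=0)
            dQ = dQpre @ self.Wd1.T        # gradient wrt quantized latents
            # straight-through: copy to encoder latents; commitment adds its pull
            dH = dQ + 2.0 * c.beta * (H - Q) / H.size
            dH1 = (dH @ self.We2.T) * (1.0 - H1**2)
            gWe2 = H1.T @ dH
            gbe2 = dH.sum(axis=0)
            gWe1 = P.T @ dH1
            gbe1 = dH1.sum(axis=0)
            # codebook term: pull each assigned entry toward its latents
            gE = np.zeros_like(self.codebook.entries)
            np.add.at(gE, idx, 2.0 * (Q - H) / H.size)

            opt.step(params, [gWe1, gbe1, gWe2, gbe2, gWd1, gbd1, gWd2, gbd2, gE])

        # record transfer statistics of the training set
        self.train_bandwidth = float(
            np.mean([_bandwidth_95(e, self.train_fs) for e in X])
        )
        return self


def train_vqvae(
    envelopes: Sequence[AcousticEnvelope] | np.ndarray,
    config: VqVaeConfig | None = None,
) -> VqVae:
    """Train a :class:`VqVae` on a set of equal-length envelopes."""
    if isinstance(envelopes, np.ndarray):
        X = envelopes
        fs = 64.0
    else:
        lengths = {len(e.values) for e in envelopes}
        if len(lengths) != 1:
            raise ValueError("all envelopes must have the same length")
        X = np.vstack([e.values for e in envelopes])
        fs = envelopes[0].fs
    cfg = config or VqVaeConfig()
    L = X.shape[1] - X.shape[1] % cfg.patch_size
    model = VqVae(L, cfg)
    model.train_fs = fs
    model.fit(X[:, :L])
    return model


# ---------------------------------------------------------------------------
# transfer check and sonification

def _bandwidth_95(x: np.ndarray, fs: float) -> float:
    """Frequency below which 95% of the (mean-removed) spectral energy lies."""
    x = np.asarray(x, float)
    p = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    tot = p.sum()
    if tot == 0:
        return 0.0
    return float(freqs[int(np.searchsorted(np.cumsum(p), 0.95 * tot))])


@dataclass
class TransferReport:
    """Outcome of the source/target transfer-compatibility check."""

    passed: bool
    bandwidth_ok: bool
    dims_ok: bool
    bandwidth_source: float
    bandwidth_target: float
    tol: float

    def __str__(self) -> str:
        return (
            f"transfer check: {'PASS' if self.passed else 'FAIL'} "
            f"(bandwidth {self.bandwidth_source:.2f} vs "
            f"{self.bandwidth_target:.2f} Hz, tol {self.tol:.0%}, "
            f"dims {'ok' if self.dims_ok else 'mismatch'})"
        )


def check_transfer_conditions(
    source: np.ndarray,
    target: np.ndarray,
    tol: float = 0.2,
    fs: float = 64.0,
) -> TransferReport:
    """Check that two signal sets are exchangeable for the trained coder.

    Passes iff the mean 95%-energy spectral bandwidths agree within ``tol``
    (relative to the larger) and the per-sample dimensions match.
    """
    S = np.atleast_2d(np.asarray(source, float))
    T = np.atleast_2d(np.asarray(target, float))
    if S.size == 0 or T.size == 0:
        raise ValueError("both sets must be non-empty")
    dims_ok = S.shape[1] == T.shape[1]
    bw_s = float(np.mean([_bandwidth_95(row, fs) for row in S]))
    bw_t = float(np.mean([_bandwidth_95(row, fs) for row in T]))
    hi = max(bw_s, bw_t)
    bandwidth_ok = hi == 0 or abs(bw_s - bw_t) / hi <= tol
    return TransferReport(bandwidth_ok and dims_ok, bandwidth_ok, dims_ok, bw_s, bw_t, tol)


class EegFrontProjection:
    """Linear front end mapping connectivity features to the envelope length.

    A single convolution-style map: seeded linear weights, a short smoothing
    kernel along the output axis, and a softplus nonlinearity keeping the
    result nonnegative.  Optionally fitted by ridge regression against
    paired training envelopes.
    """

    def __init__(self, n_features: int, output_length: int, seed: int = 0,
                 smooth_len: int = 5) -> None:
        rng = np.random.default_rng(seed)
        self.W = rng.standard_normal((n_features, output_length)) / np.sqrt(n_features)
        self.b = np.zeros(output_length)
        self.smooth = np.ones(smooth_len) / smooth_len
        self.output_length = output_length

    def fit(self, features: np.ndarray, envelopes: np.ndarray, ridge: float = 1e-2) -> "EegFrontProjection":
        """Ridge-regress pre-nonlinearity outputs onto inverse-softplus targets."""
        X = np.asarray(features, float)
        E = np.clip(np.asarray(envelopes, float), 1e-6, None)
        T = E + np.log1p(-np.exp(-E))  # softplus^{-1}
        Xc = X - X.mean(axis=0)
        A = Xc.T @ Xc + ridge * np.trace(Xc.T @ Xc) / X.shape[1] * np.eye(X.shape[1])
        self.W = np.linalg.solve(A, Xc.T @ (T - T.mean(axis=0)))
        self.b = T.mean(axis=0) - X.mean(axis=0) @ self.W
        return self

    def __call__(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, float))
        Z = X @ self.W + self.b
        Z = np.apply_along_axis(lambda r: np.convolve(r, self.smooth, mode="same"), 1, Z)
        return _softplus(Z)


def sonify(
    model: VqVae,
    eeg_features: np.ndarray,
    smoothing: bool = False,
    check: bool = True,
    tol: float = 0.5,
) -> np.ndarray:
    """Decode envelope-compatible EEG feature rows into acoustic envelopes.

    ``eeg_features`` must already have the encoder's input length (see
    :class:`EegFrontProjection`).  With ``check`` the transfer-compatibility
    report against the training bandwidth is enforced and a failing check
    raises.  ``smoothing`` applies a 3-sample moving average to the inputs
    before encoding, damping abrupt changes in the generated envelopes.
    """
    X = np.atleast_2d(np.asarray(eeg_features, float))
    if X.shape[1] != model.input_length:
        raise ValueError(
            f"feature rows of length {X.shape[1]}; encoder expects {model.input_length}"
        )
    if check and model.train_bandwidth is not None:
        bw = float(np.mean([_bandwidth_95(r, model.train_fs) for r in X]))
        hi = max(bw, model.train_bandwidth)
        if hi > 0 and abs(bw - model.train_bandwidth) / hi > tol:
            report = TransferReport(False, False, True, bw, model.train_bandwidth, tol)
            raise ValueError(f"refusing to sonify: {report}")
    if smoothing:
        k = np.ones(3) / 3.0
        X = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 1, X)
    return model.reconstruct(X)
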