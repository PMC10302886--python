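# Methods

This note documents the models and procedures implemented in `lcalign`,
the numerical choices behind them, what the synthetic studies emulate, and
the package's known limits.

## EEG conditioning

Raw epochs pass through a fixed chain: zero-phase bandpass, channel
removal, common-average reference, resampling, and windowing. The bandpass
is a 3rd-order Butterworth applied forward and backward (`sosfiltfilt`), so
the magnitude response is squared (effective 6th order) and the phase
response cancels — a requirement for any later phase estimate. The default
band is 1–45 Hz; physiological sub-bands are θ 4–8, α 8–12, and β 12–30 Hz,
re-filtered from the conditioned signal with the same design. When epochs
arrive already downsampled (80 Hz is the working rate), the upper band edge
is clipped to 95 % of Nyquist; at 80 Hz the "broadband" content is whatever
survived resampling anyway. Montage presets follow the 19-channel 10–20
cap: `E17` removes the artifact-prone occipital pair (O1, O2), `E14`
additionally removes Fp1, Fp2, and Pz.

Windowing uses a symmetric Hann taper with 50 % overlap. Only full-length
windows are kept, so the count is exactly
`M = floor((T − τ)/(τ/2)) + 1`; for 12 s trials the τ grid
{12, 6, 3, 1.5, 0.75, 0.375} s gives {1, 3, 7, 15, 31, 63} windows.
Windows are defined in seconds, which is the synchronization contract
between the 80 Hz EEG stream and the 64 Hz audio envelope: the two
modalities are never resampled to a common rate.

## Functional connectivity

**PLV.** The instantaneous phase is the angle of the analytic signal
(Hilbert construction) of the tapered, band-limited window; the phase is
only meaningful for narrowband input, which is why the taper and band
filter come first. The first and last 5 % of samples are excluded from the
phasor average to suppress the analytic signal's edge distortion. For
independent phases the expected PLV is the Rayleigh mean
√π/2·N^(−1/2) ≈ 0.029 at N = 960 — the test suite checks this against
direct simulation.

**GFC.** The Gaussian similarity exp(−‖x_c − x_c′‖²/2σ²) is computed on
per-channel z-scored windows; without standardization the distance is
dominated by amplitude offsets that re-referencing does not fully remove.
The length scale σ is selected per band by maximizing the variance of the
off-diagonal connectivity values over a 20-point log-spaced grid centered
on the median pairwise distance: both limits (σ → 0, all values 0; σ → ∞,
all values 1) have zero variance, so the maximizer is interior. A
degenerate pair set falls back to the grid median with a warning.

Matrices are symmetric with unit diagonal by construction and vectorized
as the strict upper triangle in row-major order, giving N_φ(N_φ−1)/2
features per window/band/measure, with full per-column provenance kept in
`feature_index`.

## Acoustic features

Twenty descriptors per analysis frame (2048 samples, 50 % hop, Hann
spectrum): zero-crossing rate, high/low energy ratio (split 1500 Hz),
normalized spectral entropy, spread, 85 % roll-off, flatness, roughness,
RMS, broadband spectral flux, spectral centroid, and spectral flux in ten
octave bands anchored at 31.25 Hz. Roughness is a sensory-dissonance
dialect: pairwise Plomp–Levelt-style interaction of the strongest spectral
peaks. The descriptor list in the source literature contains a duplicated
entry yet is counted as 20; the slot is filled with the spectral centroid,
a standard music-information descriptor. Flatness is computed from a
single periodogram, for which white noise concentrates near
exp(−γ_Euler) ≈ 0.56, not near 1 — thresholds in tests were derived by
Monte-Carlo from this implementation.

Each window's frame trajectory is reduced by its first principal
component: the leading axis of the centered trajectory (sign fixed,
scaled by the component standard deviation) gives one scalar per
descriptor per window; a constant trajectory maps to zero with a warning.

The envelope pipeline is square → 125 ms boxcar convolution → polyphase
resample to 64 Hz → cube-root compression. The boxcar length passes
amplitude modulation below ≈ 8 Hz; for a sinusoid of amplitude A the
plateau is (A²/2)^(1/3) exactly, which the tests verify. Per trial and
window, the feature row is the 20 reduced descriptors plus N_φ−1 envelope
samples drawn evenly from that window's stretch of the envelope, giving
Q = N_τ(20 + N_φ − 1); the envelope samples are taken per window, which
makes that width formula dimensionally exact.

## Two-step alignment

**Step 1 — supervised CKA.** For each modality the weighting W (P×d,
default d = min(P, 32)) is fitted by full-batch gradient ascent of the
centered-kernel alignment with the delta label kernel. The gradient is
analytic (verified against finite differences to ~1e-11):
with M = (∂ρ/∂K) ∘ K and r its row sums,
∂ρ/∂W = 2 Ξᵀ(M − diag(r)) Ξ W. Steps that improve the alignment are
accepted and grow the step size ×1.2; rejected steps halve it; the run
stops after 10 stalled iterations (relative change < 1e-6) or 500
iterations, returning the best-seen W. W is initialized from the top-d
principal axes of the standardized features (a tiny seeded perturbation
breaks ties), scaled so the median projected pairwise squared distance is
1, which puts the initial kernel in its sensitive range. Features are
standardized per column before both the kernel and the CCA; the Gaussian
kernel is scale-sensitive, so this is load-bearing.

Selection is soft: the projection ξ̃ = ξW weights features rather than
thresholding them. Relevance is the normalized L2 norm of W's rows;
electrode relevance averages the relevance of all features whose channel
pair includes the electrode (pooling windows, bands, measures) and
normalizes the maximum to 1.

*Calibration caveat.* The in-sample fitted alignment is an optimized
statistic: with n trials and a flexible kernel the ascent aligns almost
perfectly with arbitrary labels, so the in-sample value cannot be compared
to a fixed-kernel permutation band. `alignment_holdout_test` therefore
fits on a random half, evaluates the alignment of the learned kernel on
the held-out half, and permutes held-out labels for the null; under
label-independence the observed value is exchangeable with the null by
construction. The same logic applies to the canonical correlation — its
permutation null refits the CCA per shuffle.

**Step 2 — CCA.** First canonical pair only, by Cholesky whitening of the
ridge-regularized auto-covariances and SVD of the whitened
cross-covariance. The ridge term is `reg · tr(Σ)/dim · I` with
reg = 1e-3 by default, keeping the fit defined when feature counts
approach the trial count; reg = 0 recovers textbook CCA (used by the
exactness and affine-invariance tests). The sign of α_X's first nonzero
entry is forced positive for reproducibility.

The model surface is `LabeledCorrelationAlignment(X, Y, labels).fit()`
returning an `LCAResults` with the weightings, the canonical pair,
relevance maps, partition quality, `transform` for held-out trials, and a
`summary()` table. `fit(single_step=True)` skips the supervised weighting
— the baseline the two-step comparison is scored against.

## Partition quality γ

γ = silhouette term + scatter term. Per sample, ξ₀ is the mean distance to
its own group and ξ₁ the mean distance to the closest other group; the
silhouette term averages (ξ₁−ξ₀)/max(ξ₀, ξ₁). The scatter term is the mean
squared distance of samples to their group centroid. The composed statistic
is reported verbatim along with both components, because the scatter term
*increases* with within-group spread and can therefore pull against the
interpretation "larger γ = cleaner partition"; `variant="silhouette"`
drops it. Distances are Euclidean throughout. Model-level γ is computed on
the paired canonical scores (u, v) under the trial labels.

## Cross-validation and sweeps

`loso_correlation` refits the whole two-step model on all-but-one subject
and records the squared Pearson correlation of the held-out subject's
canonical variates; it reports mean, standard deviation, and per-fold
values. `sweep` re-runs extraction plus alignment along one axis — window
length, band, electrode set, or subject — reporting per-label-averaged r²
and γ per setting.

## Sonification

The envelope autoencoder is written in plain numpy with hand-derived
backpropagation and Adam, deterministic under a fixed seed in
single-threaded execution. The encoder is patch-strided (stride = kernel =
`patch_size`, default 16 samples): each patch maps through a shared
tanh hidden layer (width 32) to a D = 16 latent; each latent snaps to the
nearest of K = 64 codebook entries (ties to the lowest index); the decoder
mirrors the encoder with a softplus head, keeping outputs nonnegative.
The three-term loss is reconstruction MSE + codebook MSE (stop-gradient on
the latents) + β × commitment MSE (stop-gradient on the code vectors),
β = 0.25 by default. Gradients pass the quantizer by the straight-through
estimator; the codebook is updated only by the codebook term, the encoder
additionally by the commitment pull — the stop-gradient semantics are
structural in the hand-written backward pass, not emulated. Codebook sizes
and widths were chosen so training on ≤ 768-sample envelopes takes seconds
on one CPU.

Transfer compatibility between the training envelopes and any candidate
encoder input requires matching per-sample dimension and mean 95 %-energy
spectral bandwidth within a tolerance (default 20 % for the standalone
check); `sonify` enforces this unless disabled. EEG features reach the
encoder through a convolution-style front projection: a seeded linear map
to the envelope length with a short smoothing kernel and softplus output,
optionally ridge-fitted against paired training envelopes. Feeding the
rank-1 canonical representation X̃ α̂ α̂ᵀ instead of the full projected
features removes off-direction variance, and the decoded envelopes are
measurably smoother (smaller mean absolute first difference); feeding the
fitted front projection with the full features makes the generated
envelopes cluster by affective label. One shared model is trained for the
label set; labels act through the inputs, and per-label models can be
trained on label subsets if conditioning is wanted.

## Synthetic studies and what they show

`datasets` plants three kinds of ground truth:

- **Phase coupling:** listed channel pairs share a 10 Hz sinusoid with
  random per-trial phase and a fixed quarter-cycle lag whenever the trial
  carries the listed label — PLV of the pair is analytically 1 in the
  noiseless limit. A per-label channel-mixing option plants
  label-dependent amplitude covariance visible to GFC but not PLV.
- **Label-templated audio:** each quadrant has a distinct attack/decay
  envelope and fundamental, with multiplicative jitter.
- **Coupled feature pairs:** a shared unit-variance latent enters one
  column of X directly and one column of Y as ρz + √(1−ρ²)e, so the
  population first canonical correlation is exactly ρ; disjoint columns
  carry per-label mean shifts. With `label_corr > 0` the latent is a
  normalized noise/label mixture — the affective state drives both
  modalities — which leaves ρ unchanged but lets the supervised step
  retain the coupled columns.

Study sizes used by the tests and the acceptance script were fixed as
part of the study design: canonical recovery at n = 500, P = Q = 10;
alignment calibration at n = 96 with a 50/50 split and 500 permutations;
relevance and two-step comparisons at n = 60–100 trials with label
separation 2.0–2.5; electrode recovery on 40-trial, 8-channel studies.
The electrode-recovery study uses a *two-label* (high/low arousal)
contrast: a single coupled pair carries exactly one label bit, so a
four-class target would force the weighting to recruit noise features and
the design would confound the estimator with an unidentifiable target.
LOSO studies share one label geometry across subjects (`pattern_seed`)
with independent per-subject noise — pooled training is meaningless
otherwise.

The generators emulate label-dependent coupling statistics, not real EEG:
no 1/f spectrum, no eye-blink/line artifacts, no volume conduction, no
nonstationarity, and audio is envelope-templated harmonics rather than
music. Passing tests therefore demonstrate that the estimators recover
the structures they target at realistic sizes and are calibrated under
their nulls — not that any particular r² will be attained on recorded
data.

## Numerical and degenerate-input conventions

Zero-variance feature columns standardize to zero, not NaN. An all-zero
signal has no phase and raises. A zero-norm centered kernel yields
alignment 0 with a warning; a zero weighting matrix yields uniform
relevance with a warning. Rank-deficient covariances with reg = 0 raise
with guidance to add regularization. Quantizer ties break to the lowest
codebook index; the canonical sign convention and the PCA sign fix
(largest-magnitude loading positive) make every reported vector
reproducible. All stochastic stages take explicit integer seeds and are
bit-reproducible, single-threaded.

## Limitations

The CKA ascent is non-convex; different seeds can reach different local
optima (the best-seen iterate is returned, and determinism holds per
seed). Only the first canonical pair is computed. The silhouette/scatter
composition of γ is reported as defined, with the caveat above. The
autoencoder is deliberately small — a sonification demonstrator for
envelopes, not a music synthesizer — and the front projection is a single
linear layer, so generated audio is low-level envelope content modulating
a fixed carrier.
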