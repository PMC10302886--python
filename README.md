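# lcalign

Labeled correlation alignment between EEG responses and the auditory
stimuli that elicited them, with VQ-VAE sonification of the selected
neural features.

## The problem

In affective music-listening experiments, participants hear short musical
excerpts labeled by arousal–valence quadrant (HAPV, HANV, LANV, LAPV) while
multichannel EEG is recorded. Two questions follow: *which* neural features
covary with the acoustic content of the stimuli, and can those features be
turned back into sound (sonification)? Plain canonical correlation between
EEG and audio features couples the modalities but ignores the emotion
labels, and EEG's poor signal-to-noise ratio plus heavy inter-subject
variability makes that single-step coupling weak.

`lcalign` implements a two-step **labeled correlation alignment (LCA)**:

1. **Supervised selection.** For each modality Ξ ∈ {X (EEG), Y (audio)},
   learn a linear weighting W_Ξ maximizing the centered kernel alignment

   ρ(W) = ⟨K̄_Ξ(W), K̄_Λ⟩_F / (‖K̄_Ξ(W)‖_F ‖K̄_Λ‖_F),

   where κ_Ξ(ξ, ξ′) = exp(−‖(ξ−ξ′)ᵀW‖²/2) is a Gaussian kernel on weighted
   features, κ_Λ(λ, λ′) = δ(λ, λ′) is the delta kernel on the labels, and
   K̄ = H K H is the double-centered kernel. Row norms of W give a
   per-feature relevance map that back-projects onto electrodes.
2. **Canonical correlation.** Fit the first canonical pair (α_X, α_Y) of
   the weighted features X̃ = XW_X, Ỹ = YW_Y, maximizing
   α_Xᵀ Σ_X̃Ỹ α_Y under unit-variance constraints, with ridge-regularized
   covariances. The canonical correlation r (reported as r²) measures the
   stimulus–response coupling.

EEG features are per-trial functional connectivity matrices — **phase
locking value** (PLV), |E exp(j(φ_c − φ_c′))|, and **Gaussian functional
connectivity** (GFC), exp(−‖x_c − x_c′‖²/2σ²) — computed on Hann-tapered
50 %-overlap windows of band-limited epochs and vectorized
(N_FC = N_φ(N_φ−1)/2 per window, band, and measure). Audio features are 20
windowed music descriptors reduced per window to their first principal
component, plus samples of the cube-root-compressed 64 Hz amplitude
envelope. Partition quality of the coupled representation under the labels
is scored by a silhouette-style statistic γ, and confidence comes from
leave-one-subject-out cross-validation. A compact vector-quantized
variational autoencoder trained on acoustic envelopes decodes
LCA-selected EEG features into new envelopes.

Everything is testable without any recording: the `datasets` module plants
phase coupling, label structure, and an exact population canonical
correlation into synthetic studies.

## Worked example

```python
import numpy as np
from lcalign import CouplingSpec, LabeledCorrelationAlignment, WindowGrid
from lcalign.datasets import gen_eeg_trials, gen_audio_trials
from lcalign.connectivity import extract_fc_features
from lcalign.audio import assemble_audio_features

spec = CouplingSpec(
    n_channels=8, n_trials_per_subject=40,
    labels=("HAPV", "LAPV"),
    coupled_pairs=[(2, 5, "HAPV")],   # CH02-CH05 phase-locked under high arousal
    seed=0,
)
eeg = gen_eeg_trials(spec)[0]
stimuli = gen_audio_trials(eeg.labels, fs=8000.0, seed=0, trial_length=12.0)

grid = WindowGrid(tau=6.0)            # 3 Hann windows, 50% overlap
X = extract_fc_features(eeg, grid)    # PLV + GFC, 28 pairs x 3 windows x 2
Y = assemble_audio_features(stimuli, grid, n_phi=eeg.n_channels, fs=8000.0)

model = LabeledCorrelationAlignment.from_features(X, Y, eeg.labels, d=8)
res = model.fit(seed=0)
print(res.summary())
rel = res.relevance_x.per_electrode
print("top electrodes:", sorted(rel, key=rel.get, reverse=True)[:3])
```

prints

```
Labeled Correlation Alignment
==============================================
trials:               40
EEG features (P):     168
audio features (Q):   81
mode:                 two-step (CKA + CCA)
CKA alignment (EEG):  1.0000
CKA alignment (audio):1.0000
canonical r:          0.9994
canonical r^2:        0.9988
gamma (partition):    0.9875
==============================================
top electrodes: ['CH05', 'CH02', 'CH06']
```

The planted coupled pair (CH02, CH05) tops the electrode relevance map.
The in-sample r² of 0.999 reflects 168 features fitted on 40 trials —
generalization is what `lcalign.evaluation.loso_correlation` measures
(held-out r² ≈ 0.67 on the synthetic multi-subject study the acceptance
script runs), and the null calibration of both r and the alignment is
checked by permutation tests on held-out splits.

A CLI mirrors the library: `lcalign simulate | extract-eeg | extract-audio
| align | evaluate | train-vae | sonify` (see `lcalign --help`).

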