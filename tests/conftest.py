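import numpy as np
import pytest

from lcalign.datasets import CouplingSpec, gen_coupled_features, gen_eeg_trials, label_envelope_template


@pytest.fixture(scope="session")
def coupled_features():
    """Labeled feature pair with planted rho=0.7 and clear label shifts."""
    return gen_coupled_features(100, 12, 12, rho=0.7, label_sep=2.5, seed=0)


@pytest.fixture(scope="session")
def planted_eeg():
    """Two-label EEG study with one phase-coupled pair (CH02, CH05)."""
    spec = CouplingSpec(
        n_channels=8,
        n_trials_per_subject=40,
        labels=("HAPV", "LAPV"),
        coupled_pairs=[(2, 5, "HAPV")],
        osc_amp=1.5,
        seed=0,
    )
    return gen_eeg_trials(spec)[0]


@pytest.fixture(scope="session")
def envelope_bank():
    """Label-templated envelope set (48 x 192) with mild amplitude jitter."""
    rng = np.random.default_rng(3)
    labels = [i % 4 for i in range(48)]
    E = np.vstack(
        [label_envelope_template(l, 192) * (1 + 0.05 * rng.standard_normal()) for l in labels]
    )
    return E, labels
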