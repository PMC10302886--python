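"""Quantizer, loss accounting, training contracts, transfer check, sonification."""

import numpy as np
import pytest

from lcalign.datasets import gen_coupled_features
from lcalign.evaluation import clustering_gamma
from lcalign.lca import LabeledCorrelationAlignment
from lcalign.vqvae import (
    Codebook,
    EegFrontProjection,
    VqVaeConfig,
    check_transfer_conditions,
    quantize,
    sonify,
    train_vqvae,
    vqvae_loss,
)


class TestQuantize:
    def test_exact_match_has_zero_error(self):
        cb = Codebook(np.arange(12.0).reshape(4, 3))
        idx, q = quantize(cb.entries[3], cb)
        assert idx == 3
        np.testing.assert_array_equal(q, cb.entries[3])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        cb = Codebook(rng.standard_normal((8, 4)))
        h = rng.standard_normal((10, 4))
        _, q1 = quantize(h, cb)
        _, q2 = quantize(q1, cb)
        np.testing.assert_array_equal(q1, q2)

    def test_nearest_neighbor_1d(self):
        cb = Codebook(np.array([[0.0], [1.0]]))
        idx, q = quantize(np.array([0.4]), cb)
        assert idx == 0 and q[0] == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            quantize(np.zeros(3), Codebook(np.zeros((4, 2))))


class TestLoss:
    def test_scalar_worked_example(self):
        # input 1, recon 0, latent 2, quantized 0, beta 0.5:
        # 1^2 + 2^2 + 0.5*2^2 = 1 + 4 + 2 = 7
        total, recon, code, commit = vqvae_loss(
            np.array([1.0]), np.array([0.0]), np.array([2.0]), np.array([0.0]), 0.5
        )
        assert (total, recon, code, commit) == (7.0, 1.0, 4.0, 2.0)

    def test_perfect_reconstruction_zero_total(self):
        x = np.ones((2, 4))
        h = np.ones((2, 3))
        assert vqvae_loss(x, x, h, h, 0.25)[0] == 0.0

    def test_beta_zero_kills_commitment(self):
        x = np.zeros(4)
        total, _, code, commit = vqvae_loss(x, x, np.ones(2), np.zeros(2), 0.0)
        assert commit == 0.0 and total == code

    def test_term_accounting(self):
        rng = np.random.default_rng(1)
        args = [rng.standard_normal(6) for _ in range(4)]
        total, recon, code, commit = vqvae_loss(*args, beta=0.7)
        assert total == pytest.approx(recon + code + commit, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            vqvae_loss(np.zeros(3), np.zeros(4), np.zeros(2), np.zeros(2), 0.5)


class TestTraining:
    def test_constant_envelopes_reconstructed(self):
        X = np.full((16, 192), 0.7)
        m = train_vqvae(X, VqVaeConfig(epochs=200, seed=0))
        rec = m.reconstruct(X)
        rel = np.mean((rec - X) ** 2) / np.mean(X**2)
        assert rel < 1e-3

    def test_loss_decreases(self, envelope_bank):
        E, _ = envelope_bank
        m = train_vqvae(E, VqVaeConfig(epochs=150, seed=0))
        assert m.loss_history[-1][0] < m.loss_history[0][0]

    def test_seed_determinism(self, envelope_bank):
        E, _ = envelope_bank
        a = train_vqvae(E, VqVaeConfig(epochs=40, seed=2))
        b = train_vqvae(E, VqVaeConfig(epochs=40, seed=2))
        assert a.loss_history[-1] == b.loss_history[-1]
        np.testing.assert_array_equal(a.codebook.entries, b.codebook.entries)

    def test_codebook_stays_finite(self, envelope_bank):
        E, _ = envelope_bank
        m = train_vqvae(E, VqVaeConfig(epochs=100, seed=1))
        assert np.all(np.isfinite(m.codebook.entries))

    def test_too_few_envelopes_rejected(self):
        with pytest.raises(ValueError):
            train_vqvae(np.zeros((4, 64)), VqVaeConfig(epochs=1))

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            VqVaeConfig(beta=1.5)


class TestTransferCheck:
    def test_identical_sets_pass(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 128))
        rep = check_transfer_conditions(X, X)
        assert rep.passed and rep.bandwidth_ok and rep.dims_ok

    def test_bandwidth_mismatch_fails(self):
        t = np.arange(256) / 64.0
        slow = np.sin(2 * np.pi * 2 * t)[None, :]
        fast = np.sin(2 * np.pi * 24 * t)[None, :]
        rep = check_transfer_conditions(slow, fast, tol=0.2)
        assert not rep.passed and not rep.bandwidth_ok and rep.dims_ok

    def test_dimension_mismatch_flagged(self):
        t = np.arange(256) / 64.0
        x = np.sin(2 * np.pi * 4 * t)
        rep = check_transfer_conditions(x[None, :], x[None, :128], tol=1.0)
        assert not rep.passed and not rep.dims_ok


class TestFrontProjection:
    def test_output_length_and_determinism(self):
        front = EegFrontProjection(10, 96, seed=0)
        x = np.random.default_rng(1).standard_normal((3, 10))
        out = front(x)
        assert out.shape == (3, 96)
        np.testing.assert_array_equal(out, EegFrontProjection(10, 96, seed=0)(x))

    def test_zero_input_gives_bias_output(self):
        front = EegFrontProjection(6, 64, seed=1)
        out1 = front(np.zeros((1, 6)))
        out2 = front(np.zeros((1, 6)))
        np.testing.assert_array_equal(out1, out2)
        assert np.all(out1 >= 0)

    def test_identical_rows_identical_outputs(self):
        front = EegFrontProjection(5, 64, seed=2)
        x = np.random.default_rng(0).standard_normal(5)
        out = front(np.vstack([x, x]))
        np.testing.assert_array_equal(out[0], out[1])


class TestSonify:
    def test_deterministic_outputs(self, envelope_bank):
        E, _ = envelope_bank
        m = train_vqvae(E, VqVaeConfig(epochs=60, seed=0))
        rows = EegFrontProjection(8, m.input_length, seed=0)(
            np.random.default_rng(2).standard_normal((4, 8))
        )
        np.testing.assert_array_equal(
            sonify(m, rows, check=False), sonify(m, rows, check=False)
        )

    def test_outputs_nonnegative(self, envelope_bank):
        E, _ = envelope_bank
        m = train_vqvae(E, VqVaeConfig(epochs=60, seed=0))
        rows = EegFrontProjection(8, m.input_length, seed=0)(
            np.random.default_rng(3).standard_normal((4, 8))
        )
        assert np.all(sonify(m, rows, check=False) >= 0)

    def test_wrong_length_rejected(self, envelope_bank):
        E, _ = envelope_bank
        m = train_vqvae(E, VqVaeConfig(epochs=10, seed=0))
        with pytest.raises(ValueError):
            sonify(m, np.zeros((2, m.input_length + 5)), check=False)

    def test_projected_features_give_smoother_output(self, envelope_bank):
        E, _ = envelope_bank
        wins = 0
        for s in range(5):
            cf = gen_coupled_features(64, 16, 12, rho=0.7, label_sep=2.5, seed=s)
            res = LabeledCorrelationAlignment(cf.X, cf.Y, cf.labels, d=4).fit(seed=s)
            m = train_vqvae(E, VqVaeConfig(epochs=120, seed=s))
            front = EegFrontProjection(res.X_proj.shape[1], m.input_length, seed=s)
            d_raw = np.mean(np.abs(np.diff(sonify(m, front(res.X_proj), check=False), axis=1)))
            d_sel = np.mean(
                np.abs(np.diff(sonify(m, front(res.rank_one_eeg()), check=False), axis=1))
            )
            wins += d_sel <= d_raw
        assert wins >= 4

    def test_generated_envelopes_cluster_by_label(self, envelope_bank):
        # end-to-end: labels drive EEG features -> front projection fitted on
        # paired envelopes -> generations separate by label vs permutation null
        from lcalign.datasets import label_envelope_template

        rng = np.random.default_rng(7)
        cf = gen_coupled_features(48, 16, 12, rho=0.7, label_sep=2.5, seed=1)
        lab_idx = {l: i for i, l in enumerate(sorted(set(cf.labels)))}
        E = np.vstack(
            [
                label_envelope_template(lab_idx[l], 192) * (1 + 0.05 * rng.standard_normal())
                for l in cf.labels
            ]
        )
        m = train_vqvae(E, VqVaeConfig(epochs=200, seed=1))
        res = LabeledCorrelationAlignment(cf.X, cf.Y, cf.labels, d=4).fit(seed=1)
        front = EegFrontProjection(res.X_proj.shape[1], m.input_length, seed=1)
        front.fit(res.X_proj, E[:, : m.input_length])
        out = sonify(m, front(res.X_proj), check=False)
        g_true = clustering_gamma(out, cf.labels, variant="silhouette").gamma
        nulls = [
            clustering_gamma(out, list(rng.permutation(cf.labels)), variant="silhouette").gamma
            for _ in range(200)
        ]
        assert np.mean(np.asarray(nulls) >= g_true) < 0.05
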