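"""Supervised CKA fitting, CCA, relevance back-projection, and the model object."""

import numpy as np
import pytest

from lcalign.connectivity import FeatureDescriptor, extract_fc_features
from lcalign.datasets import gen_coupled_features
from lcalign.kernels import center_kernel, delta_kernel
from lcalign.lca import (
    LabeledCorrelationAlignment,
    _alignment_and_grad,
    alignment_holdout_test,
    electrode_relevance,
    feature_relevance,
    fit_cca,
    fit_cka,
)
from lcalign.preprocess import WindowGrid


class TestCkaGradient:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((15, 4))
        L_c = center_kernel(delta_kernel([i % 3 for i in range(15)])).values
        L_norm = np.linalg.norm(L_c)
        W = 0.4 * rng.standard_normal((4, 2))
        _, grad = _alignment_and_grad(X, W, L_c, L_norm)
        eps = 1e-6
        for i, j in [(0, 0), (2, 1), (3, 0)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[i, j] += eps
            Wm[i, j] -= eps
            num = (
                _alignment_and_grad(X, Wp, L_c, L_norm)[0]
                - _alignment_and_grad(X, Wm, L_c, L_norm)[0]
            ) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, abs=1e-7)


class TestFitCka:
    def test_alignment_improves_from_init(self, coupled_features):
        cf = coupled_features
        proj = fit_cka(cf.X, cf.labels, d=4, seed=0)
        assert proj.alignment >= proj.alignment_trace[0]
        assert proj.alignment > 0.3

    def test_trace_monotone_over_accepted_steps(self, coupled_features):
        cf = coupled_features
        proj = fit_cka(cf.X, cf.labels, d=4, seed=1)
        diffs = np.diff(proj.alignment_trace)
        assert np.all(diffs >= -1e-12)

    def test_deterministic_under_seed(self, coupled_features):
        cf = coupled_features
        a = fit_cka(cf.X, cf.labels, d=4, seed=5)
        b = fit_cka(cf.X, cf.labels, d=4, seed=5)
        np.testing.assert_array_equal(a.W, b.W)
        assert a.alignment_trace == b.alignment_trace

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError):
            fit_cka(X, ["same"] * 10)

    def test_holdout_alignment_calibrated_under_null(self):
        # label-independent features: held-out alignment must sit inside
        # its permutation band (exchangeability)
        hits = 0
        for s in range(10):
            cf = gen_coupled_features(96, 12, 8, rho=0.0, label_sep=0.0, seed=s)
            rng = np.random.default_rng(500 + s)
            labs = list(cf.labels)
            rng.shuffle(labs)
            obs, nulls = alignment_holdout_test(cf.X, labs, n_perm=200, seed=s, d=4)
            hits += obs <= np.quantile(nulls, 0.95)
        assert hits >= 9

    def test_holdout_alignment_detects_informative_labels(self):
        cf = gen_coupled_features(96, 12, 8, rho=0.0, label_sep=2.5, seed=0)
        obs, nulls = alignment_holdout_test(cf.X, cf.labels, n_perm=200, seed=0, d=4)
        assert obs > np.quantile(nulls, 0.95)


class TestRelevance:
    def test_one_hot_for_single_nonzero_row(self):
        from lcalign.lca import CkaProjection, _Scaler

        W = np.zeros((5, 3))
        W[2] = [1.0, 2.0, 2.0]
        proj = CkaProjection(W, [0.5], 0, _Scaler(np.zeros(5), np.ones(5)))
        rel = feature_relevance(proj)
        np.testing.assert_allclose(rel, [0, 0, 1, 0, 0])

    def test_uniform_for_equal_norm_rows(self):
        from lcalign.lca import CkaProjection, _Scaler

        W = np.eye(4)
        proj = CkaProjection(W, [0.5], 0, _Scaler(np.zeros(4), np.ones(4)))
        np.testing.assert_allclose(feature_relevance(proj), 0.25)

    def test_zero_weights_warn_uniform(self):
        from lcalign.lca import CkaProjection, _Scaler

        proj = CkaProjection(np.zeros((3, 2)), [0.0], 0, _Scaler(np.zeros(3), np.ones(3)))
        with pytest.warns(UserWarning):
            np.testing.assert_allclose(feature_relevance(proj), 1 / 3)

    def test_planted_columns_outrank_noise(self):
        wins = 0
        for s in range(10):
            cf = gen_coupled_features(60, 12, 8, rho=0.0, label_sep=2.0, seed=s)
            rel = feature_relevance(fit_cka(cf.X, cf.labels, d=4, seed=s))
            planted = np.mean(rel[list(cf.label_cols)])
            noise = np.mean(np.delete(rel, list(cf.label_cols) + [cf.shared_x_col]))
            wins += planted > noise
        assert wins >= 9


class TestElectrodeRelevance:
    def _index(self, pairs):
        return [FeatureDescriptor("plv", "broadband", 0, p) for p in pairs]

    def test_concentrated_pair_tops_ranking(self):
        pairs = [("C3", "C4"), ("C3", "F3"), ("C4", "F3"), ("F3", "F4")]
        rel = np.array([0.9, 0.04, 0.03, 0.03])
        er = electrode_relevance(rel, self._index(pairs))
        top2 = sorted(er, key=er.get, reverse=True)[:2]
        assert set(top2) == {"C3", "C4"}
        assert max(er.values()) == 1.0

    def test_uniform_relevance_uniform_electrodes(self):
        # complete graph on 4 electrodes: every electrode in 3 pairs
        from itertools import combinations

        pairs = list(combinations(["A", "B", "C", "D"], 2))
        er = electrode_relevance(np.full(6, 1 / 6), self._index(pairs))
        assert np.allclose(list(er.values()), 1.0)

    def test_planted_coupling_recovered_through_pipeline(self, planted_eeg):
        fx = extract_fc_features(planted_eeg, WindowGrid(tau=12.0))
        proj = fit_cka(fx.values, planted_eeg.labels, d=8, seed=0)
        er = electrode_relevance(feature_relevance(proj), fx.feature_index)
        top2 = sorted(er, key=er.get, reverse=True)[:2]
        assert set(top2) == {"CH02", "CH05"}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            electrode_relevance(np.ones(3), self._index([("A", "B")]))


class TestCca:
    def test_y_equals_x_gives_unit_r(self):
        X = np.random.default_rng(0).standard_normal((50, 5))
        assert fit_cca(X, X, regularization=0.0).r == pytest.approx(1.0, abs=1e-6)

    def test_1d_equals_abs_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((80, 1))
        y = -0.6 * x + 0.4 * rng.standard_normal((80, 1))
        expected = abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1])
        assert fit_cca(x, y, regularization=0.0).r == pytest.approx(expected, abs=1e-9)

    def test_unit_variance_constraints(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 6))
        Y = rng.standard_normal((100, 4))
        res = fit_cca(X, Y, regularization=0.0)
        u, v = res.scores(
            (X - X.mean(0)) / X.std(0), (Y - Y.mean(0)) / Y.std(0)
        )
        assert np.var(u, ddof=1) == pytest.approx(1.0, abs=1e-6)
        assert np.var(v, ddof=1) == pytest.approx(1.0, abs=1e-6)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        cf = gen_coupled_features(200, 6, 6, rho=0.8, seed=3)
        A = rng.standard_normal((6, 6)) + 3 * np.eye(6)
        r1 = fit_cca(cf.X, cf.Y, regularization=0.0, standardize=False).r
        r2 = fit_cca(cf.X @ A, cf.Y, regularization=0.0, standardize=False).r
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_sign_convention(self):
        cf = gen_coupled_features(100, 5, 5, rho=0.9, seed=4)
        res = fit_cca(cf.X, cf.Y)
        nz = np.flatnonzero(res.alpha_x)
        assert res.alpha_x[nz[0]] > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_cca(np.zeros((2, 3)), np.zeros((2, 3)))


class TestModelObject:
    def test_fit_returns_results_with_summary(self, coupled_features):
        cf = coupled_features
        res = LabeledCorrelationAlignment(cf.X, cf.Y, cf.labels, d=4).fit(seed=0)
        text = res.summary()
        assert "canonical r" in text and "two-step" in text
        assert 0 <= res.r <= 1

    def test_two_step_beats_single_step_gamma_usually(self):
        wins = 0
        for s in range(10):
            cf = gen_coupled_features(100, 12, 12, rho=0.7, label_sep=2.5, seed=s)
            m = LabeledCorrelationAlignment(cf.X, cf.Y, cf.labels, d=4)
            wins += m.fit(seed=s).gamma().gamma >= m.fit(single_step=True, seed=s).gamma().gamma
        assert wins >= 8

    def test_fixed_seed_bit_identical(self, coupled_features):
        cf = coupled_features
        m = LabeledCorrelationAlignment(cf.X, cf.Y, cf.labels, d=4)
        r1 = m.fit(seed=3)
        r2 = m.fit(seed=3)
        np.testing.assert_array_equal(r1.cca.alpha_x, r2.cca.alpha_x)
        assert r1.r == r2.r

    def test_decoupled_modalities_r_within_refit_null(self):
        # the fitted r is an optimized statistic, so the permutation null
        # must refit the CCA on each shuffled trial correspondence
        rng = np.random.default_rng(0)
        cf = gen_coupled_features(80, 8, 8, rho=0.0, label_sep=2.0, seed=9)
        res = LabeledCorrelationAlignment(cf.X, cf.Y, cf.labels, d=4).fit(seed=0)
        nulls = [
            fit_cca(res.X_proj, res.Y_proj[rng.permutation(len(res.Y_proj))]).r
            for _ in range(200)
        ]
        assert res.r <= np.quantile(nulls, 0.99)

    def test_rank_one_eeg_is_rank_one(self, coupled_features):
        cf = coupled_features
        res = LabeledCorrelationAlignment(cf.X, cf.Y, cf.labels, d=4).fit(seed=0)
        R = res.rank_one_eeg()
        assert np.linalg.matrix_rank(R, tol=1e-8) == 1

    def test_label_mismatch_rejected(self, coupled_features):
        cf = coupled_features
        with pytest.raises(ValueError):
            LabeledCorrelationAlignment(cf.X, cf.Y, cf.labels[:-1])
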