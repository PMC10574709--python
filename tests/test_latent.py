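"""PLS-DA/OPLS-DA, VIP, S-line, cross-validation and permutation testing."""

import warnings

import numpy as np
import pytest

from nmrpattern import (DummyY, cross_validate, fit_oplsda, fit_plsda,
                        permutation_test, predict, predict_class, s_line,
                        vip_scores)
from nmrpattern.latent import model_from_json, model_to_json


def _center(X):
    return X - X.mean(axis=0)


class TestPLS:
    def test_first_component_matches_closed_form(self, rng):
        """Univariate y, one component: the weight vector is X'y normalized
        and predictions follow the closed-form PLS1 component."""
        X = _center(rng.normal(size=(30, 6)))
        y = _center(rng.normal(size=(30, 1)))
        m = fit_plsda(X, y, n_components=1)
        w_expected = (X.T @ y).ravel()
        w_expected /= np.linalg.norm(w_expected)
        assert abs(abs(w_expected @ m.weights[:, 0]) - 1.0) < 1e-10
        t = X @ w_expected
        c = float(y.ravel() @ t / (t @ t))
        np.testing.assert_allclose(predict(m, X).ravel(), t * c + m.y_mean, atol=1e-10)

    def test_matches_sklearn_first_component(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = _center(rng.normal(size=(25, 8)))
        y = _center(rng.normal(size=(25, 1)))
        ours = predict(fit_plsda(X, y, 1), X).ravel()
        theirs = PLSRegression(n_components=1, scale=False).fit(X, y).predict(X).ravel()
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_perfectly_predictable_target(self, rng):
        # orthogonal columns so the first weight points exactly along y
        X, _ = np.linalg.qr(_center(rng.normal(size=(40, 5))))
        X = _center(X)
        y = X[:, [2]].copy()
        m = fit_plsda(X, y, n_components=1)
        assert m.r2y_per_component[0] >= 0.99

    def test_full_rank_recovers_x(self, rng):
        X = _center(rng.normal(size=(20, 4)))
        Y = DummyY.from_labels(["a"] * 10 + ["b"] * 10)
        m = fit_plsda(X, Y, n_components=4)
        assert m.r2x_cumulative >= 0.999

    def test_scores_orthogonal_and_coef_consistent(self, rng):
        X = _center(rng.normal(size=(30, 10)))
        Y = DummyY.from_labels(["a", "b", "c"] * 10)
        m = fit_plsda(X, Y, n_components=3)
        G = m.x_scores.T @ m.x_scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        # B reproduces the score-space prediction T C' on training X
        np.testing.assert_allclose(X @ m.coef, m.x_scores @ m.y_loadings.T, atol=1e-8)

    def test_single_class_rejected(self, rng):
        X = _center(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="single-class"):
            fit_plsda(X, DummyY.from_labels(["a"] * 10), 1)

    def test_json_round_trip(self, tmp_path, rng):
        X = _center(rng.normal(size=(20, 6)))
        Y = DummyY.from_labels(["a", "b"] * 10)
        m = fit_plsda(X, Y, 2)
        model_to_json(m, tmp_path / "m.json")
        back = model_from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.coef, m.coef)
        assert back.class_order == m.class_order


class TestVIP:
    def test_symmetric_weights_give_unit_vip(self):
        # single component with all |w_j| equal -> every VIP is exactly 1
        y = np.repeat([0.0, 1.0], 6)[:, None]
        yc = _center(y)
        X = yc @ np.array([[1.0, 1.0, -1.0, -1.0]])
        m = fit_plsda(X, y, 1)
        np.testing.assert_allclose(np.abs(m.weights[:, 0]), 0.5, atol=1e-12)
        np.testing.assert_allclose(vip_scores(m).vip, 1.0, atol=1e-10)

    def test_normalization_identity(self, small_scaled):
        X, _, Y = small_scaled
        for a in (1, 2, 3):
            m = fit_plsda(X, Y, a)
            v = vip_scores(m).vip
            assert np.sum(v**2) == pytest.approx(X.shape[1], abs=1e-6)

    def test_matches_brute_force_oracle(self, rng):
        """VIP equals a direct transcription of the formula written
        independently of the model code."""
        X = _center(rng.normal(size=(20, 6)))
        Y = DummyY.from_labels(["a", "b"] * 10)
        m = fit_plsda(X, Y, 2)
        p = X.shape[1]
        ssy = m.ssy_explained
        vip_direct = np.empty(p)
        for j in range(p):
            acc = 0.0
            for a in range(m.n_components):
                w_a = m.weights[:, a]
                acc += ssy[a] * (w_a[j] / np.linalg.norm(w_a)) ** 2
            vip_direct[j] = np.sqrt(p * acc / ssy.sum())
        np.testing.assert_allclose(vip_scores(m).vip, vip_direct, atol=1e-10)


class TestOPLS:
    def test_zero_orthogonal_degenerates_to_pls(self, small_scaled):
        X, _, Y = small_scaled
        om = fit_oplsda(X, Y, n_predictive=2, n_orthogonal=0)
        pm = fit_plsda(X, Y, n_components=2)
        np.testing.assert_allclose(om.predictive_scores, pm.x_scores, atol=1e-8)

    def test_predictive_orthogonal_scores_orthogonal(self, small_scaled):
        X, _, Y = small_scaled
        om = fit_oplsda(X, Y, n_predictive=2, n_orthogonal=2)
        cross = om.predictive_scores.T @ om.orthogonal_scores
        np.testing.assert_allclose(cross, 0.0, atol=1e-7)

    def test_orthogonal_filtering_raises_r2y(self, rng):
        """y-correlated direction plus strong y-orthogonal structure: OPLS
        concentrates the class signal in its single predictive component."""
        n = 60
        y = np.repeat([0.0, 1.0], n // 2)[:, None]
        yc = _center(y)
        rng_local = np.random.default_rng(0)
        ortho = _center(rng_local.normal(size=(n, 1)))
        ortho -= yc * (yc.T @ ortho / (yc.T @ yc)).item()
        d_sig = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        d_orth = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 0.0])
        X = yc @ d_sig[None, :] + 3.0 * ortho @ d_orth[None, :]
        X += 0.05 * rng_local.normal(size=X.shape)
        X = _center(X)
        r2y_pls = fit_plsda(X, y, 1).r2y_cumulative
        om = fit_oplsda(X, y, n_predictive=1, n_orthogonal=1)
        assert om.r2y_cumulative >= r2y_pls - 1e-12
        assert om.r2x_predictive + om.r2x_orthogonal <= 1.0 + 1e-9

    def test_rank_bound_enforced(self, rng):
        X = _center(rng.normal(size=(8, 4)))
        y = _center(np.arange(8.0)[:, None])
        with pytest.raises(ValueError, match="rank"):
            fit_oplsda(X, y, n_predictive=3, n_orthogonal=5)


class TestSLine:
    def test_perfectly_correlated_column(self, rng):
        n = 40
        y = np.repeat([0.0, 1.0], n // 2)[:, None]
        X = _center(rng.normal(size=(n, 5)))
        om = fit_oplsda(X, y, 1, 0)
        X2 = np.column_stack([X, om.predictive_scores[:, 0]])
        om2 = fit_oplsda(X2, y, 1, 0)
        sl = s_line(om2, np.column_stack([X, om2.predictive_scores[:, 0]]))
        assert sl.correlation[-1] == pytest.approx(1.0, abs=1e-8)

    def test_independent_noise_weak_correlation(self):
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            n = 60
            y = np.repeat([0.0, 1.0], n // 2)[:, None]
            signal = _center(y) @ np.ones((1, 2))
            noise = _center(rng.normal(size=(n, 6)))
            X = _center(np.column_stack([signal, noise]))
            om = fit_oplsda(X, y, 1, 0)
            sl = s_line(om, X)
            hits.append(np.abs(sl.correlation[2:]).mean())
        assert np.mean(hits) < 0.5

    def test_planted_saponins_dominate_covariance(self, species_table):
        """LF-vs-LJF contrast: the largest |p(cov)| buckets sit in the
        saponin methyl region 0.65-1.80 ppm."""
        from nmrpattern import scale_columns

        binary = ["LF" if lab == "LF" else "LJF" for lab in species_table.labels]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xc, _ = scale_columns(species_table.values, "center")
            om = fit_oplsda(Xc, DummyY.from_labels(binary), 1, 1)
            sl = s_line(om, Xc)
        top = np.argsort(-np.abs(sl.covariance))[:5]
        for j in top:
            lo, hi = species_table.bucket_edges[j]
            assert 0.65 <= lo and hi <= 1.80, f"bucket {j} at [{lo}, {hi}] ppm"

    def test_three_class_model_rejected(self, small_scaled):
        X, _, Y = small_scaled
        om = fit_oplsda(X, Y, 2, 1)
        with pytest.raises(ValueError, match="two-class"):
            s_line(om, X)


class TestCrossValidation:
    def test_separable_cohort_predictive(self, small_scaled):
        X, _, Y = small_scaled
        r2y, q2 = cross_validate(X, Y, n_components=2, folds=7, seed=0)
        assert q2 > 0.5
        assert r2y >= q2

    def test_permuted_labels_not_predictive(self, small_scaled):
        X, _, Y = small_scaled
        rng = np.random.default_rng(1)
        q2s = []
        for _ in range(10):
            perm = rng.permutation(X.shape[0])
            Yp = DummyY(Y.indicators[perm], Y.class_order)
            _, q2 = cross_validate(X, Yp, n_components=2, folds=7, seed=0)
            q2s.append(q2)
        assert np.mean(q2s) < 0.05

    def test_loo_agrees_with_7fold_on_separable_data(self, small_scaled):
        X, _, Y = small_scaled
        _, q2_7 = cross_validate(X, Y, 2, folds=7, seed=0)
        _, q2_loo = cross_validate(X, Y, 2, folds=X.shape[0], seed=0)
        assert q2_7 > 0.5 and q2_loo > 0.5

    def test_opls_cv_runs(self, small_scaled):
        X, _, Y = small_scaled
        r2y, q2 = cross_validate(X, Y, 2, folds=7, seed=0, model_kind="opls",
                                 n_orthogonal=1)
        assert q2 > 0.5


class TestPermutation:
    def test_result_shape_and_reference_point(self, small_scaled):
        X, _, Y = small_scaled
        res = permutation_test(X, Y, n_permutations=10, n_components=2, seed=3)
        assert len(res.correlations) == 11
        assert res.correlations[0] == 1.0
        _, q2 = cross_validate(X, Y, 2, folds=7, seed=3)
        assert res.q2_values[0] == q2  # exact reuse of the CV stream

    def test_single_class_rejected(self, rng):
        X = _center(rng.normal(size=(10, 4)))
        Y = np.ones((10, 1))
        with pytest.raises(ValueError, match="single class"):
            permutation_test(X, Y, n_permutations=5)

    def test_separable_cohort_not_overfitting(self, small_scaled):
        X, _, Y = small_scaled
        res = permutation_test(X, Y, n_permutations=30, n_components=2, seed=5)
        assert res.q2_intercept < 0
        assert res.q2_values[0] > np.quantile(res.q2_values[1:], 0.95)


class TestPrediction:
    def test_training_accuracy_on_separable_cohort(self, small_table, small_scaled):
        X, _, Y = small_scaled
        m = fit_plsda(X, Y, 2)
        labels, yhat = predict_class(m, X)
        assert labels == list(small_table.labels)
        assert np.abs(yhat.sum(axis=1).mean() - 1.0) < 0.2

    def test_class_centroid_classified_home(self, small_scaled):
        X, _, Y = small_scaled
        m = fit_plsda(X, Y, 2)
        for j, lab in enumerate(Y.class_order):
            centroid = X[Y.indicators[:, j] == 1].mean(axis=0)
            pred, _ = predict_class(m, centroid)
            assert pred[0] == lab

    def test_column_mismatch_rejected(self, small_scaled):
        X, _, Y = small_scaled
        m = fit_plsda(X, Y, 2)
        with pytest.raises(ValueError, match="column count"):
            predict(m, X[:, :10])
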