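"""Latent-variable models and classifiers against independent oracles and
their analytic identities."""

import numpy as np
import pandas as pd
import pytest

from salmofuse import chemometrics as cm


def two_class_labels(n):
    return np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))


class TestNipalsPCA:
    def test_rank_one(self, rng):
        X = np.outer(rng.standard_normal(12), rng.standard_normal(5))
        m = cm.nipals_pca(X, 3)
        assert m.n_components == 1
        assert m.r2x == pytest.approx(1.0, abs=1e-9)

    def test_matches_svd_oracle(self, rng):
        X = rng.standard_normal((20, 8))
        m = cm.nipals_pca(X, 4)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for i in range(4):
            sign = np.sign(m.P[:, i] @ Vt[i])
            np.testing.assert_allclose(m.P[:, i], sign * Vt[i], atol=1e-6)
            np.testing.assert_allclose(m.T[:, i], sign * U[:, i] * s[i], atol=1e-6)
            assert m.explained_variance[i] == pytest.approx(
                s[i] ** 2 / (s**2).sum(), abs=1e-9
            )

    def test_scores_orthogonal(self, rng):
        m = cm.nipals_pca(rng.standard_normal((25, 10)), 5)
        G = m.T.T @ m.T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_duplicated_row_changes_centered_model(self, rng):
        """Appending a duplicate row shifts the mean, so loadings of a
        centered model change — centering is part of the fit contract."""
        X = rng.standard_normal((10, 4))
        m1 = cm.nipals_pca(X, 2)
        m2 = cm.nipals_pca(np.vstack([X, X[:1]]), 2)
        assert not np.allclose(np.abs(m1.P), np.abs(m2.P), atol=1e-8)


class TestQ2:
    def test_deterministic(self, rng):
        X = rng.standard_normal((30, 6))
        a = cm.q2_cv(X, 3, folds=7, seed=5)
        b = cm.q2_cv(X, 3, folds=7, seed=5)
        np.testing.assert_array_equal(a[0], b[0])

    def test_strong_single_factor(self, rng):
        t = rng.standard_normal(50)
        X = 3 * np.outer(t, rng.standard_normal(8)) + 0.2 * rng.standard_normal(
            (50, 8)
        )
        _, q2 = cm.q2_cv(X, 1, folds=7, seed=0)
        assert q2 > 0.8

    def test_noise_q2_below_r2x(self, rng):
        X = rng.standard_normal((30, 8))
        _, q2 = cm.q2_cv(X, 2, folds=7, seed=0)
        m = cm.nipals_pca(X, 2)
        assert q2 < m.r2x

    def test_fold_validation(self, rng):
        with pytest.raises(ValueError):
            cm.q2_cv(rng.standard_normal((5, 3)), 1, folds=10)


class TestPLSDA:
    def test_separable_one_dimensional(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        m = cm.plsda_fit(X, y, n_components=1)
        assert (cm.plsda_predict(m, X) == y).all()

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((30, 8))
        y = np.array(["a", "b", "c"] * 10)
        Y = pd.get_dummies(pd.Series(y)).to_numpy(float)
        m = cm.plsda_fit(X, y, n_components=4)
        ref = PLSRegression(n_components=4, scale=False, tol=1e-12,
                            max_iter=2000).fit(X, Y)
        mine = (X - m.mean) @ m.coef + m.y_mean
        np.testing.assert_allclose(mine, ref.predict(X), atol=1e-6)

    def test_variance_bookkeeping(self, rng):
        X = rng.standard_normal((40, 10))
        y = two_class_labels(40)
        m = cm.plsda_fit(X, y, n_components=3, cv_folds=7)
        assert 0 <= m.r2x <= 1 and 0 <= m.r2y <= 1
        assert m.q2 <= m.r2y + 1e-9

    def test_single_class_rejected(self, rng):
        with pytest.raises(cm.DegenerateLabelError):
            cm.plsda_fit(rng.standard_normal((5, 3)), np.array(["a"] * 5))

    def test_sample_order_equivariance(self, rng):
        X = rng.standard_normal((30, 6))
        y = np.array(list("abc") * 10)
        perm = rng.permutation(30)
        m1 = cm.plsda_fit(X, y, 3)
        m2 = cm.plsda_fit(X[perm], y[perm], 3)
        q = rng.standard_normal((5, 6))
        np.testing.assert_array_equal(
            cm.plsda_predict(m1, q), cm.plsda_predict(m2, q)
        )


class TestOPLSDA:
    def test_zero_ortho_equals_one_component_plsda(self, rng):
        X = rng.standard_normal((40, 10))
        y = two_class_labels(40)
        mo = cm.oplsda_fit(X, y, n_ortho=0, n_pred=1)
        mp = cm.plsda_fit(X, y, n_components=1)
        q = rng.standard_normal((8, 10))
        np.testing.assert_array_equal(
            cm.oplsda_predict(mo, q), cm.plsda_predict(mp, q)
        )
        np.testing.assert_allclose(mo.T, mp.T, atol=1e-10)

    def test_orthogonal_filter_removes_planted_factor(self, rng):
        """Adding a strong Y-orthogonal factor leaves the OPLS predictive
        score unchanged."""
        n, p = 60, 12
        X0 = rng.standard_normal((n, p))
        y = two_class_labels(n)
        m1 = cm.plsda_fit(X0, y, 1)
        w, t_ref, p0 = m1.W[:, 0], m1.T[:, 0], m1.P[:, 0]
        yc = (y == "a").astype(float)
        yc -= yc.mean()
        basis = np.column_stack([np.ones(n), yc, t_ref])
        t_orth = rng.standard_normal(n)
        t_orth -= basis @ np.linalg.lstsq(basis, t_orth, rcond=None)[0]
        B = np.column_stack([w, p0])
        v = rng.standard_normal(p)
        v -= B @ np.linalg.lstsq(B, v, rcond=None)[0]
        v /= np.linalg.norm(v)
        Xa = X0 + 5 * np.outer(t_orth, v)
        mo = cm.oplsda_fit(Xa, y, n_ortho=1, n_pred=1)
        mo0 = cm.oplsda_fit(X0, y, n_ortho=1, n_pred=1)
        corr = np.corrcoef(mo.T[:, 0], mo0.T[:, 0])[0, 1]
        assert abs(corr) >= 0.999
        np.testing.assert_allclose(mo.T[:, 0], mo0.T[:, 0], atol=1e-6)

    def test_reconstruction_identity(self, rng):
        X = rng.standard_normal((30, 8))
        y = np.array(list("abcde") * 6)
        m = cm.oplsda_fit(X, y, n_ortho=2)
        Xc = (X - m.mean) / m.scale
        filtered = m._osc_filter(Xc)
        E = filtered - m.T @ m.P.T
        recon = m.T @ m.P.T + m.T_o @ m.P_o.T + E
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_orthogonal_scores_uncorrelated_with_all_class_columns(self, rng):
        X = rng.standard_normal((50, 12))
        y = np.array(list("abcde") * 10)
        m = cm.oplsda_fit(X, y, n_ortho=3)
        Y = pd.get_dummies(pd.Series(y)).to_numpy(float)
        Yc = Y - Y.mean(axis=0)
        for j in range(m.T_o.shape[1]):
            for k in range(Yc.shape[1]):
                r = np.corrcoef(m.T_o[:, j], Yc[:, k])[0, 1]
                assert abs(r) < 1e-8

    def test_adding_ortho_components_never_hurts_training_r2y(self, rng):
        X = rng.standard_normal((40, 15))
        y = two_class_labels(40)
        r2y = [cm.oplsda_fit(X, y, n_ortho=k, n_pred=1).r2y for k in range(4)]
        assert all(b >= a - 1e-9 for a, b in zip(r2y, r2y[1:]))

    def test_rank_exhaustion(self, rng):
        X = np.outer(rng.standard_normal(10), rng.standard_normal(4))
        X += 1e-12 * rng.standard_normal(X.shape)
        y = two_class_labels(10)
        with pytest.raises(cm.RankError):
            cm.oplsda_fit(X, y, n_ortho=5)


class TestSPlot:
    def test_variable_equal_to_score(self, rng):
        X = rng.standard_normal((40, 5))
        y = two_class_labels(40)
        m = cm.plsda_fit(X, y, 1)
        X2 = np.column_stack([X, m.T[:, 0] + m.mean.mean()])
        m2 = cm.plsda_fit(X2, y, 1)
        sp = cm.s_plot(m2, X2)
        # the planted copy of the score correlates almost perfectly
        assert abs(sp.correlation.iloc[-1]) > 0.99

    def test_matches_direct_covariance_oracle(self, rng):
        X = rng.standard_normal((30, 6))
        y = two_class_labels(30)
        m = cm.plsda_fit(X, y, 1)
        sp = cm.s_plot(m, X)
        t = m.T[:, 0]
        Xc = X - m.mean
        for j in range(6):
            assert sp.covariance.iloc[j] == pytest.approx(
                np.cov(t, Xc[:, j])[0, 1], abs=1e-10
            )
            assert sp.correlation.iloc[j] == pytest.approx(
                np.corrcoef(t, Xc[:, j])[0, 1], abs=1e-10
            )

    def test_noise_variable_uncorrelated(self, rng):
        n = 2000
        y = two_class_labels(n)
        signal = 2.0 * (y == "a") - 1.0  # unit-variance class contrast
        X = np.column_stack(
            [signal + 0.1 * rng.standard_normal(n), rng.standard_normal(n)]
        )
        m = cm.plsda_fit(X, y, 1)
        sp = cm.s_plot(m, X)
        assert abs(sp.correlation.iloc[1]) < 3 / np.sqrt(n)

    def test_zero_variance_variable(self, rng):
        X = np.column_stack([rng.standard_normal(20), np.full(20, 3.0)])
        m = cm.plsda_fit(X, two_class_labels(20), 1)
        sp = cm.s_plot(m, X)
        assert sp.correlation.iloc[1] == 0.0

    def test_sign_consistency(self, rng):
        X = rng.standard_normal((50, 10))
        m = cm.plsda_fit(X, two_class_labels(50), 1)
        sp = cm.s_plot(m, X)
        nz = (sp.covariance != 0) & (sp.correlation != 0)
        assert (np.sign(sp.covariance[nz]) == np.sign(sp.correlation[nz])).all()


class TestSelectBiomarkers:
    def _splot(self, corr, cov, contrast):
        idx = [f"v{i}" for i in range(len(corr))]
        return cm.SPlotResult(
            pd.Series(cov, index=idx), pd.Series(corr, index=idx), contrast
        )

    def test_unreachable_threshold_empty(self):
        sp = self._splot([0.9, 0.5], [1.0, 0.2], "c1")
        per, consensus = cm.select_biomarkers([sp], corr_cut=1.01)
        assert per["c1"] == [] and consensus == []

    def test_consensus_logic(self):
        splots = [
            self._splot([0.9, 0.1, 0.8], [1.0, 0.01, 0.9], f"c{i}")
            for i in range(3)
        ]
        per, consensus = cm.select_biomarkers(
            splots, corr_cut=0.5, cov_quantile=0.0, min_contrasts=3
        )
        assert "v0" in consensus and "v2" in consensus
        assert "v1" not in consensus

    def test_planted_markers_recovered(self):
        """One-vs-rest S-plots rank the planted marker bins at the top."""
        from salmofuse import synthetic_data as sd
        from salmofuse.preprocess import tic_normalize

        marker_bins = [100.1, 103.1, 106.1, 109.1, 112.1]
        effects = [
            sd.MarkerEffect(b, {c: 4.0})
            for b, c in zip(marker_bins, sd.CLASS_NAMES)
        ]
        cfg = sd.SimConfig(n_per_class=30, seed=33, lo=100, hi=140,
                           marker_effects=effects)
        block = sd.sample_spectra_block(effects, cfg)
        labels = np.repeat(sd.CLASS_NAMES, 30)
        X = tic_normalize(block).data
        splots = []
        for cls in sd.CLASS_NAMES:
            contrast = np.where(labels == cls, cls, "rest")
            m = cm.oplsda_fit(X, contrast, n_ortho=1, n_pred=1, scale="pareto")
            splots.append(cm.s_plot(m, X, contrast=cls))
        for sp, b in zip(splots, marker_bins):
            top = sp.correlation.abs().idxmax()
            assert top == f"{b:.1f}"


class TestVIP:
    def test_uniform_weights_give_unit_vip(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        y = np.array(["a", "a", "b", "b"])
        m = cm.plsda_fit(X, y, n_components=1)
        np.testing.assert_allclose(cm.vip(m), 1.0, atol=1e-9)

    def test_mean_square_is_one(self, rng):
        X = rng.standard_normal((30, 12))
        y = np.array(list("abc") * 10)
        m = cm.plsda_fit(X, y, 4)
        v = cm.vip(m)
        assert (v**2).mean() == pytest.approx(1.0, abs=1e-9)

    def test_planted_markers_exceed_one(self, rng):
        n = 100
        y = two_class_labels(n)
        signal = (y == "a").astype(float)
        X = rng.standard_normal((n, 20))
        X[:, 0] += 3 * signal
        X[:, 1] -= 3 * signal
        m = cm.plsda_fit(X, y, 2)
        v = cm.vip(m)
        assert v.iloc[0] > 1 and v.iloc[1] > 1
        assert v.iloc[2:].mean() < 1


class TestLDA:
    def test_boundary_is_perpendicular_bisector(self):
        """With an exactly spherical pooled covariance and equal priors the
        decision boundary is the perpendicular bisector of the means."""
        pattern = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        mean_a, mean_b = np.array([0.0, 0.0]), np.array([3.0, 1.0])
        X = np.vstack([pattern + mean_a, pattern + mean_b])
        y = np.array(["a"] * 4 + ["b"] * 4)
        m = cm.lda_fit(X, y)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-2, 5, (50, 2))
        mid = (mean_a + mean_b) / 2
        expect = np.where((pts - mid) @ (mean_b - mean_a) > 0, "b", "a")
        np.testing.assert_array_equal(cm.lda_predict(m, pts), expect)

    def test_singular_covariance_advises_pca_lda(self, rng):
        X = rng.standard_normal((6, 20))  # p > n
        y = two_class_labels(6)
        with pytest.raises(cm.SingularCovarianceError, match="pca_lda"):
            cm.lda_fit(X, y)
        model = cm.pca_lda(X, y, n_pcs=3)
        assert len(cm.pca_lda_predict(model, X)) == 6

    def test_symmetric_confusion_on_symmetric_data(self, rng):
        X = np.vstack(
            [rng.normal(-2, 1, (50, 2)), rng.normal(2, 1, (50, 2))]
        )
        y = np.array(["a"] * 50 + ["b"] * 50)
        m = cm.lda_fit(X, y)
        pred = cm.lda_predict(m, X)
        err_a = ((pred == "b") & (y == "a")).sum()
        err_b = ((pred == "a") & (y == "b")).sum()
        assert abs(err_a - err_b) <= 3


class TestKNN:
    def test_query_equals_training_point(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["a", "b", "c"])
        assert cm.knn_predict(X, y, np.array([[1.0]]), k=1)[0] == "b"

    def test_matches_brute_force_oracle(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.array(["a", "b"] * 20)
        Q = rng.standard_normal((15, 3))
        pred = cm.knn_predict(X, y, Q, k=3)
        for qi, q in enumerate(Q):
            d = np.array([np.sqrt(((q - x) ** 2).sum()) for x in X])
            top = np.argsort(d, kind="stable")[:3]
            votes = pd.Series(y[top]).value_counts()
            assert pred[qi] == votes.idxmax()

    def test_vote_tie_broken_by_mean_distance(self):
        X = np.array([[0.0], [1.0]])
        y = np.array(["a", "b"])
        assert cm.knn_predict(X, y, np.array([[0.4]]), k=2)[0] == "a"
        assert cm.knn_predict(X, y, np.array([[0.6]]), k=2)[0] == "b"
        # equidistant: lowest class index wins
        assert cm.knn_predict(X, y, np.array([[0.5]]), k=2)[0] == "a"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cm.knn_predict(np.empty((0, 2)), np.array([]), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            cm.knn_predict(np.zeros((3, 2)), np.array(["a"] * 3),
                           np.zeros((1, 2)), k=5)


class TestAdapters:
    @pytest.mark.parametrize("maker", [cm.make_random_forest, cm.make_svm])
    def test_external_classifiers_deterministic(self, maker, rng):
        X = rng.standard_normal((60, 5))
        y = np.array(["a", "b", "c"] * 20)
        a = maker(seed=3).fit(X, y).predict(X)
        b = maker(seed=3).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_adapter_does_not_mutate_estimator(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        est = RandomForestClassifier(n_estimators=5, random_state=0)
        ad = cm.SklearnAdapter(est)
        ad.fit(rng.standard_normal((20, 3)), np.array(["a", "b"] * 10))
        assert not hasattr(est, "estimators_")
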