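"""Scaling, PCA, OPLS-DA, cross-validation, VIP and refinement tests.

scikit-learn serves only as an independent comparison oracle (PCA and
single-component PLS1); all assertions target this package's own
implementations.
"""

import numpy as np
import pytest
from scipy import stats

from agrimet.multivariate import (OPLSDA, CvReport, PCAModel, UnitVarianceScaler,
                                  assign_folds, cross_validate, cv_anova,
                                  external_validate, fit_cv_anova,
                                  hotelling_ellipse, refine_by_year,
                                  select_components, vip)

Y_SYSTEM = np.array(([1.0] * 3 + [0.0] * 6) * 2)   # C vs pooled organic
YEARS = np.repeat([2007, 2008], 9)


def lognormal_study(rng, n_feat, affected_frac=0.0, fold=1.0, cv=0.18,
                    y=Y_SYSTEM, year_frac=0.0, year_fold=1.0):
    """Intensity matrix mimicking the averaged 18-sample study layout."""
    base = 10 ** rng.uniform(3.5, 6.5, n_feat)
    X = base * np.exp(rng.normal(0, cv, size=(18, n_feat)))
    aff = rng.random(n_feat) < affected_frac
    X[np.ix_(y == 1, aff)] *= fold
    yr_aff = rng.random(n_feat) < year_frac
    X[np.ix_(YEARS == 2008, yr_aff)] *= year_fold
    return X, aff, yr_aff


class TestScaler:
    def test_two_point_column(self):
        X = np.array([[1.0], [3.0]])
        out = UnitVarianceScaler().fit_transform(X)
        np.testing.assert_allclose(out[:, 0], [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_column_dropped(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            s = UnitVarianceScaler().fit(X)
        assert list(s.dropped_) == [1]
        assert s.transform(X).shape == (3, 1)

    def test_unit_variance_postcondition(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 30)) * rng.uniform(0.1, 100, size=30)
        out = UnitVarianceScaler().fit_transform(X)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_single_sample_is_an_error(self):
        with pytest.raises(ValueError):
            UnitVarianceScaler().fit(np.ones((1, 4)))

    def test_params_roundtrip(self):
        s = PCAModel(n_components=3)
        assert s.get_params() == {"n_components": 3}
        s.set_params(n_components=2)
        assert s.n_components == 2
        with pytest.raises(ValueError):
            s.set_params(bogus=1)


class TestPCA:
    def test_rank_one_matrix(self):
        u = np.arange(6.0)[:, None]
        v = np.ones((1, 4))
        pca = PCAModel(n_components=1).fit(u @ v)
        assert pca.r2x_[0] == pytest.approx(1.0)

    def test_matches_sklearn_oracle(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 50))
        Xs = UnitVarianceScaler().fit_transform(X)
        ours = PCAModel(n_components=3).fit(Xs)
        ref = SkPCA(n_components=3).fit(Xs)
        for a in range(3):
            sign = np.sign(ours.loadings_[:, a] @ ref.components_[a])
            np.testing.assert_allclose(ours.loadings_[:, a],
                                       sign * ref.components_[a], atol=1e-8)
            np.testing.assert_allclose(ours.scores_[:, a],
                                       sign * ref.transform(Xs)[:, a], atol=1e-8)
        np.testing.assert_allclose(ours.r2x_, ref.explained_variance_ratio_, atol=1e-10)

    def test_full_decomposition_sums_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 5))
        pca = PCAModel(n_components=5).fit(X)
        assert pca.r2x_.sum() == pytest.approx(1.0)
        assert (np.diff(pca.r2x_) <= 1e-12).all()

    def test_invariant_to_variable_ordering(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 20))
        perm = rng.permutation(20)
        a = PCAModel(n_components=2).fit(X)
        b = PCAModel(n_components=2).fit(X[:, perm])
        np.testing.assert_allclose(a.scores_, b.scores_, atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            PCAModel(n_components=9).fit(np.random.default_rng(0).normal(size=(6, 20)))


class TestHotelling:
    def test_unit_variance_symmetry(self):
        rng = np.random.default_rng(4)
        S = rng.normal(size=(18, 2))
        S = (S - S.mean(0)) / S.std(0, ddof=1)
        axes = hotelling_ellipse(S, 0.95)
        n = 18
        t2 = 2 * (n - 1) * (n + 1) / (n * (n - 2)) * stats.f.ppf(0.95, 2, n - 2)
        np.testing.assert_allclose(axes, np.sqrt(t2), rtol=1e-10)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(5)
        S = rng.normal(size=(12, 2))
        sizes = [hotelling_ellipse(S, a)[0] for a in (0.5, 0.9, 0.95, 0.999)]
        assert all(x < y for x, y in zip(sizes, sizes[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            hotelling_ellipse(np.ones((3, 2)))


class TestOplsFit:
    def test_perfect_single_direction_fit(self):
        # y exactly equal to one X column, no other structure: R2Y = 1
        X = np.zeros((12, 4))
        X[:, 1] = np.r_[np.ones(6), np.zeros(6)]
        y = X[:, 1].copy()
        m = OPLSDA(n_ortho=0).fit(X - X.mean(axis=0), y)
        assert m.r2y_ == pytest.approx(1.0)

    def test_matches_pls1_oracle_without_orthogonal_components(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(7)
        X = rng.normal(size=(18, 40))
        Xs = UnitVarianceScaler().fit_transform(X)
        model = OPLSDA(n_ortho=0).fit(Xs, Y_SYSTEM)
        ref = PLSRegression(n_components=1, scale=False).fit(Xs, Y_SYSTEM)
        w_ref = ref.x_weights_[:, 0]
        sign = np.sign(model.w_ @ w_ref)
        np.testing.assert_allclose(model.w_, sign * w_ref, atol=1e-8)
        np.testing.assert_allclose(model.t_, sign * ref.x_scores_[:, 0], atol=1e-8)

    @pytest.mark.parametrize("n_ortho", [1, 2, 3])
    def test_score_and_weight_orthogonality(self, n_ortho):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(18, 60))
        Xs = UnitVarianceScaler().fit_transform(X)
        m = OPLSDA(n_ortho=n_ortho).fit(Xs, Y_SYSTEM)
        assert np.linalg.norm(m.w_) == pytest.approx(1.0)
        for a in range(m.n_ortho_):
            t_o = m.T_o_[:, a]
            assert abs(m.t_ @ t_o) < 1e-8 * np.linalg.norm(m.t_) * np.linalg.norm(t_o)
            assert abs(m.w_ @ m.W_o_[:, a]) < 1e-10
            assert np.linalg.norm(m.W_o_[:, a]) == pytest.approx(1.0)

    def test_one_class_absent_is_an_error(self):
        X = np.random.default_rng(9).normal(size=(6, 5))
        with pytest.raises(ValueError):
            OPLSDA(n_ortho=0).fit(X, np.ones(6))

    def test_excessive_n_ortho_truncated(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(6, 8))
        Xs = UnitVarianceScaler().fit_transform(X)
        with pytest.warns(UserWarning, match="truncated"):
            m = OPLSDA(n_ortho=50).fit(Xs, np.array([1.0, 1, 1, 0, 0, 0]))
        assert m.n_ortho_ <= 4

    def test_training_predictions_recover_fit(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(18, 30))
        Xs = UnitVarianceScaler().fit_transform(X)
        m = OPLSDA(n_ortho=2).fit(Xs, Y_SYSTEM)
        yc = Y_SYSTEM - Y_SYSTEM.mean()
        np.testing.assert_allclose(m.predict(Xs) - Y_SYSTEM.mean(),
                                   m.c_ * m.t_, atol=1e-10)
        r2 = 1 - ((yc - m.c_ * m.t_) ** 2).sum() / (yc ** 2).sum()
        assert m.r2y_ == pytest.approx(r2)


class TestCrossValidation:
    def test_fold_assignment_deterministic_and_trainable(self):
        f1 = assign_folds(Y_SYSTEM, 7)
        f2 = assign_folds(Y_SYSTEM, 7)
        np.testing.assert_array_equal(f1, f2)
        for k in range(7):
            train = Y_SYSTEM[f1 != k]
            assert {0.0, 1.0} <= set(train)

    def test_every_sample_predicted_once(self):
        rng = np.random.default_rng(12)
        Xs = UnitVarianceScaler().fit_transform(rng.normal(size=(18, 30)))
        rep = cross_validate(Xs, Y_SYSTEM, 0, 7)
        assert rep.y_pred_cv.shape == (18,)
        assert np.isfinite(rep.y_pred_cv).all()

    def test_null_data_q2_nonpositive_in_most_runs(self):
        neg = 0
        for s in range(50):
            rng = np.random.default_rng(100 + s)
            Xs = UnitVarianceScaler().fit_transform(rng.normal(size=(18, 2000)))
            rep = cross_validate(Xs, Y_SYSTEM, 0, 7)
            neg += rep.q2 <= 0
        assert neg >= 45  # >= 90% of seeds

    def test_separated_classes_score_high(self):
        rng = np.random.default_rng(3)
        X, _, _ = lognormal_study(rng, 500, affected_frac=0.2, fold=3.0, cv=0.1)
        Xs = UnitVarianceScaler().fit_transform(X)
        rep = cross_validate(Xs, Y_SYSTEM, 0, 7)
        assert rep.q2 > 0.5
        assert rep.n_correct >= 16

    def test_q2_bounded_by_r2y(self):
        for s in range(5):
            rng = np.random.default_rng(40 + s)
            X, _, _ = lognormal_study(rng, 200, affected_frac=0.1, fold=1.8)
            Xs = UnitVarianceScaler().fit_transform(X)
            rep = cross_validate(Xs, Y_SYSTEM, 1, 7)
            m = OPLSDA(n_ortho=1).fit(Xs, Y_SYSTEM)
            assert rep.q2 <= m.r2y_ + 1e-12

    def test_missing_class_in_training_split_is_an_error(self):
        rng = np.random.default_rng(13)
        Xs = UnitVarianceScaler().fit_transform(rng.normal(size=(8, 10)))
        y = np.array([1.0] + [0.0] * 7)
        with pytest.raises(ValueError, match="fold"):
            cross_validate(Xs, y, 0, 7)


class TestComponentSelection:
    def test_pure_noise_gives_no_model(self):
        rng = np.random.default_rng(14)
        Xs = UnitVarianceScaler().fit_transform(rng.normal(size=(18, 2000)))
        n_ortho, rep = select_components(Xs, Y_SYSTEM)
        assert n_ortho is None

    def test_single_direction_signal_needs_no_orthogonal_component(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(18, 300)) * 0.05
        X += np.outer(Y_SYSTEM - Y_SYSTEM.mean(), rng.normal(size=300))
        Xs = UnitVarianceScaler().fit_transform(X)
        n_ortho, rep = select_components(Xs, Y_SYSTEM)
        assert n_ortho == 0
        assert rep.q2 > 0.5

    def test_structured_orthogonal_variation_adds_components(self):
        rng = np.random.default_rng(16)
        signal = np.outer(Y_SYSTEM - Y_SYSTEM.mean(), rng.normal(size=300))
        noise = rng.normal(size=(18, 300)) * 0.3
        ortho_dir = np.where(YEARS == 2008, 1.0, -1.0) * 3.0
        ortho = np.outer(ortho_dir, rng.normal(size=300))
        base_n, _ = select_components(
            UnitVarianceScaler().fit_transform(signal + noise), Y_SYSTEM)
        with_n, _ = select_components(
            UnitVarianceScaler().fit_transform(signal + noise + ortho), Y_SYSTEM)
        assert with_n >= base_n + 1


class TestCvAnova:
    def test_press_equal_ssy_gives_p_one(self):
        f, df1, df2, p = cv_anova(4.0, 4.0, 1, 18)
        assert f == 0.0 and p == 1.0

    def test_monotone_in_press(self):
        ps = [cv_anova(press, 4.0, 1, 18)[3] for press in (3.0, 2.0, 1.0, 0.1)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_df_convention(self):
        f, df1, df2, p = cv_anova(1.0, 4.0, 2, 18)
        assert (df1, df2) == (3, 14)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            cv_anova(1.0, 4.0, 5, 6)

    def test_null_pvalues_approximately_uniform(self):
        # permuted class labels; keep the models that fit (Q2 > 0)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(18, 50))
        Xs = UnitVarianceScaler().fit_transform(X)
        ps = []
        for _ in range(200):
            y = rng.permutation(Y_SYSTEM)
            rep = cross_validate(Xs, y, 0, 7)
            if rep.q2 > 0:
                ssy = float(((y - y.mean()) ** 2).sum())
                ps.append(cv_anova(rep.press, ssy, 1, 18)[3])
        assert len(ps) >= 5
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestVip:
    def test_sum_of_squares_identity(self):
        for n_ortho in (0, 2):
            rng = np.random.default_rng(17)
            Xs = UnitVarianceScaler().fit_transform(rng.normal(size=(18, 120)))
            m = OPLSDA(n_ortho=n_ortho).fit(Xs, Y_SYSTEM)
            v = vip(m)
            assert (v ** 2).sum() == pytest.approx(120.0, rel=1e-12)
            vp = vip(m, kind="predictive")
            assert (vp ** 2).sum() == pytest.approx(120.0, rel=1e-12)

    def test_informative_variable_attains_maximum(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(18, 50)) * 0.2
        X[:, 7] += (Y_SYSTEM - Y_SYSTEM.mean()) * 5
        Xs = UnitVarianceScaler().fit_transform(X)
        m = OPLSDA(n_ortho=0).fit(Xs, Y_SYSTEM)
        assert int(np.argmax(vip(m))) == 7

    def test_null_fraction_above_one_is_moderate(self):
        fracs = []
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            Xs = UnitVarianceScaler().fit_transform(rng.normal(size=(18, 300)))
            m = OPLSDA(n_ortho=0).fit(Xs, Y_SYSTEM)
            fracs.append(float((vip(m) > 1).mean()))
        assert 0.3 <= min(fracs) and max(fracs) <= 0.7

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError):
            vip(OPLSDA(n_ortho=0))


class TestRefinement:
    def test_partition_and_recovery(self):
        rng = np.random.default_rng(5)
        X, _, yr_aff = lognormal_study(rng, 2000, cv=0.1, year_frac=0.2, year_fold=2.0)
        Xs = UnitVarianceScaler().fit_transform(X)
        kept, model, rep = refine_by_year(Xs, YEARS)
        removed = np.setdiff1d(np.arange(2000), kept)
        assert kept.size + removed.size == 2000
        recovery = np.isin(np.flatnonzero(yr_aff), removed).mean()
        assert recovery >= 0.80
        # rebuilt year model on kept variables loses predictive power
        n2, rep2 = select_components(Xs[:, kept], (YEARS == 2008).astype(float))
        assert (n2 is None) or (rep2.q2 < rep.q2)

    def test_no_year_model_refuses_refinement(self):
        rng = np.random.default_rng(19)
        Xs = UnitVarianceScaler().fit_transform(rng.normal(size=(18, 1000)))
        with pytest.raises(ValueError, match="refinement refused"):
            refine_by_year(Xs, YEARS)


class TestExternalValidation:
    def test_identical_separated_data_is_perfect(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(9, 40)) * 0.05
        y = np.array([1.0] * 3 + [0.0] * 6)
        X[:, 0] += y * 10
        res = external_validate(X, y, X, y, folds=7)
        assert res["rate"] == 1.0

    def test_permuted_labels_score_near_chance(self):
        rates = []
        for s in range(20):
            rng = np.random.default_rng(500 + s)
            X, _, _ = lognormal_study(rng, 300)
            y = rng.permutation(Y_SYSTEM)
            m = YEARS == 2007
            try:
                res = external_validate(X[m], y[m], X[~m], y[~m], folds=7)
            except ValueError:
                continue  # a training split lost a class; legitimate refusal
            rates.append(res["rate"])
        assert len(rates) >= 10
        assert 0.35 <= np.mean(rates) <= 0.85  # near the majority prior (6/9)

    def test_cross_year_recovery_beats_majority_baseline(self):
        rates = []
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            X, _, _ = lognormal_study(rng, 500, affected_frac=0.1, fold=2.0,
                                      year_frac=0.2, year_fold=2.0)
            for train_year in (2007, 2008):
                m = YEARS == train_year
                res = external_validate(X[m], Y_SYSTEM[m], X[~m], Y_SYSTEM[~m],
                                        folds=7)
                rates.append(res["rate"])
        assert np.mean(rates) > 6 / 9

    def test_empty_variable_set_rejected(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(9, 10))
        y = np.array([1.0] * 3 + [0.0] * 6)
        with pytest.raises(ValueError, match="empty"):
            external_validate(X, y, X, y, variables=np.array([], dtype=int))
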