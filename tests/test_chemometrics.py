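import numpy as np
import pytest

from urimet import (
    CvResult,
    cross_validate,
    cv_anova,
    flag_outliers,
    oplsda_fit,
    pca_fit,
    permutation_test,
    select_variables,
    vip_scores,
)

from conftest import two_class_matrix


def labels(n_a, n_b):
    return np.array(["BPH"] * n_a + ["PCa"] * n_b)


def separable_data(rng, n_a=10, n_b=10, k=30, gap=6.0, noise=0.3):
    """Two Gaussian clouds separated along a planted direction."""
    direction = rng.normal(size=k)
    direction /= np.linalg.norm(direction)
    X = rng.normal(scale=noise, size=(n_a + n_b, k))
    X[n_a:] += gap * direction
    return X - X.mean(axis=0), labels(n_a, n_b)


class TestPca:
    def test_planted_direction_recovered_by_first_component(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=40)
        direction /= np.linalg.norm(direction)
        scores = rng.normal(scale=5.0, size=60)
        X = np.outer(scores, direction) + rng.normal(scale=0.1, size=(60, 40))
        model = pca_fit(X, 3)
        cosine = abs(model.loadings[:, 0] @ direction)
        assert cosine > 0.99

    def test_loadings_orthonormal_and_scores_centred(self):
        rng = np.random.default_rng(1)
        model = pca_fit(rng.normal(size=(25, 12)), 4)
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0.0, atol=1e-10)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_spiked_sample_is_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 50))
        X[7, 10:15] += 10 * X.std()  # 10x contaminant spike in one sample
        model = pca_fit(X, 3, sample_ids=[f"s{i}" for i in range(40)])
        assert "s7" in flag_outliers(model)

    def test_vanishing_alpha_flags_nobody(self):
        rng = np.random.default_rng(3)
        model = pca_fit(rng.normal(size=(30, 10)), 3)
        assert flag_outliers(model, alpha=1e-12) == []

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(4)
        rates = []
        for _ in range(40):
            model = pca_fit(rng.normal(size=(60, 15)), 3)
            rates.append(len(flag_outliers(model, alpha=0.05)) / 60)
        assert 0.01 < np.mean(rates) < 0.12


class TestOplsda:
    def test_orthogonal_scores_uncorrelated_with_class(self):
        rng = np.random.default_rng(5)
        for n_ortho in (1, 2, 3):
            X, y = separable_data(rng, 12, 14, 40, gap=3.0, noise=1.0)
            model = oplsda_fit(X, y, n_ortho)
            enc = np.where(y == "PCa", 1.0, -1.0)
            for j in range(model.t_ortho.shape[1]):
                r = np.corrcoef(model.t_ortho[:, j], enc)[0, 1]
                assert abs(r) < 1e-8
            assert np.linalg.norm(model.w) == pytest.approx(1.0)

    def test_b_reproduces_training_predictions(self):
        rng = np.random.default_rng(6)
        X, y = separable_data(rng)
        model = oplsda_fit(X, y, 2)
        # deflate manually with the stored orthogonal components
        Xd = X - X.mean(axis=0)
        for j in range(model.t_ortho.shape[1]):
            t_o = Xd @ model.w_ortho[j]
            Xd = Xd - np.outer(t_o, model.p_ortho[j])
        yhat_components = (Xd @ model.w) * model.q + model.y_offset
        np.testing.assert_allclose(model.predict(X), yhat_components, atol=1e-10)

    def test_separable_cohort_fits_almost_perfectly(self):
        rng = np.random.default_rng(7)
        X, y = separable_data(rng, 10, 10, 25, gap=20.0, noise=0.01)
        model = oplsda_fit(X, y, 0)
        assert model.r2y > 0.99
        assert (model.predict_labels(X) == y).all()

    def test_single_class_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            oplsda_fit(rng.normal(size=(6, 5)), ["A"] * 6, 0)

    def test_too_many_orthogonal_components_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            oplsda_fit(rng.normal(size=(6, 5)), labels(3, 3), 5)

    def test_zero_orthogonal_matches_independent_pls1(self):
        # cross-check against an independent NIPALS PLS1 implementation
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(10)
        X, y = two_class_matrix(rng, 15, 8)
        enc = np.where(y == "B", 1.0, -1.0)
        model = oplsda_fit(X, y, 0)
        oracle = PLSRegression(n_components=1, scale=False).fit(X, enc)
        np.testing.assert_allclose(model.predict(X), oracle.predict(X).ravel(), atol=1e-10)


class TestVip:
    def test_identical_variables_all_score_one(self):
        rng = np.random.default_rng(11)
        col = rng.normal(size=20)
        X = np.tile(col[:, None], (1, 7))
        model = oplsda_fit(X, labels(10, 10), 0)
        np.testing.assert_allclose(vip_scores(model), 1.0, atol=1e-10)

    def test_single_informative_variable_approaches_sqrt_k(self):
        rng = np.random.default_rng(12)
        n, k = 40, 25
        y = labels(20, 20)
        enc = np.where(y == "PCa", 1.0, -1.0)
        X = rng.normal(scale=1e-6, size=(n, k))
        X[:, 0] = enc
        model = oplsda_fit(X, y, 0)
        assert vip_scores(model)[0] == pytest.approx(np.sqrt(k), rel=1e-3)

    def test_mean_squared_vip_is_one(self, strong_model_cv):
        model, _ = strong_model_cv
        assert (vip_scores(model) ** 2).mean() == pytest.approx(1.0, abs=1e-10)


class TestCrossValidation:
    def test_perfect_predictor_limit_gives_q2_near_one(self):
        rng = np.random.default_rng(13)
        X, y = separable_data(rng, 14, 14, 20, gap=30.0, noise=0.01)
        cv = cross_validate(X, y, 0, n_folds=7, seed=1)
        assert cv.q2y > 0.99

    def test_permuted_labels_on_null_data_give_nonpositive_q2(self):
        rng = np.random.default_rng(14)
        q2s = []
        for _ in range(15):
            X = rng.normal(size=(30, 40))
            y = labels(15, 15)[rng.permutation(30)]
            q2s.append(cross_validate(X, y, 1, n_folds=5, seed=2).q2y)
        assert np.mean(q2s) <= 0.0

    def test_q2_bounded_by_r2(self):
        rng = np.random.default_rng(15)
        for _ in range(8):
            X, y = separable_data(rng, 12, 12, 30, gap=rng.uniform(0, 4), noise=1.0)
            model = oplsda_fit(X, y, 1)
            cv = cross_validate(X, y, 1, n_folds=6, seed=3)
            assert cv.q2y <= model.r2y + 1e-9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(16)
        X, y = separable_data(rng)
        a = cross_validate(X, y, 1, n_folds=5, seed=9)
        b = cross_validate(X, y, 1, n_folds=5, seed=9)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.b_folds, b.b_folds)
        assert a.q2y == b.q2y

    def test_folds_partition_and_stratify(self):
        rng = np.random.default_rng(17)
        X, y = separable_data(rng, 14, 21, 10)
        cv = cross_validate(X, y, 0, n_folds=7, seed=4)
        assert len(cv.fold_assignments) == 35
        for f in range(7):
            members = y[cv.fold_assignments == f]
            assert set(members) == {"BPH", "PCa"}

    def test_too_many_folds_rejected(self):
        rng = np.random.default_rng(18)
        X, y = separable_data(rng, 4, 20, 10)
        with pytest.raises(ValueError):
            cross_validate(X, y, 0, n_folds=7, seed=0)


class TestPermutation:
    def test_record_counts_and_reproducibility(self):
        rng = np.random.default_rng(19)
        X, y = separable_data(rng, 8, 9, 15, gap=2.0, noise=1.0)
        a = permutation_test(X, y, 1, n_permutations=12, seed=21, n_folds=4)
        b = permutation_test(X, y, 1, n_permutations=12, seed=21, n_folds=4)
        assert a.n_permutations == len(a.q2y_perm) == len(a.r2y_perm) == 12
        np.testing.assert_array_equal(a.q2y_perm, b.q2y_perm)
        assert np.isfinite(a.r2_intercept) and np.isfinite(a.q2_intercept)

    def test_minimum_permutations_enforced(self):
        rng = np.random.default_rng(20)
        X, y = separable_data(rng)
        with pytest.raises(ValueError):
            permutation_test(X, y, 1, n_permutations=5, seed=0)


class TestCvAnova:
    def test_strong_signal_is_significant(self):
        rng = np.random.default_rng(21)
        X, y = separable_data(rng, 15, 15, 20, gap=8.0, noise=0.5)
        cv = cross_validate(X, y, 1, n_folds=6, seed=5)
        assert cv_anova(cv, y) < 0.01

    def test_null_p_is_conservative(self):
        # the F statistic clips at 0 under the null, so p rarely reaches
        # the significance region (type-I control, not uniformity)
        rng = np.random.default_rng(22)
        ps = []
        for _ in range(25):
            X = rng.normal(size=(30, 25))
            y = labels(15, 15)[rng.permutation(30)]
            cv = cross_validate(X, y, 1, n_folds=5, seed=6)
            ps.append(cv_anova(cv, y))
        ps = np.array(ps)
        assert np.all((ps >= 0) & (ps <= 1))
        assert (ps < 0.01).mean() <= 0.08
        assert np.median(ps) > 0.2


class TestSelection:
    def test_stable_coefficient_kept_unstable_dropped(self):
        # hand-built fold coefficients: variable 0 identical across folds,
        # variable 1 alternates +/-c symmetrically
        b_folds = np.zeros((6, 2))
        b_folds[:, 0] = 0.5
        b_folds[:, 1] = [0.5, -0.5, 0.5, -0.5, 0.5, -0.5]
        fake_cv = CvResult(
            fold_assignments=np.arange(6),
            b_folds=b_folds,
            press=1.0,
            q2y=0.5,
            b_cvse=np.sqrt(5 / 6 * ((b_folds - b_folds.mean(0)) ** 2).sum(0)),
            n_folds=6,
            n_orthogonal=1,
            seed=0,
        )

        class Fake:
            b = np.array([0.5, 0.1])

        sel = select_variables(Fake(), fake_cv, 1.0)
        assert bool(sel.keep[0]) is True      # zero spread, nonzero b
        assert bool(sel.keep[1]) is False     # sign-alternating folds

    def test_null_retention_is_modest(self):
        # under exchangeable labels the selection should not keep most buckets
        rng = np.random.default_rng(23)
        from urimet import CohortConfig
        from conftest import PreparedCohort

        prep = PreparedCohort(CohortConfig(seed=77, effect_map={}), align=False)
        model = oplsda_fit(prep.scaled.values, prep.y, 1)
        cv = cross_validate(prep.scaled.values, prep.y, 1, 7, seed=8)
        sel = select_variables(model, cv, 1.0)
        assert sel.keep.mean() < 0.30
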