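import numpy as np
import pytest

from gazeintent.models import (
    KNN_K_GRID,
    MLKNN_K,
    RIDGE_LAMBDA_GRID,
    RidgeScorer,
    SVM_C_GRID,
    fit_binary_relevance,
    fit_classifier_chain,
    fit_mlknn,
)


class TestRidgeBase:
    def test_closed_form_no_intercept(self):
        # beta = (X'X + I)^-1 X'y = 5/6 for X=[1,2]', y=[1,2]'
        m = RidgeScorer(np.array([[1.0], [2.0]]), np.array([1.0, 2.0]), lam=1.0,
                        fit_intercept=False)
        assert m.beta[0] == pytest.approx(5 / 6)
        assert m.scores(np.array([[3.0]]))[0] == pytest.approx(2.5)

    def test_ols_limit_reproduces_linear_target(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 3.0
        m = RidgeScorer(X, y, lam=0.0)
        np.testing.assert_allclose(m.scores(X), y, atol=1e-8)

    def test_large_lambda_shrinks_to_label_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 2, 30).astype(float)
        m = RidgeScorer(X, y, lam=1e12)
        np.testing.assert_allclose(m.beta, 0.0, atol=1e-9)
        np.testing.assert_allclose(m.scores(X), y.mean(), atol=1e-6)

    def test_score_monotone_in_positive_coefficient_feature(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        m = RidgeScorer(X, y, lam=0.5)
        assert m.beta[0] > 0
        s = m.scores(np.array([[1.0], [2.0]]))
        assert s[1] > s[0]

    def test_parameter_grids_match_search_ranges(self):
        np.testing.assert_allclose(RIDGE_LAMBDA_GRID, np.arange(0.25, 2.01, 0.25))
        assert KNN_K_GRID == (5, 10, 15, 20, 25, 30)
        np.testing.assert_allclose(SVM_C_GRID, np.arange(0.2, 2.01, 0.2))
        assert MLKNN_K == 15


class TestBinaryRelevance:
    def test_knn_score_is_neighbor_vote_fraction(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        Y = np.array([[1], [1], [0], [0]])
        model = fit_binary_relevance(X, Y, base="knn", params={"K": 4})
        s = model.scores(np.array([[5.0]]))
        assert s[0, 0] == pytest.approx(0.5)
        assert model.predict(np.array([[5.0]]))[0, 0] == 1  # >= threshold convention

    def test_knn_k1_recovers_training_label(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 2))
        Y = rng.integers(0, 2, (10, 3))
        Y[:, 1] = [0, 1] * 5
        model = fit_binary_relevance(X, Y, base="knn", params={"K": 1})
        np.testing.assert_array_equal(model.predict(X), Y)

    def test_label_isolation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        Y = rng.integers(0, 2, (30, 3))
        Y2 = Y.copy()
        Y2[:, 1] = rng.integers(0, 2, 30)  # scramble a different label
        q = rng.normal(size=(5, 4))
        a = fit_binary_relevance(X, Y, "knn", {"K": 3}).scores(q)[:, 0]
        b = fit_binary_relevance(X, Y2, "knn", {"K": 3}).scores(q)[:, 0]
        np.testing.assert_array_equal(a, b)

    def test_constant_label_degenerates_with_warning(self):
        X = np.random.default_rng(4).normal(size=(10, 2))
        Y = np.column_stack([np.ones(10, dtype=int), np.arange(10) % 2])
        with pytest.warns(UserWarning, match="constant"):
            model = fit_binary_relevance(X, Y, "ridge", {"lambda": 1.0})
        assert model.predict(X)[:, 0].tolist() == [1] * 10

    def test_empty_query_gives_empty_output(self):
        X = np.random.default_rng(5).normal(size=(8, 2))
        Y = np.tile([0, 1], (8, 1)); Y[:4] = [1, 0]
        model = fit_binary_relevance(X, Y, "knn", {"K": 2})
        assert model.scores(np.zeros((0, 2))).shape == (0, 2)
        assert model.predict(np.zeros((0, 2))).shape == (0, 2)

    def test_svm_base_fits_and_scores(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(-2, 0.3, (15, 2)), rng.normal(2, 0.3, (15, 2))])
        Y = np.array([[0]] * 15 + [[1]] * 15)
        model = fit_binary_relevance(X, Y, "svm", {"C": 1.0})
        assert (model.predict(X)[:, 0] == Y[:, 0]).mean() == 1.0


class TestClassifierChain:
    def test_deterministic_downstream_label_predicted_perfectly(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 2))
        y1 = (X[:, 0] > 0).astype(int)
        Y = np.column_stack([y1, y1])  # label 2 == label 1
        model = fit_classifier_chain(X, Y, "ridge", {"lambda": 0.1}, order=(0, 1))
        preds = model.predict(X)
        np.testing.assert_array_equal(preds[:, 1], preds[:, 0])

    def test_independent_labels_match_binary_relevance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 3))
        Y = np.column_stack([(X[:, 0] > 0), (X[:, 1] > 0)]).astype(int)
        q = rng.normal(size=(20, 3))
        cc = fit_classifier_chain(X, Y, "ridge", {"lambda": 1.0}).predict(q)
        br = fit_binary_relevance(X, Y, "ridge", {"lambda": 1.0}).predict(q)
        assert (cc == br).mean() > 0.9

    def test_default_order_is_label_order(self):
        X = np.random.default_rng(9).normal(size=(12, 2))
        Y = np.random.default_rng(9).integers(0, 2, (12, 3))
        Y[:, :] = np.array([[0, 1, 0]] * 6 + [[1, 0, 1]] * 6)
        model = fit_classifier_chain(X, Y, "ridge", {"lambda": 1.0})
        assert model.chain_order == (0, 1, 2)

    def test_invalid_order_rejected(self):
        X = np.zeros((4, 1))
        Y = np.array([[0, 1]] * 2 + [[1, 0]] * 2)
        with pytest.raises(ValueError, match="permutation"):
            fit_classifier_chain(X, Y, "ridge", {}, order=(0, 0))


class TestMLkNN:
    def test_all_active_label_predicts_active(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 2))
        Y = np.column_stack([np.ones(20, int), rng.integers(0, 2, 20)])
        model = fit_mlknn(X, Y, k=3)
        m = 20
        assert model.prior[0] == pytest.approx((m + 1) / (m + 2))
        assert model.predict(rng.normal(size=(5, 2)))[:, 0].tolist() == [1] * 5

    def test_smoothing_floor_for_absent_label(self):
        X = np.random.default_rng(11).normal(size=(10, 2))
        Y = np.column_stack([np.zeros(10, int), np.arange(10) % 2])
        model = fit_mlknn(X, Y, k=2)
        assert model.prior[0] == pytest.approx(1 / 12)
        assert model.prior[0] > 0

    def test_posteriors_match_independent_bayes_trace(self):
        """Full independent recomputation of the ML-kNN tables in loops."""
        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 2))
        Y = rng.integers(0, 2, (12, 2))
        k, s = 3, 1.0
        model = fit_mlknn(X, Y, k=k, s=s)
        Xs = model.standardizer.transform(X)
        q = rng.normal(size=(4, 2))
        qs = model.standardizer.transform(q)
        m, L = Y.shape
        for l in range(L):
            prior = (s + Y[:, l].sum()) / (2 * s + m)
            cpos = np.zeros(k + 1); cneg = np.zeros(k + 1)
            for i in range(m):
                d = ((Xs - Xs[i]) ** 2).sum(axis=1)
                order = [j for j in np.argsort(d, kind="stable") if j != i][:k]
                c = int(Y[order, l].sum())
                (cpos if Y[i, l] else cneg)[c] += 1
            ppos = (s + cpos) / (s * (k + 1) + cpos.sum())
            pneg = (s + cneg) / (s * (k + 1) + cneg.sum())
            got = model.scores(q)[:, l]
            for r in range(len(q)):
                d = ((Xs - qs[r]) ** 2).sum(axis=1)
                order = np.argsort(d, kind="stable")[:k]
                c = int(Y[order, l].sum())
                want = prior * ppos[c] / (prior * ppos[c] + (1 - prior) * pneg[c])
                assert got[r] == pytest.approx(want, abs=1e-12)

    def test_posterior_in_unit_interval(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 3))
        Y = rng.integers(0, 2, (30, 4))
        model = fit_mlknn(X, Y, k=5)
        s = model.scores(rng.normal(size=(10, 3)))
        assert ((s >= 0) & (s <= 1)).all()

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            fit_mlknn(np.zeros((5, 1)), np.zeros((5, 2), dtype=int), k=5)


class TestDeterminism:
    def test_refit_is_bitwise_identical(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(25, 4))
        Y = rng.integers(0, 2, (25, 3))
        q = rng.normal(size=(7, 4))
        for fit in (
            lambda: fit_binary_relevance(X, Y, "knn", {"K": 3}),
            lambda: fit_classifier_chain(X, Y, "ridge", {"lambda": 0.5}),
            lambda: fit_mlknn(X, Y, k=4),
        ):
            np.testing.assert_array_equal(fit().scores(q), fit().scores(q))

    def test_knn_distance_ties_resolved_by_training_index(self):
        X = np.array([[0.0], [0.0], [0.0], [5.0]])
        Y = np.array([[1], [0], [0], [0]])
        model = fit_binary_relevance(X, Y, "knn", {"K": 1})
        # the three zero rows are equidistant; index 0 (label 1) must win
        assert model.scores(np.array([[0.0]]))[0, 0] == 1.0
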