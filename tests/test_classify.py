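import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from copeak.classify import (LabeledSet, NBModel, NEGATIVE, POSITIVE,
                             cross_validate, kmeans2, nb_classify,
                             nb_classify_matrix, nb_fit, nb_posterior,
                             nb_posterior_matrix, rank_features_roc,
                             sample_training)

from _oracles import best_two_partition_inertia, nb_posterior_oracle


def labeled(X, y):
    return LabeledSet(X=np.asarray(X), y=np.asarray(y),
                      ids=[f"i{k}" for k in range(len(y))])


def random_model(rng, d=6):
    return NBModel(prior_pos=(p := float(rng.uniform(0.1, 0.9))),
                   prior_neg=1 - p,
                   theta_pos=rng.uniform(0.05, 0.95, size=d),
                   theta_neg=rng.uniform(0.05, 0.95, size=d))


class TestNbFit:
    def test_laplace_smoothing_hand_example(self):
        model = nb_fit(labeled([[1], [1], [0], [0]], [1, 1, 0, 0]))
        assert model.theta_pos[0] == pytest.approx(3 / 4)
        assert model.theta_neg[0] == pytest.approx(1 / 4)
        assert model.prior_pos == pytest.approx(0.5)
        assert model.prior_neg == pytest.approx(0.5)

    def test_priors_are_class_fractions(self):
        model = nb_fit(labeled([[1], [0], [0]], [1, 0, 0]))
        assert model.prior_pos == pytest.approx(1 / 3)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            nb_fit(labeled([[1], [0]], [1, 1]))

    def test_smoothing_keeps_theta_strictly_inside_unit_interval(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            X = rng.integers(0, 2, size=(n, 5))
            y = np.zeros(n, dtype=int)
            y[:max(1, n // 3)] = 1
            if y.sum() in (0, n):
                continue
            model = nb_fit(labeled(X, y))
            n_pos, n_neg = int(y.sum()), int(n - y.sum())
            for theta, n_c in ((model.theta_pos, n_pos),
                               (model.theta_neg, n_neg)):
                assert (theta >= 1 / (n_c + 2) - 1e-15).all()
                assert (theta <= (n_c + 1) / (n_c + 2) + 1e-15).all()

    def test_invariant_to_training_order(self, rng):
        X = rng.integers(0, 2, size=(12, 4))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 0, 1, 0])
        perm = rng.permutation(12)
        a = nb_fit(labeled(X, y))
        b = nb_fit(labeled(X[perm], y[perm]))
        np.testing.assert_array_equal(a.theta_pos, b.theta_pos)
        np.testing.assert_array_equal(a.theta_neg, b.theta_neg)

    def test_model_json_roundtrip(self, tmp_path, rng):
        model = random_model(rng)
        model.to_json(tmp_path / "m.json")
        back = NBModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(back.theta_pos, model.theta_pos)
        assert back.threshold == model.threshold


class TestNbPosterior:
    def test_symmetric_model_gives_half(self, rng):
        theta = rng.uniform(0.1, 0.9, size=5)
        model = NBModel(0.5, 0.5, theta, theta.copy())
        for _ in range(5):
            x = rng.integers(0, 2, size=5)
            assert nb_posterior(model, x) == pytest.approx(0.5)

    def test_closed_form_on_fitted_toy_model(self):
        model = nb_fit(labeled([[1], [1], [0], [0]], [1, 1, 0, 0]))
        assert nb_posterior(model, [1]) == pytest.approx(0.75)

    def test_matches_product_form_oracle(self, rng):
        for _ in range(100):
            model = random_model(rng)
            x = rng.integers(0, 2, size=6)
            expected = nb_posterior_oracle(model.prior_pos, model.prior_neg,
                                           model.theta_pos, model.theta_neg,
                                           x)
            assert nb_posterior(model, x) == pytest.approx(expected,
                                                           abs=1e-9)

    @given(st.integers(0, 2**10 - 1))
    def test_posteriors_normalize(self, bits):
        rng = np.random.default_rng(bits)
        model = random_model(rng, d=10)
        x = np.array([(bits >> i) & 1 for i in range(10)])
        lp, ln = nb_posterior(model, x), 1 - nb_posterior(model, x)
        # P(pos|x) + P(neg|x) = 1 by construction; check the log-space path
        from copeak.classify import _log_joint
        a, b = _log_joint(model, x.reshape(1, -1))
        total = np.exp(a - np.logaddexp(a, b)) + np.exp(b - np.logaddexp(a, b))
        assert abs(float(total[0]) - 1.0) < 1e-12

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            nb_posterior(random_model(rng, d=4), [1, 0])

    def test_agrees_with_sklearn_bernoulli_nb(self, rng):
        """Independent cross-check against a reference implementation."""
        sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
        X = rng.integers(0, 2, size=(40, 8))
        y = (rng.random(40) < 0.4).astype(int)
        if y.sum() in (0, 40):
            y[:5] = 1
            y[5:] = 0
        model = nb_fit(labeled(X, y))
        ref = sklearn_nb.BernoulliNB(alpha=1.0).fit(X, y)
        ours = nb_posterior_matrix(model, X)
        theirs = ref.predict_proba(X)[:, list(ref.classes_).index(1)]
        np.testing.assert_allclose(ours, theirs, atol=1e-9)


class TestNbClassify:
    def test_threshold_is_inclusive(self):
        model = NBModel(0.5, 0.5, np.array([0.5]), np.array([0.5]),
                        threshold=0.5)
        # symmetric model: posterior exactly 0.5 -> positive at th=0.5
        assert nb_classify(model, [1]) == POSITIVE
        model.threshold = 0.500001
        assert nb_classify(model, [1]) == NEGATIVE

    def test_threshold_half_equals_argmax(self, rng):
        for _ in range(50):
            model = random_model(rng)
            model.threshold = 0.5
            x = rng.integers(0, 2, size=6)
            post = nb_posterior(model, x)
            argmax = POSITIVE if post >= 0.5 else NEGATIVE
            assert nb_classify(model, x) == argmax


class TestSampleTraining:
    def test_ratio_1_to_2_with_18_positives(self, rng):
        pos = rng.integers(0, 2, size=(18, 3))
        neg = rng.integers(0, 2, size=(100, 3))
        train = sample_training(pos, [f"p{i}" for i in range(18)],
                                neg, [f"n{i}" for i in range(100)],
                                ratio=2, seed=11)
        assert len(train) == 54
        assert int(train.y.sum()) == 18
        assert len(set(train.ids)) == 54       # without replacement

    def test_deterministic_for_fixed_seed(self, rng):
        pos = rng.integers(0, 2, size=(5, 3))
        neg = rng.integers(0, 2, size=(40, 3))
        a = sample_training(pos, list("abcde"), neg,
                            [f"n{i}" for i in range(40)], ratio=3, seed=2)
        b = sample_training(pos, list("abcde"), neg,
                            [f"n{i}" for i in range(40)], ratio=3, seed=2)
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.X, b.X)

    def test_pool_too_small_errors(self, rng):
        with pytest.raises(ValueError, match="too small"):
            sample_training(np.ones((18, 2)), ["p"] * 18,
                            np.zeros((10, 2)), ["n"] * 10, ratio=2, seed=0)


class TestKmeans2:
    def test_recovers_separated_blobs(self, rng):
        a = np.tile([1, 1, 1, 1, 0, 0, 0, 0], (8, 1))
        b = np.tile([0, 0, 0, 0, 1, 1, 1, 1], (5, 1))
        a[0, 0] = 0                      # a little noise
        X = np.vstack([a, b])
        result = kmeans2(X, seed=3, restarts=10)
        assert len(set(result.assignment[:8])) == 1
        assert len(set(result.assignment[8:])) == 1
        assert result.assignment[0] != result.assignment[-1]
        # cluster 1 is the larger one
        assert (result.assignment == 1).sum() >= (result.assignment == 2).sum()

    def test_duplicate_pair_clusters_together(self):
        X = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1]])
        result = kmeans2(X, seed=0, restarts=5)
        assert result.assignment[0] == result.assignment[1]
        assert result.assignment[2] != result.assignment[0]

    def test_all_identical_rows_error(self):
        with pytest.raises(ValueError):
            kmeans2(np.ones((6, 4)), seed=0)

    def test_inertia_non_increasing_within_run(self, rng):
        X = rng.integers(0, 2, size=(40, 6))
        result = kmeans2(X, seed=9, restarts=3)
        diffs = np.diff(result.inertia_history)
        assert (diffs <= 1e-9).all()

    def test_finds_best_partition_in_most_seeded_runs(self, rng):
        """With 20 restarts, the exhaustive-search optimum is reached in at
        least 90% of small instances."""
        hits = 0
        n_instances = 10
        for k in range(n_instances):
            X = rng.integers(0, 2, size=(10, 4)).astype(float)
            if np.all(X == X[0]):
                X[0] = 1 - X[0]
            best = best_two_partition_inertia(X)
            result = kmeans2(X, seed=100 + k, restarts=20)
            if result.inertia <= best + 1e-9:
                hits += 1
        assert hits >= 0.9 * n_instances


class TestRankFeaturesRoc:
    def test_perfect_feature_ranks_first_with_criterion_half(self):
        X = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        y = np.array([1, 1, 0, 0])
        ranking = rank_features_roc(labeled(X, y))
        assert ranking[0] == (0, pytest.approx(0.5))

    def test_uninformative_feature_has_zero_criterion(self):
        X = np.array([[1], [1], [1], [1]])
        y = np.array([1, 1, 0, 0])
        (feature,) = rank_features_roc(labeled(X, y))
        assert feature == (0, pytest.approx(0.0))

    def test_auc_equals_mann_whitney_u_statistic(self, rng):
        for _ in range(20):
            n = 30
            X = rng.integers(0, 2, size=(n, 3))
            y = (rng.random(n) < 0.5).astype(int)
            if y.sum() in (0, n):
                continue
            ranking = dict(rank_features_roc(labeled(X, y)))
            for j in range(3):
                u = mannwhitneyu(X[y == 1, j], X[y == 0, j],
                                 alternative="two-sided",
                                 use_continuity=False).statistic
                auc = u / (y.sum() * (n - y.sum()))
                assert ranking[j] == pytest.approx(abs(auc - 0.5))

    def test_criterion_bounded_and_sorted(self, rng):
        X = rng.integers(0, 2, size=(20, 8))
        y = np.array([1] * 7 + [0] * 13)
        ranking = rank_features_roc(labeled(X, y))
        crits = [c for _, c in ranking]
        assert all(0 <= c <= 0.5 for c in crits)
        assert crits == sorted(crits, reverse=True)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            rank_features_roc(labeled([[1], [0]], [1, 1]))


class TestCrossValidate:
    def _set(self, n_pos=9, n_neg=18, d=3, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(n_pos + n_neg, d))
        y = np.array([1] * n_pos + [0] * n_neg)
        return labeled(X, y)

    def test_always_positive_classifier_closed_form(self):
        train = self._set()
        always_pos = lambda fit_set: lambda X: [POSITIVE] * len(X)
        p, r, a = cross_validate(train, folds=9, classifier=always_pos)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 3)
        assert a == pytest.approx(1 / 3)

    def test_perfect_classifier(self):
        # feature 0 encodes the label exactly
        rng = np.random.default_rng(1)
        n = 27
        y = np.array([1] * 9 + [0] * 18)
        X = np.column_stack([y, rng.integers(0, 2, size=(n, 2))])
        oracle = lambda fit_set: lambda Xt: [
            POSITIVE if row[0] else NEGATIVE for row in Xt]
        p, r, a = cross_validate(labeled(X, y), folds=9, classifier=oracle)
        assert (p, r, a) == (1.0, 1.0, 1.0)

    def test_stratification_requires_enough_examples(self):
        train = labeled([[1], [1], [0], [0]], [1, 1, 0, 0])
        with pytest.raises(ValueError, match="fewer than"):
            cross_validate(train, folds=9)

    def test_deterministic_for_fixed_seed(self):
        train = self._set(seed=4)
        np.testing.assert_equal(cross_validate(train, seed=3),
                                cross_validate(train, seed=3))
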