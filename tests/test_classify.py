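"""Base classifiers, Bayesian search, and majority-vote fusion."""

import itertools

import numpy as np
import pytest

from stmi import classify
from stmi.errors import DataError, ParameterError


def blobs(rng, n=40, sep=6.0):
    X = np.vstack(
        [rng.standard_normal((n // 2, 2)), rng.standard_normal((n // 2, 2)) + sep]
    )
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    return X, y


def xor_blobs(rng, n=400, noise=0.3):
    y = rng.integers(0, 2, n)
    quad = rng.integers(0, 2, n)
    x1 = np.where(y == quad, 1.0, -1.0)
    x2 = np.where(quad == 1, 1.0, -1.0)
    X = np.c_[x1, x2] + noise * rng.standard_normal((n, 2))
    return X, y


class TestTrainClassifier:
    @pytest.mark.parametrize("name", classify.CLASSIFIER_NAMES)
    def test_every_classifier_fits_separable_blobs(self, name, rng):
        X, y = blobs(rng)
        hp = {
            "svm": {"kernel": "linear", "C": 1.0},
            "discriminant": {"kind": "linear"},
            "knn": {"k": 3, "metric": "euclidean", "weight": "equal"},
            "dt": {"max_splits": 5},
            "rf": {"min_leaf": 1, "predictors_per_split": 2},
        }[name]
        model = classify.train_classifier(name, X, y, hp)
        assert (model.predict(X) == y).mean() == 1.0

    def test_knn_k1_memorizes_distinct_points(self, rng):
        X, y = blobs(rng, sep=0.5)
        model = classify.train_classifier(
            "knn", X, y, {"k": 1, "metric": "euclidean", "weight": "equal"}
        )
        assert (model.predict(X) == y).mean() == 1.0

    @pytest.mark.parametrize("metric", ["mahalanobis", "cubic", "cosine"])
    @pytest.mark.parametrize("weight", ["inverse", "squared-inverse"])
    def test_knn_metric_weight_combinations(self, metric, weight, rng):
        X, y = blobs(rng)
        X += 3.0  # keep away from the origin for the cosine metric
        model = classify.train_classifier(
            "knn", X, y, {"k": 3, "metric": metric, "weight": weight}
        )
        assert (model.predict(X) == y).mean() > 0.9

    def test_xor_needs_a_nonlinear_kernel(self):
        """Linear SVM is near chance on XOR; the gaussian kernel solves it."""
        rng = np.random.default_rng(7)
        X, y = xor_blobs(rng, n=400)
        Xt, yt = xor_blobs(rng, n=400)
        lin = classify.train_classifier("svm", X, y, {"kernel": "linear", "C": 1.0})
        rbf = classify.train_classifier("svm", X, y, {"kernel": "gaussian", "C": 10.0, "gamma": 1.0})
        assert (lin.predict(Xt) == yt).mean() <= 0.75
        assert (rbf.predict(Xt) == yt).mean() >= 0.95

    def test_linear_discriminant_approaches_bayes_rule(self):
        """Equal-covariance Gaussians: accuracy within 2% of the analytic
        Bayes accuracy Phi(delta/2) at n=2000."""
        from scipy.stats import norm as normal

        rng = np.random.default_rng(3)
        delta = 2.0
        n = 2000
        X = np.vstack(
            [rng.standard_normal((n // 2, 2)), rng.standard_normal((n // 2, 2)) + [delta, 0]]
        )
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        model = classify.train_classifier("discriminant", X, y, {"kind": "linear"})
        Xt = np.vstack(
            [rng.standard_normal((n // 2, 2)), rng.standard_normal((n // 2, 2)) + [delta, 0]]
        )
        acc = (model.predict(Xt) == y).mean()
        assert abs(acc - normal.cdf(delta / 2)) < 0.02

    def test_unknown_name_and_single_class_raise(self, rng):
        X, y = blobs(rng)
        with pytest.raises(ParameterError):
            classify.train_classifier("mlp", X, y, {})
        with pytest.raises(DataError):
            classify.train_classifier("svm", X, np.zeros(len(y), int), {})


class TestBayesOptimize:
    def test_finds_the_maximum_of_a_quadratic(self):
        """1-D concave quadratic with argmax 0.3: found within 5% of the domain."""
        space = classify.SearchSpace({"x": classify.Real(0.0, 1.0)})
        result = classify.bayes_optimize(
            lambda p: -((p["x"] - 0.3) ** 2), space, n_iter=25, seed=0
        )
        assert abs(result.best_params["x"] - 0.3) < 0.05

    def test_single_iteration_returns_the_evaluated_point(self):
        space = classify.SearchSpace({"x": classify.Real(0.0, 1.0)})
        result = classify.bayes_optimize(lambda p: p["x"], space, n_iter=1, seed=4)
        assert len(result.evaluated) == 1
        assert result.best_params == result.evaluated[0][0]

    def test_deterministic_given_seed(self):
        space = classify.SearchSpace(
            {"x": classify.Real(1e-3, 1e3, log=True), "k": classify.Integer(1, 30)}
        )
        f = lambda p: -abs(np.log10(p["x"])) - abs(p["k"] - 7) / 10
        r1 = classify.bayes_optimize(f, space, n_iter=15, seed=11)
        r2 = classify.bayes_optimize(f, space, n_iter=15, seed=11)
        assert r1.trace == r2.trace
        assert r1.best_params == r2.best_params

    def test_trace_is_nondecreasing_and_points_stay_in_space(self):
        space = classify.SearchSpace(
            {
                "c": classify.Categorical(("a", "b", "c")),
                "v": classify.Real(0.1, 10.0, log=True),
            }
        )
        seen = []
        f = lambda p: seen.append(p) or (p["v"] if p["c"] == "b" else 0.0)
        result = classify.bayes_optimize(f, space, n_iter=20, seed=2)
        assert all(a <= b for a, b in zip(result.trace, result.trace[1:]))
        assert all(space.contains(p) for p in seen)
        with pytest.raises(ParameterError):
            classify.bayes_optimize(f, space, n_iter=0)

    @pytest.mark.parametrize("name", classify.CLASSIFIER_NAMES)
    def test_optimize_classifier_end_to_end(self, name, rng):
        X, y = blobs(rng, n=30)
        model, result = classify.optimize_classifier(name, X, y, n_iter=8, seed=0)
        assert result.best_value >= 0.9
        assert (model.predict(X) == y).mean() >= 0.9


class TestMajorityVote:
    def test_three_against_two(self):
        assert classify.majority_vote(["L", "L", "L", "R", "R"]) == "L"

    def test_unanimity(self):
        assert classify.majority_vote(["R"] * 5) == "R"

    def test_all_32_patterns_equal_the_mode(self):
        """Exhaustive check over every 5-voter binary outcome."""
        for votes in itertools.product([0, 1], repeat=5):
            expected = int(sum(votes) >= 3)
            assert classify.majority_vote(list(votes)) == expected

    def test_agreement_implies_fused_equals_base(self, rng):
        for _ in range(10):
            v = int(rng.integers(0, 2))
            assert classify.majority_vote([v] * 5) == v

    def test_abstention_falls_back_to_first_voter(self):
        assert classify.majority_vote([1, None, 0, 0, 1]) == 1

    def test_invalid_votes_raise(self):
        with pytest.raises(DataError):
            classify.majority_vote([0, 1])
        with pytest.raises(DataError):
            classify.majority_vote([0, 1, 2, 1, 0])
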