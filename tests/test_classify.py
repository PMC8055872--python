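import numpy as np
import pandas as pd
import pytest

from hippus.classify import (
    LogisticFit,
    decision_grid,
    encode_labels,
    evaluate_combinations,
    fit_logistic,
    roc_auc,
)
from oracles import auc_mannwhitney


class TestFitLogistic:
    def test_constant_feature_gives_prevalence_intercept(self):
        y = np.array([0, 0, 0, 1, 1], float)
        fit = fit_logistic(np.full((5, 1), 2.5), y)
        assert fit.weights[0] == 0.0
        assert fit.intercept == pytest.approx(np.log((2 / 5) / (3 / 5)), abs=1e-6)

    def test_perfect_separation_flagged_ordering_preserved(self):
        X = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]])
        y = np.array([0, 0, 0, 1, 1, 1], float)
        fit = fit_logistic(X, y)
        assert fit.separation_flag and not fit.converged
        assert fit.probabilities[:3].max() < fit.probabilities[3:].min()

    def test_loglik_maximal_on_grid(self):
        X = np.array([[0.2], [0.7], [0.4], [0.3], [0.9], [0.6]])
        y = np.array([0, 0, 1, 0, 1, 1], float)
        fit = fit_logistic(X, y)
        b0, b1 = fit.intercept, fit.weights[0]

        def ll(a, b):
            eta = a + b * X[:, 0]
            p = 1 / (1 + np.exp(-eta))
            return np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        best = ll(b0, b1)
        for da in np.linspace(-0.5, 0.5, 11):
            for db in np.linspace(-0.5, 0.5, 11):
                assert ll(b0 + da, b1 + db) <= best + 1e-9

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(60, 2))
        eta = 0.3 + X @ np.array([1.0, -0.7])
        y = (rng.random(60) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((4, 1)), np.ones(4))


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0

    def test_constant_score_auc_half(self):
        res = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert res.auc == 0.5

    def test_known_mixed_case(self):
        res = roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)

    def test_equals_mannwhitney_exactly(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(n), 1)  # force ties
            assert roc_auc(scores, y).auc == pytest.approx(
                auc_mannwhitney(scores, y), abs=1e-12
            )

    def test_curve_endpoints(self, rng):
        y = np.r_[np.ones(5), np.zeros(5)]
        res = roc_auc(rng.random(10), y)
        assert res.roc_points[0] == (0.0, 0.0) and res.roc_points[-1] == (1.0, 1.0)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        p = rng.random(20)
        assert roc_auc(p, y).auc == roc_auc(p**2, y).auc  # p**2 monotone on (0,1)

    def test_label_flip_complement(self, rng):
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        p = rng.random(20)
        assert roc_auc(p, y).auc + roc_auc(p, 1 - y).auc == pytest.approx(1.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(5):
            y = rng.integers(0, 2, 25)
            y[:2] = [0, 1]
            scores = np.round(rng.random(25), 1)
            assert roc_auc(scores, y).auc == pytest.approx(
                roc_auc_score(y, scores), abs=1e-12
            )


class TestDecisionGrid:
    def _fit(self, intercept, w):
        return LogisticFit(
            feature_names=["f1", "f2"], intercept=intercept, weights=np.asarray(w, float),
            probabilities=np.array([]), converged=True, separation_flag=False,
            n_iter=1, log_likelihood=0.0,
        )

    def test_zero_coefficients_give_half_everywhere(self):
        g = decision_grid(self._fit(0.0, [0.0, 0.0]), ((0, 1), (0, 1)), resolution=5)
        assert np.allclose(g.P, 0.5)

    def test_vertical_boundary(self):
        g = decision_grid(self._fit(0.0, [1.0, 0.0]), ((-1, 1), (-1, 1)), resolution=21)
        inside = g.region[:, g.x >= 0]
        outside = g.region[:, g.x < 0]
        assert inside.all() and not outside.any()

    def test_pointwise_probabilities(self, rng):
        fit = self._fit(0.3, [1.2, -0.8])
        g = decision_grid(fit, ((0, 2), (0, 2)), resolution=11)
        for _ in range(5):
            i, j = rng.integers(0, 11, 2)
            eta = 0.3 + 1.2 * g.x[j] - 0.8 * g.y[i]
            assert g.P[i, j] == pytest.approx(1 / (1 + np.exp(-eta)))

    def test_requires_two_features(self):
        with pytest.raises(ValueError):
            decision_grid(
                LogisticFit(["a"], 0.0, np.zeros(1), np.array([]), True, False, 1, 0.0),
                ((0, 1), (0, 1)),
            )


class TestEvaluateCombinations:
    def _table(self, rng, n=30):
        y = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
        return (
            pd.DataFrame(
                {
                    "size_mm": rng.normal(3.6 + 0.4 * y, 0.4),
                    "sampen": rng.normal(0.17 - 0.04 * y, 0.06),
                    "tranen": rng.normal(0.16 - 0.02 * y, 0.05),
                }
            ),
            ["TD" if v == 0 else "ADHD" for v in y],
        )

    def test_gate_respected_and_singles_present(self, rng):
        table, labels = self._table(rng)
        allowed = [("size_mm",), ("sampen",), ("tranen",), ("size_mm", "sampen")]
        res = evaluate_combinations(table, labels, allowed)
        assert set(res) == set(allowed)
        assert ("sampen", "tranen") not in res

    def test_superset_in_sample_auc_not_worse(self, rng):
        for _ in range(10):
            table, labels = self._table(rng)
            res = evaluate_combinations(
                table, labels, [("size_mm",), ("size_mm", "sampen")]
            )
            assert (
                res[("size_mm", "sampen")]["auc"]
                >= res[("size_mm",)]["auc"] - 0.02
            )

    def test_cv_auc_reported_separately(self, rng):
        table, labels = self._table(rng)
        res = evaluate_combinations(table, labels, [("size_mm",)], cv_folds=3)
        assert 0 <= res[("size_mm",)]["cv_auc"] <= 1


def test_encode_labels_positive_class():
    y = encode_labels(["TD", "ADHD", "drug-naive-ADHD"])
    np.testing.assert_array_equal(y, [0, 1, 1])
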