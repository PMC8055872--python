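import numpy as np
import pandas as pd
import pytest

from hippus.stats import (
    ancova_group_age,
    chi_square_2x2,
    correlation_matrix,
    multicollinearity_gate,
    pearson_r,
    two_sample_t,
)
from oracles import ancova_lstsq


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert (t, p) == (0.0, 1.0)

    def test_textbook_value(self):
        t, p = two_sample_t([1.0, 2, 3], [4.0, 5, 6])
        # pooled sd = 1, se = sqrt(1/3 + 1/3)
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
        assert 0 < p < 0.05

    def test_swap_negates_t(self, rng):
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=10)
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means(self):
        t, p = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and t < 0 and p == 0.0


class TestChiSquare:
    def test_balanced_table(self):
        chi2, p = chi_square_2x2([[5, 5], [5, 5]])
        assert (chi2, p) == (0.0, 1.0)

    def test_hand_computation(self):
        obs = np.array([[8.0, 12.0], [8.0, 8.0]])
        n = obs.sum()
        expected = np.outer(obs.sum(1), obs.sum(0)) / n
        ref = float(np.sum((obs - expected) ** 2 / expected))
        chi2, _ = chi_square_2x2(obs)
        assert chi2 == pytest.approx(ref)

    def test_transpose_invariance(self):
        a, _ = chi_square_2x2([[8, 12], [8, 8]])
        b, _ = chi_square_2x2([[8, 8], [12, 8]])
        assert a == pytest.approx(b)

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestAncova:
    def test_constant_age_reduces_to_anova_and_t_squared(self, rng):
        vals = np.r_[rng.normal(0, 1, 10), rng.normal(1, 1, 10)]
        groups = ["A"] * 10 + ["B"] * 10
        res = ancova_group_age(vals, groups, np.full(20, 30.0))
        assert res.covariate_dropped
        t, _ = two_sample_t(vals[:10], vals[10:])
        assert res.F == pytest.approx(t**2, abs=1e-10)

    def test_no_group_effect_beyond_age(self, rng):
        # both groups see identical (age, value) pairs: the group indicator
        # explains exactly nothing once age is in the model
        age10 = rng.uniform(20, 50, 10)
        vals10 = 0.1 * age10 + rng.normal(0, 0.5, 10)
        res = ancova_group_age(
            np.r_[vals10, vals10], ["A"] * 10 + ["B"] * 10, np.r_[age10, age10]
        )
        assert res.F == pytest.approx(0.0, abs=1e-10)

    def test_matches_lstsq_oracle(self, rng):
        vals = rng.normal(size=8)
        groups = ["A"] * 4 + ["B"] * 4
        age = rng.uniform(20, 50, 8)
        res = ancova_group_age(vals, groups, age)
        F, eta, dfn, dfd = ancova_lstsq(vals, groups, age)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.eta_sq == pytest.approx(eta, rel=1e-10)
        assert res.df == (dfn, dfd)

    def test_posthoc_sign_convention(self):
        vals = np.r_[np.arange(5.0), np.arange(5.0) + 10.0]
        groups = ["A"] * 5 + ["B"] * 5
        res = ancova_group_age(vals, groups, np.r_[np.arange(10.0) + 20])
        assert res.posthoc_t > 0  # second-sorted level (B) is larger

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            ancova_group_age([1.0, 2, 3], ["A"] * 3, [30.0] * 3)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_formula_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        r, _ = pearson_r(x, y)
        ref = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(ref)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1, 1], [1.0, 2, 3])


def _feature_table(rho_sampen_tranen, rng, n=40):
    """size independent; sampen/tranen with prescribed correlation."""
    size = rng.normal(3.8, 0.4, n)
    a = rng.normal(size=n)
    b = rho_sampen_tranen * a + np.sqrt(max(0.0, 1 - rho_sampen_tranen**2)) * rng.normal(size=n)
    return pd.DataFrame({"size_mm": size, "sampen": 0.15 + 0.05 * a, "tranen": 0.15 + 0.04 * b})


class TestMulticollinearityGate:
    def test_collinear_pair_excluded(self, rng):
        table = _feature_table(0.97, rng)
        allowed = multicollinearity_gate(table)
        assert ("sampen", "tranen") not in allowed
        assert ("size_mm", "sampen", "tranen") not in allowed
        assert ("size_mm", "sampen") in allowed
        assert ("size_mm", "tranen") in allowed

    def test_all_seven_when_uncorrelated(self, rng):
        table = _feature_table(0.0, rng)
        assert len(multicollinearity_gate(table)) == 7

    def test_boundary_is_strict(self, rng):
        table = _feature_table(0.9, rng)
        cm = correlation_matrix(table, ["size_mm", "sampen", "tranen"], threshold=0.8)
        r = abs(cm.R.loc["sampen", "tranen"])
        # threshold equal to the observed |R|: not strictly above -> retained
        allowed = multicollinearity_gate(table, threshold=r)
        assert ("sampen", "tranen") in allowed


def test_correlation_matrix_symmetry(rng):
    table = _feature_table(0.5, rng)
    cm = correlation_matrix(table, ["size_mm", "sampen", "tranen"])
    assert np.allclose(cm.R, cm.R.T)
    assert np.all(np.abs(cm.R.to_numpy()) <= 1.0)
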