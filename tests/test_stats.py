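"""Statistical tests against closed forms and exact small-sample oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from forcematch.exceptions import (
    CollinearityError,
    DegenerateInputError,
    InvalidArgumentError,
)
from forcematch.stats import (
    bonferroni,
    chi_square_2x2,
    ks_normality,
    pearson_r,
    rank_test,
    standardized_regression,
    t_test,
)


def exact_mw_p(x, y):
    """Independent enumeration oracle over all rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    obs = abs(ranks[:n1].sum() - n1 * (len(pooled) + 1) / 2.0)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        dev = abs(ranks[list(comb)].sum() - n1 * (len(pooled) + 1) / 2.0)
        total += 1
        hits += dev >= obs - 1e-12
    return hits / total


def exact_wilcoxon_p(x, mu):
    d = np.asarray(x, float) - mu
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    mean_w = len(d) * (len(d) + 1) / 4.0
    obs = abs(ranks[d > 0].sum() - mean_w)
    hits = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        hits += abs(w - mean_w) >= obs - 1e-12
    return hits / 2 ** len(d)


class TestRankTests:
    def test_identical_samples_z_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = rank_test(x, x, kind="mann_whitney")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_mw_exact_matches_enumeration(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = rank_test(x, y, kind="mann_whitney", method="exact")
        assert res.p == pytest.approx(exact_mw_p(x, y))
        assert res.p == pytest.approx(2 / 20)
        # scipy exact p as a second, independent cross-check
        assert res.p == pytest.approx(
            sps.mannwhitneyu(x, y, method="exact").pvalue
        )

    def test_mw_z_matches_hand_formula(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = rank_test(x, y, kind="mann_whitney")
        # U1 = 0, mean = 4.5, var = n1 n2 (N+1)/12 = 5.25 (no ties)
        assert res.statistic == pytest.approx(-4.5 / np.sqrt(5.25))

    def test_mw_sign_convention(self, rng):
        hi = rng.normal(2.0, 0.5, 12)
        lo = rng.normal(0.0, 0.5, 12)
        assert rank_test(hi, lo, kind="mann_whitney").statistic > 0
        assert rank_test(lo, hi, kind="mann_whitney").statistic < 0

    @pytest.mark.parametrize("seed", range(6))
    def test_mw_ordering_agrees_with_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, rng.integers(3, 6))
        y = rng.normal(0.5, 1, rng.integers(3, 6))
        res = rank_test(x, y, kind="mann_whitney", method="exact")
        assert res.p == pytest.approx(exact_mw_p(x, y))

    def test_wilcoxon_exact_matches_enumeration(self):
        # binary-exact values so the two 0.125 differences genuinely tie
        x = np.array([1.25, 1.125, 0.875, 1.375])
        res = rank_test(x, kind="wilcoxon_signed_rank", mu=1.0, method="exact")
        assert res.p == pytest.approx(exact_wilcoxon_p(x, 1.0))
        assert res.extra["W_plus"] == pytest.approx(8.5)

    def test_wilcoxon_sign_convention(self):
        up = rank_test(
            np.array([1.2, 1.3, 1.1, 1.4, 0.95]), kind="wilcoxon_signed_rank", mu=1.0
        )
        assert up.statistic > 0

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            rank_test(np.ones(5), kind="wilcoxon_signed_rank", mu=1.0)


class TestTTest:
    def test_closed_form(self):
        # x = mu + c with sample SD s: t = c sqrt(n) / s
        x = np.array([2.0, 2.0, 2.0, 4.0])
        res = t_test(x, mu=2.0)
        c, s, n = 0.5, x.std(ddof=1), 4
        assert res.statistic == pytest.approx(c * np.sqrt(n) / s)
        assert res.df == 3
        assert res.p == pytest.approx(2 * sps.t.sf(res.statistic, 3))

    def test_symmetric_sample_t_zero(self):
        res = t_test(np.array([-1.0, -0.5, 0.5, 1.0]), mu=0.0)
        assert res.statistic == pytest.approx(0.0)

    def test_paired_identical_is_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            t_test(x, x, mode="paired")

    def test_matches_scipy(self, rng):
        x = rng.normal(0.4, 1.0, 18)
        res = t_test(x, mu=0.0)
        ref = sps.ttest_1samp(x, 0.0)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestKS:
    def test_affine_invariance(self, rng):
        x = rng.normal(3.0, 2.0, 18)
        a = ks_normality(x).statistic
        b = ks_normality(5.0 * x - 7.0).statistic
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_step_scan_oracle(self, rng):
        x = rng.normal(0, 1, 25)
        res = ks_normality(x)
        xs = np.sort(x)
        cdf = sps.norm.cdf(xs, x.mean(), x.std(ddof=1))
        n = len(x)
        d_plus = np.max(np.arange(1, n + 1) / n - cdf)
        d_minus = np.max(cdf - np.arange(0, n) / n)
        assert res.statistic == pytest.approx(max(d_plus, d_minus), abs=1e-12)

    def test_near_perfect_normal_sample_small_d(self):
        n = 30
        x = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        res = ks_normality(x)
        assert res.statistic < 1 / (2 * n) + 0.02

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ks_normality(np.ones(10))


class TestChiSquare:
    def test_published_gender_table(self):
        res = chi_square_2x2(12, 6, 89, 86)
        assert res.statistic == pytest.approx(1.64, abs=0.005)
        assert res.df == 1

    def test_proportional_table_zero(self):
        assert chi_square_2x2(10, 20, 30, 60).statistic == pytest.approx(0.0)

    def test_matches_direct_formula(self):
        a, b, c, d = 7, 3, 4, 9
        res = chi_square_2x2(a, b, c, d)
        n = a + b + c + d
        total = 0.0
        for obs, (r, col) in zip(
            [a, b, c, d], [(a + b, a + c), (a + b, b + d), (c + d, a + c), (c + d, b + d)]
        ):
            e = r * col / n
            total += (obs - e) ** 2 / e
        assert res.statistic == pytest.approx(total)

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateInputError):
            chi_square_2x2(0, 0, 5, 5)


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(5.0)
        assert pearson_r(x, x).statistic == pytest.approx(1.0)

    def test_matches_sum_formula(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        res = pearson_r(x, y)
        n = 20
        r = (n * (x * y).sum() - x.sum() * y.sum()) / np.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        assert res.statistic == pytest.approx(r, rel=1e-10)
        assert res.df == 18

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestBonferroni:
    def test_multiply_and_cap(self):
        assert np.allclose(bonferroni([0.01, 0.2], 2), [0.02, 0.4])
        assert np.allclose(bonferroni([0.6], 4), [1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=8),
        st.integers(min_value=8, max_value=20),
    )
    def test_monotone(self, ps, m):
        adj = bonferroni(ps, m)
        order = np.argsort(ps)
        assert (np.diff(np.asarray(adj)[order]) >= -1e-15).all()

    def test_family_too_small(self):
        with pytest.raises(InvalidArgumentError):
            bonferroni([0.1, 0.2, 0.3], 2)


class TestStandardizedRegression:
    def test_identity_with_orthogonal_second_predictor(self):
        x1 = np.arange(1.0, 9.0)
        x2 = np.array([1.0, -1.0] * 4)  # orthogonal to centred x1
        y = (x1 - x1.mean()) / x1.std(ddof=1)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        res = standardized_regression(y, X)
        assert res.beta("x1") == pytest.approx(1.0)
        assert res.beta("x2") == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_six_point_normal_equations(self):
        X = pd.DataFrame(
            {"a": [1.0, 2, 3, 4, 5, 6], "b": [2.0, 1, 4, 3, 6, 5]}
        )
        y = np.array([1.0, 3, 2, 5, 4, 6])

        def z(v):
            return (v - v.mean()) / v.std(ddof=1)

        res = standardized_regression(y, X)
        Z = np.column_stack([np.ones(6), z(X["a"].to_numpy()), z(X["b"].to_numpy())])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ z(y))
        assert res.beta("a") == pytest.approx(beta[1], rel=1e-10)
        assert res.beta("b") == pytest.approx(beta[2], rel=1e-10)

    def test_affine_invariance_of_inputs(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=20)
        base = standardized_regression(y, X)
        X2 = X.copy()
        X2["b"] = 100.0 * X2["b"] - 3.0
        res = standardized_regression(5.0 * y + 2.0, X2)
        for col in X.columns:
            assert res.beta(col) == pytest.approx(base.beta(col), rel=1e-9)
        assert res.r_squared == pytest.approx(base.r_squared, rel=1e-9)

    def test_orthogonal_betas_bounded_by_one(self, rng):
        n = 24
        q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        y = rng.normal(size=n)
        res = standardized_regression(y, X)
        for col in X.columns:
            assert abs(res.beta(col)) <= 1.0 + 1e-9

    def test_null_r_squared_expectation(self):
        # under the null, E[R^2] = k / (n - 1)
        n, k, reps = 40, 3, 300
        rng = np.random.default_rng(2024)
        r2 = []
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(n, k)), columns=list("abc"))
            y = rng.normal(size=n)
            r2.append(standardized_regression(y, X).r_squared)
        assert np.mean(r2) == pytest.approx(k / (n - 1), abs=0.015)

    def test_collinearity_error_names_columns(self, rng):
        a = rng.normal(size=15)
        X = pd.DataFrame({"a": a, "b": 2.0 * a, "c": rng.normal(size=15)})
        with pytest.raises(CollinearityError) as err:
            standardized_regression(rng.normal(size=15), X)
        assert {"a", "b"} <= set(err.value.columns)

    def test_paper_consistent_dof(self, rng):
        # 18 subjects, 5 predictors -> F(5, 12), per-coefficient df 12
        X = pd.DataFrame(rng.normal(size=(18, 5)), columns=list("abcde"))
        y = rng.normal(size=18)
        res = standardized_regression(y, X)
        assert (res.df_model, res.df_resid) == (5, 12)
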