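import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from faaverse.stats import (
    bca_ci,
    bf01_correlation,
    bf01_ttest,
    binomial_meta,
    chi2_two_proportions,
    cohen_d,
    jzs_bf10_from_t,
    levene,
    regression_t,
    residualize,
    welch_t,
)


class TestWelchT:
    def test_identical_samples_give_zero_t_unit_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_t(x, x.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_reduces_to_student_t_for_equal_n_and_variance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 0.8  # same variance, equal n
        res = welch_t(x, y)
        student = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(student.statistic)
        assert res.df == pytest.approx(2 * len(x) - 2)

    def test_matches_hand_welch_formula(self, rng):
        x = rng.normal(0, 1, 5)
        y = rng.normal(1, 2, 5)
        res = welch_t(x, y)
        se2 = x.var(ddof=1) / 5 + y.var(ddof=1) / 5
        t = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2 ** 2 / ((x.var(ddof=1) / 5) ** 2 / 4 + (y.var(ddof=1) / 5) ** 2 / 4)
        assert res.statistic == pytest.approx(t)
        assert res.df == pytest.approx(df)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), df))
        sp = np.sqrt((4 * x.var(ddof=1) + 4 * y.var(ddof=1)) / 8)
        assert res.effect_size == pytest.approx((x.mean() - y.mean()) / sp)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(0, 1, 6), r.normal(0.5, 2, 9)
        a, b = welch_t(x, y), welch_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([2.0, 2.0], [3.0, 3.0])


class TestRegressionT:
    def test_binary_predictor_equals_pooled_t(self, rng):
        y = rng.normal(size=12)
        x = np.array([1.0] * 5 + [0.0] * 7)
        res = regression_t(y, x)
        pooled = sps.ttest_ind(y[x == 1], y[x == 0], equal_var=True)
        assert res.statistic == pytest.approx(pooled.statistic)
        assert res.p == pytest.approx(pooled.pvalue)
        assert res.effect_kind == "pearson_r"

    def test_matches_normal_equation_hand_solve_with_confound(self, rng):
        y = rng.normal(size=10)
        x = rng.normal(size=10)
        c = rng.normal(size=10)
        res = regression_t(y, x, pd.DataFrame({"c": c}))
        X = np.column_stack([np.ones(10), x, c])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (10 - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        assert res.statistic == pytest.approx(t)
        assert res.df == 7
        assert res.effect_size == pytest.approx(t / np.sqrt(t * t + 7))
        assert res.effect_kind == "partial_r"

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(99)
        ps = [regression_t(rng.normal(size=20), rng.normal(size=20)).p
              for _ in range(300)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_rows_dropped_and_counted(self, rng):
        y = rng.normal(size=12)
        x = rng.normal(size=12)
        c = rng.normal(size=12)
        c[3] = np.nan
        res = regression_t(y, x, pd.DataFrame({"c": c}))
        assert res.n == 11 and res.n_dropped == 1

    def test_rank_deficiency_and_small_n_error(self, rng):
        x = rng.normal(size=6)
        with pytest.raises(ValueError, match="rank"):
            regression_t(rng.normal(size=6), x, pd.DataFrame({"c": 2 * x}))
        with pytest.raises(ValueError):
            regression_t([1.0, 2.0], [0.0, 1.0])


class TestResidualize:
    def test_intercept_only_demeans(self, rng):
        y = rng.normal(size=8)
        out = residualize(y, pd.DataFrame(index=range(8)))
        assert np.allclose(out, y - y.mean())

    def test_orthogonal_outcome_unchanged(self, rng):
        c = rng.normal(size=30)
        y = rng.normal(size=30)
        X = np.column_stack([np.ones(30), c])
        y_orth = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        out = residualize(y_orth, pd.DataFrame({"c": c}))
        assert np.allclose(out, y_orth, atol=1e-10)

    def test_matches_projection_matrix_and_orthogonality(self, rng):
        y = rng.normal(size=15)
        C = rng.normal(size=(15, 2))
        out = residualize(y, pd.DataFrame(C))
        X = np.column_stack([np.ones(15), C])
        P = X @ np.linalg.inv(X.T @ X) @ X.T
        assert np.allclose(out, (np.eye(15) - P) @ y)
        assert np.abs(out @ C).max() < 1e-10
        assert abs(out.sum()) < 1e-10


class TestBCa:
    def test_deterministic_and_contains_estimate(self, rng):
        x = rng.normal(size=40)
        a = bca_ci(x, np.mean, n_boot=999, seed=7)
        b = bca_ci(x, np.mean, n_boot=999, seed=7)
        assert a == b
        assert a[0] < x.mean() < a[1]

    def test_close_to_t_interval_for_large_normal_sample(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 300)
        lo, hi = bca_ci(x, np.mean, n_boot=4000, seed=1)
        t_lo, t_hi = sps.t.interval(0.95, len(x) - 1, loc=x.mean(),
                                    scale=sps.sem(x))
        assert lo == pytest.approx(t_lo, abs=0.02)
        assert hi == pytest.approx(t_hi, abs=0.02)

    def test_symmetric_statistic_small_bias_correction(self):
        # symmetric data, symmetric statistic: interval ~ symmetric around 0
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200)
        x = np.concatenate([x, -x])  # exactly symmetric sample, mean 0
        lo, hi = bca_ci(x, np.mean, n_boot=3000, seed=2)
        assert abs((hi + lo) / 2) < 0.015

    def test_degenerate_collapses_to_point_with_warning(self):
        x = np.ones(12)
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bca_ci(x, np.mean, n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_two_sample_statistic(self, rng):
        x, y = rng.normal(1, 1, 25), rng.normal(0, 1, 30)
        lo, hi = bca_ci((x, y), cohen_d, n_boot=999, seed=4)
        assert lo < cohen_d(x, y) < hi


class TestBayesFactors:
    def test_null_favoring_direction_and_limits(self, rng):
        x = rng.normal(0, 1, 30)
        x = x - x.mean()  # t exactly 0
        assert bf01_ttest(x) > 3
        y = rng.normal(4, 1, 30)
        assert bf01_ttest(x, y) < 0.01

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 25)
        t = sps.ttest_ind(x, y, equal_var=True).statistic
        ours = bf01_ttest(x, y)
        theirs = 1.0 / float(pingouin.bayesfactor_ttest(t, 20, 25))
        assert ours == pytest.approx(theirs, rel=1e-8)

    def test_correlation_bf_direction_and_pingouin_agreement(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=25)
        y_null = rng.normal(size=25)
        assert bf01_correlation(x, y_null) > 0.3  # typically favours null
        y_strong = x + 0.1 * rng.normal(size=25)
        assert bf01_correlation(x, y_strong) < 0.01
        r = float(np.corrcoef(x, y_null)[0, 1])
        theirs = 1.0 / float(pingouin.bayesfactor_pearson(r, 25))
        assert bf01_correlation(x, y_null) == pytest.approx(theirs, rel=1e-6)

    def test_correlation_preconditions(self):
        with pytest.raises(ValueError):
            bf01_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            bf01_correlation([1.0] * 10, list(range(10)))


class TestBinomialMeta:
    def test_zero_significant_gives_one(self):
        assert binomial_meta(0, 40) == pytest.approx(1.0)

    def test_matches_exact_tail_sum(self):
        k, n, p0 = 4, 25, 0.05
        tail = sum(sps.binom.pmf(i, n, p0) for i in range(k, n + 1))
        assert binomial_meta(k, n, p0) == pytest.approx(tail, rel=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(1, 60))
    def test_non_increasing_in_k(self, n):
        ps = [binomial_meta(k, n) for k in range(n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            binomial_meta(5, 4)


class TestChi2TwoProportions:
    def test_equal_proportions_zero_statistic(self):
        res = chi2_two_proportions(6, 24, 4, 16)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)
        same = chi2_two_proportions(7, 20, 7, 20)
        assert same.statistic == 0.0

    def test_matches_expected_count_hand_formula(self):
        k1, n1, k2, n2 = 8, 20, 3, 25
        res = chi2_two_proportions(k1, n1, k2, n2)
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]], float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(chi2)
        assert res.df == 1.0
        assert res.p == pytest.approx(sps.chi2.sf(chi2, 1))

    def test_empty_margin_errors(self):
        with pytest.raises(ValueError):
            chi2_two_proportions(0, 10, 0, 10)


class TestLevene:
    def test_identical_groups_give_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = levene([g, list(g)])
        assert res.statistic == pytest.approx(0.0)

    def test_within_group_permutation_invariance(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 3, 12)
        r1 = levene([a, b])
        r2 = levene([a[::-1], rng.permutation(b)])
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_matches_anova_on_absolute_deviations(self, rng):
        groups = [rng.normal(0, s, n) for s, n in [(1, 8), (2, 10), (0.5, 7)]]
        res = levene(groups)
        z = [np.abs(g - g.mean()) for g in groups]
        f = sps.f_oneway(*z)
        assert res.statistic == pytest.approx(f.statistic)
        assert res.p == pytest.approx(f.pvalue)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            levene([[1.0], [1.0, 2.0]])


def test_jzs_bf_monotone_in_evidence():
    bfs = [1 / jzs_bf10_from_t(t, 25, 25) for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
    assert all(a > b for a, b in zip(bfs, bfs[1:]))
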