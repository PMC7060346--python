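import numpy as np
import pandas as pd
import pytest

from cardiogate import (InvalidInputError, PriorSpec, bf_pearson,
                        bf_regression, bf_robustness, bf_ttest,
                        correlation_matrix, ols_enter, paired_t, pearson,
                        wilcoxon_signed_rank)
from cardiogate.errors import InvalidParameterError

from _oracles import (bf_pearson_closed_form, bf_pearson_grid,
                      bf_regression_grid, bf_ttest_grid, wilcoxon_exact_p)


class TestPairedT:
    def test_hand_arithmetic(self):
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0], with_bf=False)
        assert res.estimate == pytest.approx(2.0)
        assert res.statistic == pytest.approx(3.4641016, abs=1e-6)
        assert res.df == 2

    def test_ci_contains_estimate(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = paired_t(x, y, with_bf=False)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_zero_variance_degenerate(self):
        with pytest.raises(InvalidInputError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_matches_scipy(self, rng):
        from scipy import stats as sps
        x, y = rng.normal(size=15), rng.normal(size=15)
        res = paired_t(x, y, with_bf=False)
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestWilcoxon:
    def test_all_positive_differences(self):
        res = wilcoxon_signed_rank([2, 4, 6, 8, 10.0], [1, 2, 3, 4, 5.0])
        assert res.statistic == 15.0           # W+ = n(n+1)/2
        assert res.p == pytest.approx(2 / 32)  # two-sided from 1/2^5 one-sided
        assert res.extra["p_mode"] == "exact"

    def test_antisymmetric_differences_centre(self):
        x = np.array([1.0, 2.0, 3.0, -1.0, -2.0, -3.0]) + 10
        res = wilcoxon_signed_rank(x, np.full(6, 10.0))
        assert res.statistic == pytest.approx(6 * 7 / 4)
        assert res.p > 0.9

    def test_exact_matches_enumeration(self, rng):
        d = rng.normal(0.3, 1.0, size=10)
        d = d[d != 0]
        res = wilcoxon_signed_rank(d + 5.0, np.full(d.size, 5.0))
        assert res.p == pytest.approx(wilcoxon_exact_p(d), abs=1e-9)

    def test_exact_close_to_normal_approx_n20(self, rng):
        from scipy import stats as sps
        d = rng.normal(0.2, 1.0, size=20)
        p_exact = sps.wilcoxon(d, method="exact").pvalue
        p_approx = sps.wilcoxon(d, method="approx", correction=False).pvalue
        assert abs(p_exact - p_approx) < 0.02


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1, with_bf=False).estimate == pytest.approx(1.0)

    def test_hand_value(self):
        res = pearson([1, 2, 3, 4.0], [2, 1, 4, 3.0], with_bf=False)
        assert res.estimate == pytest.approx(0.6)

    def test_symmetry_and_t_transform(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        a = pearson(x, y, with_bf=False)
        b = pearson(y, x, with_bf=False)
        assert a.estimate == pytest.approx(b.estimate)
        from scipy import stats as sps
        r, n = a.estimate, a.n
        t = r * np.sqrt((n - 2) / (1 - r * r))
        assert a.p == pytest.approx(2 * sps.t.sf(abs(t), n - 2), rel=1e-12)

    def test_pairwise_deletion_effective_n(self):
        x = np.array([1, 2, 3, 4, np.nan, 6.0])
        y = np.array([2, 1, 4, 3, 5.0, np.nan])
        res = pearson(x, y, with_bf=False)
        assert res.n == 4


class TestOlsEnter:
    def test_exact_fit(self, rng):
        X = rng.normal(size=(20, 2))
        y = 1.0 + X @ [2.0, -1.0]
        res = ols_enter(y, X, with_bf=False)
        assert res.estimate == pytest.approx(1.0)

    def test_df_convention(self, rng):
        X = rng.normal(size=(41, 2))
        y = rng.normal(size=41)
        res = ols_enter(y, X, with_bf=False)
        assert res.df == (2, 38)

    def test_rank_deficiency_rejected(self, rng):
        X = np.column_stack([rng.normal(size=15), np.zeros(15)])
        with pytest.raises(InvalidInputError):
            ols_enter(rng.normal(size=15), X)


class TestBayesFactorTTest:
    @pytest.mark.parametrize("t, n, printed", [
        (0.583, 41, 0.198), (-1.553, 41, 0.510), (0.390, 41, 0.181)])
    def test_published_values(self, t, n, printed):
        assert bf_ttest(t, n) == pytest.approx(printed, rel=0.01)

    def test_sign_symmetry(self):
        for t in (0.4, 1.3, 2.7):
            assert bf_ttest(t, 30) == pytest.approx(bf_ttest(-t, 30), rel=1e-9)

    def test_null_t_matches_grid_oracle(self):
        assert bf_ttest(0.0, 41) < 1.0
        assert bf_ttest(0.0, 41) == pytest.approx(bf_ttest_grid(0.0, 41),
                                                  rel=1e-5)

    def test_raw_columns_equal_summary_path(self, rng):
        x = rng.normal(0.3, 1.0, size=25)
        y = rng.normal(0.0, 1.0, size=25)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert bf_ttest(x=x, y=y) == bf_ttest(t, 25)


class TestBayesFactorPearson:
    @pytest.mark.parametrize("r, n, printed", [
        (-0.438, 41, 10.214), (-0.398, 40, 4.495), (0.354, 41, 2.331),
        (0.439, 41, 10.450), (0.361, 41, 2.598)])
    def test_published_values(self, r, n, printed):
        assert bf_pearson(r, n) == pytest.approx(printed, rel=0.01)

    def test_sign_symmetry(self):
        assert bf_pearson(0.35, 30) == pytest.approx(bf_pearson(-0.35, 30),
                                                     rel=1e-8)

    def test_null_r_matches_grid_oracle(self):
        assert bf_pearson(0.0, 41) < 1.0
        assert bf_pearson(0.0, 41) == pytest.approx(bf_pearson_grid(0.0, 41),
                                                    rel=1e-5)

    def test_boundary_overflows(self):
        assert bf_pearson(1.0, 20) == np.inf

    def test_closed_form_cross_check(self):
        """The quadrature agrees with the analytic hypergeometric solution
        of the default correlation test."""
        for r, n in [(-0.438, 41), (0.2, 15), (0.7, 30)]:
            assert bf_pearson(r, n) == pytest.approx(
                bf_pearson_closed_form(r, n), rel=1e-8)

    def test_raw_columns_equal_summary_path(self, rng):
        x = rng.normal(size=18)
        y = 0.4 * x + rng.normal(size=18)
        r = float(np.corrcoef(x, y)[0, 1])
        assert bf_pearson(x=x, y=y) == bf_pearson(r, 18)


class TestBayesFactorRegression:
    def test_published_value(self):
        assert bf_regression(1.153, 41, 2) == pytest.approx(0.311, rel=0.02)

    def test_null_f_favours_null(self):
        assert bf_regression(0.0, 41, 2) < 1.0

    def test_monotone_in_f(self):
        vals = [bf_regression(f, 41, 2) for f in (0.0, 0.5, 1.0, 2.0, 5.0, 10.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        for f in (0.5, 2.0, 10.0):
            assert bf_regression(f, 41, 2) == pytest.approx(
                bf_regression_grid(f, 41, 2), rel=1e-4)

    def test_invalid_df_rejected(self):
        with pytest.raises(InvalidParameterError):
            bf_regression(1.0, 3, 2)


@pytest.mark.parametrize("kind, stat, n, k, oracle", [
    ("ttest", 0.583, 41, None, bf_ttest_grid),
    ("ttest", -2.5, 20, None, bf_ttest_grid),
    ("ttest", 3.2, 10, None, bf_ttest_grid),
    ("pearson", -0.438, 41, None, bf_pearson_grid),
    ("pearson", 0.6, 12, None, bf_pearson_grid),
    ("pearson", 0.05, 80, None, bf_pearson_grid),
    ("regression", 1.153, 41, 2, bf_regression_grid),
    ("regression", 4.0, 30, 3, bf_regression_grid),
])
def test_integrators_match_grid_oracle(kind, stat, n, k, oracle):
    """Every Bayes-factor family agrees with an independent fixed-grid
    quadrature to better than 1e-4 relative error."""
    if kind == "ttest":
        got, want = bf_ttest(stat, n), oracle(stat, n)
    elif kind == "pearson":
        got, want = bf_pearson(stat, n), oracle(stat, n)
    else:
        got, want = bf_regression(stat, n, k), oracle(stat, n, k)
    assert got == pytest.approx(want, rel=1e-4)


def test_bf_cross_check_against_pingouin():
    """Independent implementation check: pingouin's analytic default
    Bayes factors agree with the quadrature for t and r."""
    pingouin = pytest.importorskip("pingouin")
    got_t = bf_ttest(0.583, 41)
    want_t = float(pingouin.bayesfactor_ttest(0.583, 41, paired=True))
    assert got_t == pytest.approx(want_t, rel=1e-3)
    got_r = bf_pearson(-0.438, 41)
    want_r = float(pingouin.bayesfactor_pearson(-0.438, 41))
    assert got_r == pytest.approx(want_r, rel=1e-3)


class TestRobustness:
    def test_width_to_zero_drives_bf_to_one(self):
        pairs = bf_robustness(1.2, 30, "ttest", [1e-4, 0.01])
        assert pairs[0][1] == pytest.approx(1.0, abs=5e-3)

    def test_null_t_decreasing_in_width(self):
        bfs = [b for _, b in bf_robustness(0.0, 30, "ttest",
                                           [0.1, 0.3, 0.707, 1.0, 1.5])]
        assert all(a > b for a, b in zip(bfs, bfs[1:]))

    def test_default_width_consistency(self):
        (_, b), = bf_robustness(0.583, 41, "ttest", [1 / np.sqrt(2)])
        assert b == bf_ttest(0.583, 41)


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        m = correlation_matrix(df, ["a", "b"], ["a", "b", "c"], with_bf=False)
        diag = m[(m.var1 == "a") & (m.var2 == "a")].iloc[0]
        assert diag.r == 1.0
        ab = m[(m.var1 == "a") & (m.var2 == "b")].iloc[0].r
        ba = m[(m.var1 == "b") & (m.var2 == "a")].iloc[0].r
        assert ab == pytest.approx(ba)

    def test_missing_values_reduce_cell_n(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=41), "y": rng.normal(size=41)})
        df.loc[0, "x"] = np.nan   # one subject lacks the index
        m = correlation_matrix(df, ["x"], ["y"], with_bf=False)
        assert m.iloc[0].n == 40

    def test_degenerate_cell_is_nan(self):
        df = pd.DataFrame({"x": [1.0, np.nan, np.nan, 4.0],
                           "y": [2.0, 1.0, 3.0, 4.0]})
        m = correlation_matrix(df, ["x"], ["y"], with_bf=False)
        assert np.isnan(m.iloc[0].r) and m.iloc[0].n == 2
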