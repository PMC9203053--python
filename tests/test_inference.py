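"""Inferential statistics against brute-force recomputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import retromem as rm


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_rm_anova_F(wide: np.ndarray) -> tuple[float, float, float]:
    """One-way repeated-measures F from explicit sums of squares."""
    n, k = wide.shape
    grand = wide.mean()
    ss_cond = n * np.sum((wide.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((wide.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((wide - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    return (ss_cond / df1) / (ss_err / df2), df1, df2


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def brute_partial_r(x, y, z):
    rx = x - np.polyval(np.polyfit(z, x, 1), z)
    ry = y - np.polyval(np.polyfit(z, y, 1), z)
    return np.corrcoef(rx, ry)[0, 1]


# ---------------------------------------------------------------------------
# RM-ANOVA
# ---------------------------------------------------------------------------

class TestRmAnova:
    def test_identical_conditions_give_zero_F(self):
        rng = np.random.default_rng(0)
        col = rng.random(12)
        scores = pd.DataFrame({"a": col, "b": col})
        res = rm.rm_anova_hf(scores)
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            wide = rng.random((12, 5))
            scores = pd.DataFrame(wide, columns=list("abcde"))
            res = rm.rm_anova_hf(scores)
            F, df1, df2 = brute_rm_anova_F(wide)
            assert res.F == pytest.approx(F, rel=1e-10)

    def test_hand_worked_small_table(self):
        # 3 subjects x 4 conditions, worked through the SS decomposition
        wide = np.array(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 5.0, 5.0], [0.0, 1.0, 2.0, 2.0]]
        )
        F, df1, df2 = brute_rm_anova_F(wide)
        res = rm.rm_anova_hf(pd.DataFrame(wide, columns=list("wxyz")))
        assert res.F == pytest.approx(F, abs=1e-10)
        assert (res.df_num, res.df_den) == (
            pytest.approx(df1 * res.epsilon),
            pytest.approx(df2 * res.epsilon),
        )

    def test_compound_symmetry_keeps_epsilon_near_one(self):
        rng = np.random.default_rng(2)
        subj = rng.standard_normal((60, 1))
        wide = subj + 0.5 * rng.standard_normal((60, 5))
        res = rm.rm_anova_hf(pd.DataFrame(wide, columns=list("abcde")),
                             always_correct=True)
        assert res.epsilon > 0.9
        F, df1, df2 = brute_rm_anova_F(wide)
        assert res.F == pytest.approx(F, rel=1e-10)

    def test_epsilon_one_equals_uncorrected(self):
        rng = np.random.default_rng(3)
        wide = rng.random((10, 4))
        scores = pd.DataFrame(wide, columns=list("abcd"))
        res = rm.rm_anova_hf(scores, always_correct=False, sphericity_alpha=1e-30)
        F, df1, df2 = brute_rm_anova_F(wide)
        assert res.epsilon == 1.0
        assert res.p == pytest.approx(stats.f.sf(F, df1, df2), rel=1e-10)

    def test_rejects_missing_cells(self):
        scores = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, np.nan, 2.0]})
        with pytest.raises(ValueError, match="missing"):
            rm.rm_anova_hf(scores)


# ---------------------------------------------------------------------------
# pairwise t with FDR
# ---------------------------------------------------------------------------

class TestPairwiseTFdr:
    def test_identical_columns_adjust_to_one(self):
        rng = np.random.default_rng(4)
        col = rng.random(10)
        scores = pd.DataFrame({"a": col, "b": col, "c": col})
        tab = rm.pairwise_t_fdr(scores)
        assert (tab["p_fdr"] == 1.0).all()

    def test_equal_raw_ps_are_bh_fixed_point(self):
        # shifting by a constant with identical noise gives equal raw p-values
        base = np.arange(10, dtype=float)
        scores = pd.DataFrame({"a": base, "b": base + 1.0, "c": base + 2.0})
        tab = rm.pairwise_t_fdr(scores)
        degenerate = tab["degenerate"]
        assert degenerate.all()  # constant differences
        assert (tab.loc[degenerate, "p_fdr"] == 0.0).all()

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(5)
        wide = rng.random((15, 5))
        scores = pd.DataFrame(wide, columns=list("abcde"))
        tab = rm.pairwise_t_fdr(scores)
        assert len(tab) == 10  # one family of all condition pairs
        expected = brute_bh(tab["p_unc"].to_numpy())
        assert np.allclose(tab["p_fdr"].to_numpy(), expected, atol=1e-12)

    def test_monotone_in_raw_order(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(rng.random((12, 5)), columns=list("abcde"))
        tab = rm.pairwise_t_fdr(scores).sort_values("p_unc")
        assert (np.diff(tab["p_fdr"].to_numpy()) >= -1e-15).all()


# ---------------------------------------------------------------------------
# item regression
# ---------------------------------------------------------------------------

class TestItemRegression:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 1, 20)
        fit = rm.item_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.slope_p < 1e-10

    def test_standardized_slope_equals_pearson_r(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        fit = rm.item_regression(xs, ys)
        assert fit.slope == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_band_contains_line_and_narrowest_at_mean(self):
        rng = np.random.default_rng(8)
        x = rng.random(30)
        y = x + 0.3 * rng.standard_normal(30)
        fit = rm.item_regression(x, y)
        assert (fit.band_lower <= fit.y_hat + 1e-12).all()
        assert (fit.band_upper >= fit.y_hat - 1e-12).all()
        width = fit.band_upper - fit.band_lower
        assert abs(fit.x_grid[np.argmin(width)] - x.mean()) < np.ptp(x) / 8

    def test_null_slope_p_uniform(self):
        """Under independence the slope p-value is uniform (KS check)."""
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(500):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            ps.append(rm.item_regression(x, y).slope_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            rm.item_regression(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

class TestPartialCorrelation:
    def test_irrelevant_covariate_keeps_r(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(500)
        y = 0.6 * x + rng.standard_normal(500)
        z = rng.standard_normal(500)
        r_partial, _ = rm.partial_correlation(x, y, z)
        assert r_partial == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.05)

    def test_y_equal_z_gives_zero(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(50)
        z = rng.standard_normal(50)
        r_partial, _ = rm.partial_correlation(x, z.copy(), z)
        assert r_partial == pytest.approx(0.0, abs=1e-8)

    def test_matches_residual_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x, y, z = rng.standard_normal((3, 25))
            r_partial, _ = rm.partial_correlation(x, y, z)
            assert r_partial == pytest.approx(brute_partial_r(x, y, z), abs=1e-12)

    def test_collinear_covariate_rejected(self):
        z = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            rm.partial_correlation(2 * z + 1, np.random.default_rng(0).random(10), z)
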