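"""Supporting inferential statistics: repeated-measures ANOVA with
Huynh–Feldt correction, FDR-corrected pairwise t-tests, item-level OLS with
confidence bands, and partial correlations.

These are standard procedures; they are delegated to pingouin, scipy and
statsmodels and assembled into the result containers the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "RegressionFit",
    "rm_anova_hf",
    "pairwise_t_fdr",
    "item_regression",
    "partial_correlation",
]


@dataclass
class AnovaResult:
    F: float
    df_num: float
    df_den: float
    epsilon: float  # Huynh–Feldt epsilon actually applied (1 if uncorrected)
    p: float
    sphericity_p: float  # Mauchly test p-value
    corrected: bool


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_p: float
    intercept_p: float
    r: float
    x_grid: np.ndarray
    y_hat: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray


def rm_anova_hf(
    scores: pd.DataFrame,
    always_correct: bool = False,
    sphericity_alpha: float = 0.05,
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subject × condition table.

    The Huynh–Feldt epsilon rescales both degrees of freedom when a Mauchly
    sphericity test rejects at ``sphericity_alpha`` (or always, under the
    flag); epsilon is clamped to at most 1.
    """
    if scores.isna().any().any():
        raise ValueError("scores table has missing cells; complete cases required")
    if scores.shape[1] < 2 or scores.shape[0] < 3:
        raise ValueError("need >=2 conditions and >=3 subjects")
    wide = scores.reset_index(drop=True)
    long = wide.reset_index(names="subject").melt(
        id_vars="subject", var_name="condition", value_name="score"
    )
    aov = pg.rm_anova(
        data=long, dv="score", within="condition", subject="subject",
        correction=False, detailed=True,
    )
    df_num = float(aov.loc[0, "DF"])
    df_den = float(aov.loc[1, "DF"])
    # pingouin omits F when the error mean square is 0 (identical columns)
    F = float(aov.loc[0, "F"]) if "F" in aov.columns else np.nan
    if not np.isfinite(F):
        F = 0.0 if np.isclose(float(aov.loc[0, "SS"]), 0.0) else np.inf
    spher = pg.sphericity(
        data=long, dv="score", within="condition", subject="subject"
    )
    sphericity_p = float(getattr(spher, "pval", spher[-1]))
    eps_hf = float(
        pg.epsilon(
            data=long, dv="score", within="condition",
            subject="subject", correction="hf",
        )
    )
    eps_hf = min(eps_hf, 1.0) if np.isfinite(eps_hf) else 1.0
    if not np.isfinite(sphericity_p):
        sphericity_p = 1.0
    apply_correction = always_correct or sphericity_p < sphericity_alpha
    eps = eps_hf if apply_correction else 1.0
    p = float(stats.f.sf(F, df_num * eps, df_den * eps))
    return AnovaResult(
        F=F, df_num=df_num * eps, df_den=df_den * eps,
        epsilon=eps, p=p, sphericity_p=sphericity_p,
        corrected=apply_correction,
    )


def pairwise_t_fdr(scores: pd.DataFrame) -> pd.DataFrame:
    """All within-subject paired t-tests with Benjamini–Hochberg adjustment.

    One family per call (the 10 condition pairs of a 5-condition design).
    A zero-variance difference yields p = 1 when the mean difference is 0
    and is otherwise flagged degenerate (p = 0, ``degenerate`` column True).
    """
    conds = list(scores.columns)
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions")
    rows = []
    for a, b in combinations(conds, 2):
        d = scores[a].to_numpy(dtype=float) - scores[b].to_numpy(dtype=float)
        degenerate = False
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(d.mean()), 0.0
                degenerate = True
        else:
            t, p = stats.ttest_rel(scores[a], scores[b])
        rows.append(
            {
                "A": a,
                "B": b,
                "mean_diff": float(d.mean()),
                "t": float(t),
                "p_unc": float(p),
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = multipletests(table["p_unc"], method="fdr_bh")[1]
    return table


def item_regression(x, y, conf_level: float = 0.95, n_grid: int = 50) -> RegressionFit:
    """OLS of a per-pair outcome on relatedness, with a pointwise t-based
    confidence band over the observed predictor range."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >=3 aligned (x, y) observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    x_grid = np.linspace(x.min(), x.max(), n_grid)
    pred = fit.get_prediction(sm.add_constant(x_grid))
    band = pred.conf_int(alpha=1.0 - conf_level)
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        slope_p=float(fit.pvalues[1]),
        intercept_p=float(fit.pvalues[0]),
        r=r,
        x_grid=x_grid,
        y_hat=pred.predicted_mean,
        band_lower=band[:, 0],
        band_upper=band[:, 1],
    )


def partial_correlation(x, y, z) -> tuple[float, float]:
    """Correlation of x and y after removing the linear effect of z.

    Equivalent to correlating the residuals of x~z and y~z; the p-value is
    the t-based test with n−3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size) or x.size < 4:
        raise ValueError("need >=4 aligned (x, y, z) observations")
    if np.ptp(z) > 0 and abs(np.corrcoef(x, z)[0, 1]) >= 1.0 - 1e-12:
        raise ValueError("x is collinear with the covariate")
    # a response fully explained by the covariate has no residual variance:
    # the partial correlation is degenerate and reported as 0
    ry = y - np.polyval(np.polyfit(z, y, 1), z) if np.ptp(z) > 0 else y - y.mean()
    if np.std(ry) < 1e-12 * max(np.std(y), 1.0):
        return 0.0, 1.0
    df = pd.DataFrame({"x": x, "y": y, "z": z})
    res = pg.partial_corr(data=df, x="x", y="y", covar="z")
    pcol = "p_val" if "p_val" in res.columns else "p-val"
    return float(res["r"].iloc[0]), float(res[pcol].iloc[0])
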