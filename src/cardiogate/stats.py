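"""Frequentist tests with default-prior Bayesian counterparts.

Every cell of a results table is a :class:`StatResult`: estimate, test
statistic, degrees of freedom, two-tailed p, 95% confidence bounds where
defined, and the matching default-prior Bayes factor. The frequentist
machinery delegates to scipy/statsmodels; the Bayes factors come from
:mod:`cardiogate.bayes`. Missing values are handled by pairwise deletion
with the effective n recorded per cell, and no multiple-comparison
correction is applied anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from . import bayes
from .errors import InsufficientDataError, InvalidInputError
from .bayes import PriorSpec, DEFAULT_PRIOR

__all__ = ["StatResult", "paired_t", "wilcoxon_signed_rank", "pearson",
           "ols_enter", "correlation_matrix"]


@dataclass(frozen=True)
class StatResult:
    method: str
    estimate: float
    statistic: float
    df: object                  # float, or (df1, df2) for F tests
    p: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    bf10: Optional[float] = None
    n: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"method": self.method, "estimate": self.estimate,
             "statistic": self.statistic, "p": self.p,
             "ci_low": self.ci_low, "ci_high": self.ci_high,
             "bf10": self.bf10, "n": self.n}
        if isinstance(self.df, tuple):
            d["df1"], d["df2"] = self.df
        else:
            d["df"] = self.df
        d.update(self.extra)
        return d


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("paired samples must be aligned")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def paired_t(x, y, prior: PriorSpec = DEFAULT_PRIOR,
             with_bf: bool = True) -> StatResult:
    """Two-tailed repeated-measures t-test with 95% CI of the mean
    difference and the JZS Bayes factor."""
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise InsufficientDataError("paired t needs n >= 3 complete pairs")
    d = x - y
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise InvalidInputError("zero variance of the differences")
    est = float(np.mean(d))
    se = sd / sqrt(n)
    t = est / se
    df = n - 1
    p = 2 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    bf = bayes.bf_ttest(t, n, scale=prior.t_scale) if with_bf else None
    return StatResult("paired_t", est, float(t), df, float(p),
                      est - tcrit * se, est + tcrit * se, bf, n)


def wilcoxon_signed_rank(x, y) -> StatResult:
    """Wilcoxon signed-rank test of paired differences.

    Reports W+ (sum of ranks of positive differences, ties mid-ranked,
    zero differences dropped) as the statistic; p is exact for n <= 25
    without ties, else a tie-corrected normal approximation. A z
    approximation is recorded in ``extra`` alongside.
    """
    x, y = _paired(x, y)
    d = (x - y)[x != y]
    n = d.size
    if n < 5:
        raise InsufficientDataError("Wilcoxon needs >= 5 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    mode = "exact" if (n <= 25 and np.unique(np.abs(d)).size == n) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=False, method=mode)
    mu = n * (n + 1) / 4
    sigma = sqrt(n * (n + 1) * (2 * n + 1) / 24)
    z = (w_plus - mu) / sigma
    return StatResult("wilcoxon", float(np.median(d)), w_plus, np.nan,
                      float(res.pvalue), n=n, extra={"z_approx": z, "p_mode": mode})


def pearson(x, y, prior: PriorSpec = DEFAULT_PRIOR,
            with_bf: bool = True) -> StatResult:
    """Two-tailed Pearson correlation with pairwise deletion and the
    default stretched-beta Bayes factor at the effective n."""
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise InsufficientDataError("Pearson needs >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidInputError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) < 1:
        t = r * sqrt(df / (1 - r * r))
        p = 2 * sps.t.sf(abs(t), df)
    else:
        t, p = np.inf * np.sign(r), 0.0
    bf = bayes.bf_pearson(r, n, width=prior.corr_width) if with_bf else None
    return StatResult("pearson", r, float(t), df, float(p), bf10=bf, n=n)


def ols_enter(y, X, prior: PriorSpec = DEFAULT_PRIOR,
              with_bf: bool = True) -> StatResult:
    """Simultaneous-entry ("Enter" method) OLS regression.

    All predictors enter at once; reports the omnibus F with (k, n-k-1)
    degrees of freedom, R-squared, its two-tailed p, and the
    mixture-of-g Bayes factor of the full model against intercept-only.
    Listwise deletion of incomplete rows.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    n, k = X.shape
    if n <= k + 1:
        raise InsufficientDataError("OLS needs n > k + 1 complete rows")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InvalidInputError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    F, p = float(fit.fvalue), float(fit.f_pvalue)
    bf = bayes.bf_regression(F, n, k, scale=prior.reg_scale) if with_bf else None
    return StatResult("ols_enter", float(fit.rsquared), F,
                      (k, n - k - 1), p, bf10=bf, n=n,
                      extra={"params": fit.params, "r2_adj": float(fit.rsquared_adj)})


def correlation_matrix(data: pd.DataFrame, rows, cols,
                       prior: PriorSpec = DEFAULT_PRIOR,
                       with_bf: bool = True) -> pd.DataFrame:
    """Long-format table of pairwise Pearson correlations.

    One row per (row-variable, column-variable) pair with r, p, BF10 and
    the effective pairwise n after deletion of incomplete pairs; cells
    with fewer than 3 complete pairs come back as NaN with n recorded.
    Symmetric by construction (swapping the pair leaves r unchanged).
    """
    out = []
    for a in rows:
        for b in cols:
            xa = data[a].to_numpy(dtype=float)
            xb = data[b].to_numpy(dtype=float)
            keep = np.isfinite(xa) & np.isfinite(xb)
            cell = {"var1": a, "var2": b, "n": int(keep.sum())}
            if a == b:
                cell.update(r=1.0, p=0.0, bf10=np.inf)
            elif keep.sum() < 3:
                cell.update(r=np.nan, p=np.nan, bf10=np.nan)
            else:
                res = pearson(xa[keep], xb[keep], prior, with_bf=with_bf)
                cell.update(r=res.estimate, p=res.p,
                            bf10=res.bf10 if with_bf else np.nan)
            out.append(cell)
    return pd.DataFrame(out, columns=["var1", "var2", "n", "r", "p", "bf10"])
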