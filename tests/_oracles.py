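"""Independent fixed-grid quadrature oracles for the Bayes factor families.

Deliberately naive: each integral is evaluated on a dense fixed grid with
the trapezoid rule after an explicit change of variables, sharing no code
path with the adaptive integrators they check.
"""
import numpy as np
from scipy import special, stats

N_GRID = 100_001


def bf_ttest_grid(t, n, scale=1 / np.sqrt(2)):
    # delta = scale * tan(theta): Cauchy density absorbs the Jacobian,
    # leaving a flat 1/pi weight over theta in (-pi/2, pi/2).
    theta = np.linspace(-np.pi / 2 + 1e-6, np.pi / 2 - 1e-6, N_GRID)
    delta = scale * np.tan(theta)
    vals = np.nan_to_num(stats.nct.pdf(t, n - 1, delta * np.sqrt(n))) / np.pi
    num = np.trapezoid(vals, theta)
    return num / stats.t.pdf(t, n - 1)


def _log_r_density(r, rho, n):
    lognum = (np.log(n - 2) + special.gammaln(n - 1)
              + (n - 1) / 2 * np.log1p(-rho ** 2)
              + (n - 4) / 2 * np.log1p(-r ** 2))
    logden = (0.5 * np.log(2 * np.pi) + special.gammaln(n - 0.5)
              + (n - 1.5) * np.log1p(-rho * r))
    return lognum - logden + np.log(special.hyp2f1(0.5, 0.5, n - 0.5,
                                                   (rho * r + 1) / 2))


def bf_pearson_grid(r, n, width=1.0):
    a = 1.0 / width
    rho = np.linspace(-1 + 1e-9, 1 - 1e-9, N_GRID)
    prior = stats.beta.pdf((rho + 1) / 2, a, a) / 2
    num = np.trapezoid(np.exp(_log_r_density(r, rho, n)) * prior, rho)
    return num / np.exp(_log_r_density(r, 0.0, n))


def bf_pearson_closed_form(r, n, kappa=1.0):
    """Analytic two-sided default correlation Bayes factor (no quadrature)."""
    k = kappa
    log_bf = ((1 - 2 / k) * np.log(2) + 0.5 * np.log(np.pi)
              - special.betaln(1 / k, 1 / k)
              + special.gammaln((n + 2 / k - 1) / 2)
              - special.gammaln((n + 2 / k) / 2)
              + np.log(special.hyp2f1((n - 1) / 2, (n - 1) / 2,
                                      (n + 2 / k) / 2, r ** 2)))
    return np.exp(log_bf)


def bf_regression_grid(F, n, k, scale=np.sqrt(2) / 4):
    r2 = k * F / (k * F + n - k - 1)
    u = np.linspace(1e-9, 1 - 1e-9, N_GRID)
    g = u / (1 - u)
    logint = ((n - k - 1) / 2 * np.log1p(g)
              - (n - 1) / 2 * np.log1p(g * (1 - r2))
              + 0.5 * np.log(n * scale ** 2 / 2) - special.gammaln(0.5)
              - 1.5 * np.log(g) - n * scale ** 2 / (2 * g)
              + 2 * np.log1p(-u) * -1)
    return np.trapezoid(np.exp(logint), u)


def wilcoxon_exact_p(diffs):
    """Two-sided exact signed-rank p by enumeration of all sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    count = 0
    for mask in range(2 ** n):
        signs = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        w = ranks[signs].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2 ** n
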