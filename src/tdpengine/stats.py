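"""Statistical primitives: rank-sum tests, 2x2 tables, single-level and
random-intercept logistic regression, and Wald post-hoc contrasts.

Design choices, stated once:

* Wald 95% confidence intervals on the log-odds scale throughout.
* Pearson chi-square without continuity correction by default; Yates is a
  switch for parity with other software defaults.
* Rank-sum p-values come from exact enumeration when both samples have
  n <= 8 and no ties, otherwise the tie-corrected normal approximation
  (no continuity correction, so identical samples give p = 1).
* The random-intercept ("multilevel") logistic likelihood is integrated
  by Gauss-Hermite quadrature and maximized directly; no pre-installed
  Python package offers maximum-likelihood binary mixed models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

Z95 = stats.norm.ppf(0.975)


class ContractError(RuntimeError):
    pass


@dataclass
class OddsResult:
    """One odds ratio with its Wald CI, as reported per model term."""

    outcome: str
    comparison: str                 # e.g. "late_nc vs no_tdp43"
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str = "single_level"     # or "multilevel"
    covariates: tuple[str, ...] = ()
    n_used: int = 0
    estimable: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# rank-sum


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic of the first sample, two-sided p).  Exact
    enumeration for small tie-free samples; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ContractError("rank_sum_test requires two non-empty samples")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    if no_ties and x.size <= 8 and y.size <= 8:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact")
        return float(res.statistic), float(res.pvalue)
    # tie-corrected asymptotic; degenerate spread (all values tied) -> p = 1
    ranks = stats.rankdata(combined)
    n1, n2 = x.size, y.size
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u1), 1.0
    z = (u1 - mu) / np.sqrt(var)
    return float(u1), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# 2x2 tables


@dataclass
class TwoByTwoResult:
    table: np.ndarray
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    chi2_p: float
    estimable: bool
    continuity_added: bool = False


def pearson_chi2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square for an RxC table: sum (O-E)^2 / E, df=(R-1)(C-1)."""
    table = np.asarray(table, dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def two_by_two(table, yates: bool = False) -> TwoByTwoResult:
    """Odds ratio, Wald CI and chi-square for a 2x2 table.

    Rows are the two comparison groups, columns (outcome present, absent):
    OR = (a/b) / (c/d).  A zero *margin* makes the statistics non-estimable;
    a single zero cell triggers the Haldane-Anscombe +0.5 continuity
    correction (documented policy).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ContractError("two_by_two expects non-negative integer 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TwoByTwoResult(t, np.nan, np.nan, np.nan, np.nan, np.nan,
                              estimable=False)
    continuity = bool((t == 0).any())
    w = t + 0.5 if continuity else t
    a, b = w[0]
    c, d = w[1]
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) + np.array([-Z95, Z95]) * se)
    chi2, p = pearson_chi2(t, yates=yates)
    return TwoByTwoResult(t, float(or_), float(lo), float(hi), chi2, p,
                          estimable=True, continuity_added=continuity)


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogitFit:
    """Fitted logistic model: coefficient vector with covariance."""

    params: pd.Series
    cov: pd.DataFrame
    n_used: int
    converged: bool
    model: str = "single_level"
    sigma_center: float = 0.0        # random-intercept SD (multilevel only)
    note: str = ""

    def term_or(self, name: str, outcome: str = "",
                comparison: str = "") -> OddsResult:
        b = self.params[name]
        var = self.cov.loc[name, name]
        se = np.sqrt(var) if var > 0 else np.nan
        estimable = bool(np.isfinite(b) and np.isfinite(se) and se < 50)
        z = b / se if estimable else np.nan
        return OddsResult(
            outcome=outcome,
            comparison=comparison or name,
            odds_ratio=float(np.exp(b)) if estimable else np.nan,
            ci_low=float(np.exp(b - Z95 * se)) if estimable else np.nan,
            ci_high=float(np.exp(b + Z95 * se)) if estimable else np.nan,
            p_value=float(2 * stats.norm.sf(abs(z))) if estimable else np.nan,
            model=self.model,
            n_used=self.n_used,
            estimable=estimable,
            note=self.note,
        )


def fit_logistic(X: pd.DataFrame, y) -> LogitFit:
    """Maximum-likelihood logistic fit via statsmodels (design matrix in,
    no intercept added implicitly — include a 'const' column)."""
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationWarning,
    )

    y = np.asarray(y, dtype=float)
    note = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        params = pd.Series(res.params, index=X.columns)
        cov = pd.DataFrame(res.cov_params(), index=X.columns,
                           columns=X.columns)
        converged = bool(res.mle_retvals.get("converged", True))
        ses = np.sqrt(np.diag(cov))
        if (ses > 50).any():
            note = "possible separation: inflated standard errors"
    except Exception as exc:  # perfect separation raises inside statsmodels
        params = pd.Series(np.nan, index=X.columns)
        cov = pd.DataFrame(np.nan, index=X.columns, columns=X.columns)
        converged = False
        note = f"fit failed: {type(exc).__name__}"
    return LogitFit(params=params, cov=cov, n_used=len(y),
                    converged=converged, note=note)


def _cluster_loglik(eta, y, group_idx, n_groups, offset):
    """Per-cluster Bernoulli log-likelihood at linear predictor eta+offset."""
    lp = eta + offset
    ll = y * lp - np.logaddexp(0.0, lp)
    return np.bincount(group_idx, weights=ll, minlength=n_groups)


def fit_mixed_logistic(
    X: pd.DataFrame,
    y,
    groups,
    n_quad: int = 101,
) -> LogitFit:
    """Random-intercept logistic regression by Gauss-Hermite quadrature.

    The marginal likelihood integrates a N(0, sigma^2) intercept per group
    with ``n_quad`` Hermite nodes; fixed effects and sigma are maximized
    jointly (L-BFGS-B, sigma >= 0).  Fixed-effect covariance comes from the
    numerical Hessian of the profile at the optimum.  With a single group
    (or sigma driven to 0) the fit coincides with the single-level model;
    non-convergence is reported explicitly, never silently defaulted.
    """
    y = np.asarray(y, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    n_groups = len(uniques)
    Xm = np.asarray(X, dtype=float)
    k = Xm.shape[1]

    base = fit_logistic(X, y)
    if n_groups < 2:
        base.model = "multilevel"
        base.note = (base.note + "; " if base.note else "") + \
            "single group: degenerated to single-level fit"
        return base

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    def nll(theta):
        beta, sigma = theta[:k], theta[k]
        eta = Xm @ beta
        per_node = np.empty((n_quad, n_groups))
        for q in range(n_quad):
            u = np.sqrt(2.0) * sigma * nodes[q]
            per_node[q] = _cluster_loglik(eta, y, codes, n_groups, u)
        return -special.logsumexp(per_node + logw[:, None], axis=0).sum()

    beta0 = np.nan_to_num(np.asarray(base.params, dtype=float))
    x0 = np.concatenate([beta0, [0.5]])
    bounds = [(None, None)] * k + [(0.0, 10.0)]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12})
    theta = res.x
    sigma = float(theta[k])

    # numerical Hessian (central differences) for the covariance
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    m = k + 1
    H = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            f_pp = nll(theta + ei + ej)
            f_pm = nll(theta + ei - ej)
            f_mp = nll(theta - ei + ej)
            f_mm = nll(theta - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[i] * h[j])
    note = ""
    try:
        cov_all = np.linalg.inv(H)
        cov_beta = cov_all[:k, :k]
        if (np.diag(cov_beta) <= 0).any():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # boundary sigma=0 can make the full Hessian singular; condition on
        # sigma and use the fixed-effect block only
        Hb = H[:k, :k]
        cov_beta = np.linalg.pinv(Hb)
        note = "covariance conditioned on sigma (boundary)"
    params = pd.Series(theta[:k], index=X.columns)
    cov = pd.DataFrame(cov_beta, index=X.columns, columns=X.columns)
    return LogitFit(params=params, cov=cov, n_used=len(y),
                    converged=bool(res.success), model="multilevel",
                    sigma_center=sigma, note=note)


# ---------------------------------------------------------------------------
# post-hoc contrasts


@dataclass
class Contrast:
    comparison: str
    estimate: float          # log-odds difference
    se: float
    p_value: float
    estimable: bool = True
    note: str = ""


def posthoc_contrasts(
    fit: LogitFit,
    pairs: list[tuple[str, str]],
    outcome: str = "",
) -> list[Contrast]:
    """Wald tests on coefficient differences using the fit's covariance.

    P-values are reported unadjusted.  A pair of identical terms gives a
    zero difference with p = 1; non-estimable coefficients skip the
    contrast with a note.
    """
    out: list[Contrast] = []
    for a, b in pairs:
        label = f"{a} vs {b}"
        if a == b:
            out.append(Contrast(label, 0.0, 0.0, 1.0))
            continue
        ba, bb = fit.params.get(a, np.nan), fit.params.get(b, np.nan)
        if not (np.isfinite(ba) and np.isfinite(bb)):
            out.append(Contrast(label, np.nan, np.nan, np.nan,
                                estimable=False,
                                note="non-estimable coefficient"))
            continue
        var = (fit.cov.loc[a, a] + fit.cov.loc[b, b]
               - 2.0 * fit.cov.loc[a, b])
        if var <= 0:
            out.append(Contrast(label, float(ba - bb), 0.0, 1.0,
                                note="degenerate covariance"))
            continue
        se = float(np.sqrt(var))
        z = (ba - bb) / se
        out.append(Contrast(label, float(ba - bb), se,
                            float(2 * stats.norm.sf(abs(z)))))
    return out
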