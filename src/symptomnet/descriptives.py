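"""Cohort descriptive statistics: prevalence, group tests, ANCOVA, logistic fits.

These are the univariate/multivariate companions to the network analysis:
prevalence of insomnia symptoms with Wilson score intervals, severity
banding of the sum score, chi-square / t / Mann-Whitney group contrasts,
covariate-adjusted group comparison of quality of life, and the logistic
regression for independent correlates of insomnia.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint
import statsmodels.api as sm

__all__ = [
    "PrevalenceResult",
    "TestResult",
    "LogisticFit",
    "isi_category",
    "ISI_CUTOFF",
    "prevalence_with_ci",
    "pearson_chi2",
    "welch_t",
    "pooled_t",
    "mann_whitney_u",
    "ancova_group_effect",
    "logistic_insomnia",
]

ISI_CUTOFF = 8  # sum score at or above which insomnia symptoms are present

_BANDS = (
    (0, 7, "none"),
    (8, 14, "subthreshold"),
    (15, 21, "moderate"),
    (22, 28, "severe"),
)


@dataclass
class PrevalenceResult:
    positive_count: int
    total_count: int
    proportion: float
    ci_low: float
    ci_high: float
    confidence_level: float = 0.95

    def as_percent(self, decimals: int = 1) -> tuple[float, float, float]:
        return tuple(
            round(100 * v, decimals) for v in (self.proportion, self.ci_low, self.ci_high)
        )


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | tuple | None = None


@dataclass
class LogisticFit:
    """Per-predictor odds ratios with Wald 95% intervals."""

    table: pd.DataFrame  # index: predictor; columns: coef, odds_ratio, ci_low, ci_high, p_value
    converged: bool
    iterations: int
    log_likelihood: float


def isi_category(isi_total: int) -> str:
    """Severity band of the insomnia sum score.

    0-7 none, 8-14 subthreshold, 15-21 moderate, 22-28 severe; 8 is the
    clinical cut-off for having insomnia symptoms at all.
    """
    t = int(isi_total)
    if t != isi_total or not (0 <= t <= 28):
        raise ValueError(f"isi_total must be an integer in [0, 28], got {isi_total}")
    for lo, hi, lab in _BANDS:
        if lo <= t <= hi:
            return lab
    raise AssertionError("unreachable")


def prevalence_with_ci(
    positive_count: int, total_count: int, confidence_level: float = 0.95
) -> PrevalenceResult:
    """Binomial proportion with a Wilson score interval."""
    if total_count < 1:
        raise ValueError("total_count must be >= 1")
    if not (0 <= positive_count <= total_count):
        raise ValueError("positive_count must be in [0, total_count]")
    lo, hi = proportion_confint(
        positive_count, total_count, alpha=1 - confidence_level, method="wilson"
    )
    # the Wilson bound is analytically 0 (resp. 1) at the boundary counts;
    # snap away the floating-point residue
    if positive_count == 0:
        lo = 0.0
    if positive_count == total_count:
        hi = 1.0
    return PrevalenceResult(
        positive_count=int(positive_count),
        total_count=int(total_count),
        proportion=positive_count / total_count,
        ci_low=float(lo),
        ci_high=float(hi),
        confidence_level=confidence_level,
    )


def pearson_chi2(table) -> TestResult:
    """Uncorrected Pearson chi-square test of independence on an r x c table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if np.any(rows == 0):
        raise ValueError(f"zero row margin at row {int(np.argmin(rows))}")
    if np.any(cols == 0):
        raise ValueError(f"zero column margin at column {int(np.argmin(cols))}")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return TestResult(statistic=float(stat), p_value=float(p), df=int(dof), method="pearson-chi2")


def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> TestResult:
    """Welch two-sample t from summary statistics, Satterthwaite df, two-sided p."""
    if min(n1, n2) < 2:
        raise ValueError("both groups need n >= 2")
    if min(sd1, sd2) <= 0:
        raise ValueError("standard deviations must be positive")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(statistic=float(t), p_value=float(p), df=float(df), method="welch-t")


def pooled_t(mean1, sd1, n1, mean2, sd2, n2) -> TestResult:
    """Student (pooled-variance) two-sample t from summary statistics, df = n1+n2-2."""
    if min(n1, n2) < 2:
        raise ValueError("both groups need n >= 2")
    if min(sd1, sd2) <= 0:
        raise ValueError("standard deviations must be positive")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TestResult(statistic=float(t), p_value=float(p), df=float(n1 + n2 - 2), method="pooled-t")


def _u_statistic(pooled_ranks: np.ndarray, n1: int) -> float:
    return float(pooled_ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(sample1, sample2, method: str = "normal") -> TestResult:
    """Mann-Whitney U with tie-corrected signed Z, or exact permutation p.

    The statistic is U for ``sample1``; Z is signed so that positive values
    mean sample1 tends to rank higher.  ``method='exact'`` enumerates all
    splits of the pooled ranks (feasible for small samples; the permutation
    distribution of U is symmetric about n1*n2/2 even under ties, and the
    two-sided p sums both tails at the observed distance from that center).
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled, method="average")
    u = _u_statistic(ranks, n1)
    mu = n1 * n2 / 2.0
    if np.ptp(pooled) == 0:
        # all values identical across both samples: no rank tendency at all
        return TestResult(statistic=0.0, p_value=1.0, df=None,
                          method="mann-whitney-degenerate")
    if method == "exact":
        center_dist = abs(u - mu)
        count = 0
        total = 0
        idx = range(n1 + n2)
        for subset in itertools.combinations(idx, n1):
            u_perm = float(ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0)
            total += 1
            if abs(u_perm - mu) >= center_dist - 1e-12:
                count += 1
        return TestResult(statistic=u, p_value=count / total, df=None, method="mann-whitney-exact")
    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (u - mu) / np.sqrt(sigma2)
    p = 2 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)), df=None,
                      method="mann-whitney-normal")


def ancova_group_effect(outcome, group, covariates=None) -> TestResult:
    """F test of a binary group effect after linear adjustment for covariates.

    Fits outcome ~ intercept + group + covariates by least squares and
    reports the type-III F for the group term, which equals the squared t
    of the group coefficient.  With no covariates this reduces exactly to
    the squared pooled two-sample t.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    g = np.asarray(group, dtype=float).ravel()
    n = y.size
    parts = [np.ones(n), g]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.size:
            if C.ndim == 1:
                C = C[:, None]
            parts.extend(C[:, j] for j in range(C.shape[1]))
    X = np.column_stack(parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns); "
            "check for collinear covariates"
        )
    # type-III F via incremental residual sum of squares (equals the squared
    # t of the group coefficient in exact arithmetic, but stays finite when
    # covariates absorb the outcome entirely)
    full = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, np.delete(X, 1, axis=1)).fit()
    df_resid = float(full.df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    ss_group = max(float(reduced.ssr - full.ssr), 0.0)
    if ss_group <= 1e-12 * max(tss, 1e-300):
        return TestResult(statistic=0.0, p_value=1.0, df=(1, df_resid), method="ancova-F")
    F = ss_group / (full.ssr / df_resid)
    p = float(stats.f.sf(F, 1, df_resid))
    return TestResult(statistic=float(F), p_value=p, df=(1, df_resid), method="ancova-F")


def logistic_insomnia(outcome, predictors: pd.DataFrame, site=None) -> LogisticFit:
    """Binary logistic regression for correlates of insomnia.

    Maximum-likelihood fit (IRLS/Newton, tolerance 1e-8, at most 100
    iterations) of the outcome on the labeled predictors, optionally
    adjusted for study site via fixed-effect indicator columns (first site
    as reference).  Reports Wald 95% intervals on the odds-ratio scale.
    Raises on rank deficiency, non-convergence, or detected separation.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    X = pd.DataFrame(predictors).copy()
    X.columns = [str(c) for c in X.columns]
    if site is not None:
        dummies = pd.get_dummies(pd.Series(site, name="site").astype("category"),
                                 prefix="site", drop_first=True, dtype=float)
        dummies.index = X.index
        X = pd.concat([X, dummies], axis=1)
    X = X.astype(float)
    design = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(
            f"predictor matrix is rank deficient (rank {rank} < {design.shape[1]})"
        )
    model = sm.Logit(y, design)
    try:
        res = model.fit(method="newton", tol=1e-8, maxiter=100, disp=False)
    except Exception as err:  # statsmodels raises on perfect separation
        raise RuntimeError(f"logistic fit failed (possible separation): {err}") from err
    fitted = res.predict()
    if ((fitted < 1e-6) | (fitted > 1 - 1e-6)).any() and np.abs(res.params).max() > 15:
        raise RuntimeError("separation detected: fitted probabilities at 0/1 "
                           "with diverging coefficients")
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge in 100 iterations")
    conf = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "coef": res.params,
            "odds_ratio": np.exp(res.params),
            "ci_low": np.exp(conf[0]),
            "ci_high": np.exp(conf[1]),
            "p_value": res.pvalues,
        }
    )
    return LogisticFit(
        table=table,
        converged=True,
        iterations=int(res.mle_retvals.get("iterations", 0)),
        log_likelihood=float(res.llf),
    )
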