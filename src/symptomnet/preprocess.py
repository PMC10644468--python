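"""Rank-based Gaussianization and covariate adjustment for network estimation.

Ordinal questionnaire items are far from Gaussian, but the graphical model
downstream assumes multivariate normality.  The standard remedy in
psychometric network analysis is the nonparanormal (Gaussian copula)
transform: map each variable through its (shrunken, truncated) empirical CDF
and then through the standard-normal quantile function.  The resulting
columns have Gaussian margins while preserving the rank (copula) dependence
structure, so Pearson correlations of the transformed data estimate the
latent Gaussian correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtri

__all__ = [
    "TransformedMatrix",
    "npn_truncation_delta",
    "npn_transform",
    "residualize",
    "correlation_matrix",
]


@dataclass
class TransformedMatrix:
    """Subjects x variables matrix after Gaussianization.

    Each column has sample mean 0 and sample standard deviation 1 (ddof=1)
    to within 1e-8.  ``metadata`` records, per variable, the number of
    distinct values seen and the ECDF truncation bound used, so a transform
    can be audited after the fact.
    """

    values: np.ndarray
    variable_labels: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.variable_labels.index(label)]


def npn_truncation_delta(n: int) -> float:
    """Truncation bound delta_n = 1 / (4 n^{1/4} sqrt(pi log n)).

    The empirical CDF is clipped to [delta_n, 1 - delta_n] before applying
    the normal quantile function; without the clip the extreme order
    statistics map to unbounded z-scores and the transform is inconsistent.
    """
    if n < 2:
        raise ValueError("need at least 2 observations")
    return 1.0 / (4.0 * n ** 0.25 * np.sqrt(np.pi * np.log(n)))


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def npn_transform(data, variable_labels: list[str] | None = None) -> TransformedMatrix:
    """Nonparanormal transform of every column of ``data``.

    Per variable: average-tie ranks -> shrunken ECDF r/(n+1), clipped to
    [delta_n, 1-delta_n] -> standard-normal quantiles -> standardized to
    mean 0, sd 1.  Being rank-based, the output is invariant to any strictly
    monotone relabeling of a variable's values.

    Parameters
    ----------
    data : array-like or pandas.DataFrame, shape (n_subjects, n_variables)
    variable_labels : column names; taken from the DataFrame if omitted.
    """
    if hasattr(data, "columns"):  # pandas
        if variable_labels is None:
            variable_labels = [str(c) for c in data.columns]
        values = np.asarray(data, dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        if variable_labels is None:
            variable_labels = [f"V{i + 1}" for i in range(values.shape[1])]
    if values.ndim != 2:
        raise ValueError("data must be 2-dimensional (subjects x variables)")
    n, p = values.shape
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")

    delta = npn_truncation_delta(n)
    out = np.empty_like(values)
    per_var = {}
    for j in range(p):
        col = values[:, j]
        n_distinct = np.unique(col).size
        if n_distinct < 2:
            raise ValueError(f"variable {variable_labels[j]!r} is constant")
        ranks = stats.rankdata(col, method="average")
        ecdf = np.clip(ranks / (n + 1.0), delta, 1.0 - delta)
        out[:, j] = _standardize(ndtri(ecdf))
        per_var[variable_labels[j]] = {
            "n_distinct": int(n_distinct),
            "truncation_delta": delta,
        }
    meta = {"transform": "nonparanormal-truncated-ecdf", "n": n, "per_variable": per_var}
    return TransformedMatrix(out, list(variable_labels), meta)


def residualize(data: TransformedMatrix, covariate) -> TransformedMatrix:
    """Remove a covariate's linear effect from every column, then re-standardize.

    Used to build the age-adjusted network: each node is replaced by the
    residual of its least-squares regression on (intercept, covariate), so
    the adjusted network keeps the same node set as the original.
    """
    cov = np.asarray(covariate, dtype=float).ravel()
    if cov.size != data.n_subjects:
        raise ValueError("covariate length must equal subject count")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant; nothing to adjust for")
    X = np.column_stack([np.ones_like(cov), cov])
    beta, *_ = np.linalg.lstsq(X, data.values, rcond=None)
    resid = data.values - X @ beta
    sds = resid.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds < 1e-12)
    if dead.size:
        names = [data.variable_labels[j] for j in dead]
        raise ValueError(f"residual is constant for variable(s) {names}; "
                         "column coincides with the covariate")
    resid = (resid - resid.mean(axis=0)) / sds
    meta = dict(data.metadata)
    meta["residualized"] = True
    return TransformedMatrix(resid, list(data.variable_labels), meta)


def correlation_matrix(data: TransformedMatrix) -> np.ndarray:
    """Pearson correlations of the transformed columns.

    With Gaussianized margins these are the nonparametric (copula-scale)
    correlations the graphical lasso consumes.  Warns when n <= p; the
    lasso still regularizes such problems, but the warning flags them.
    """
    n, p = data.values.shape
    if n <= p:
        import warnings

        warnings.warn(f"n={n} <= p={p}: correlation matrix is rank deficient; "
                      "relying on regularization", stacklevel=2)
    R = np.corrcoef(data.values, rowvar=False)
    R = np.asarray(R, dtype=float)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R
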