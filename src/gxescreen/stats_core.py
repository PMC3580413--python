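"""Logistic maximum likelihood with offsets, likelihood-ratio tests, and
multiplicity adjustment.

This is the numerical engine under every stage of the two-stage interaction
screen: the stage-1 marginal scan fits ordinary case-control logistic models,
the stage-2 case-only test fits treatment-assignment-on-genotype models with
the randomization fraction entering as a fixed offset ``log(q/(1-q))``, and
the follow-up tables are built from nested likelihood-ratio comparisons of
the same fits.

Fitting is Newton-Raphson (iteratively reweighted least squares) with
step-halving. Separation — the classic failure mode of small stratified
genotype cells — is flagged, never silently returned: downstream consumers
report NA instead of a spurious p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "DesignMatrix",
    "LogisticFit",
    "LRTResult",
    "AdjustedPValues",
    "fit_logistic",
    "likelihood_ratio_test",
    "wald_ci",
    "combine_component_pvalues",
    "bh_adjust",
    "bonferroni_adjust",
]

# |coefficient| beyond this at (non-)convergence is treated as separation
SEPARATION_BOUND = 15.0


@dataclass
class DesignMatrix:
    """Predictor matrix with labelled columns, including an explicit intercept.

    Parameters
    ----------
    values
        Observations x predictors, no missing entries.
    column_labels
        One label per column.
    require_intercept
        When true (the default) exactly one constant-one column must be
        present; no-intercept parameterizations (genotype-level indicator
        fits) set this to False.
    """

    values: np.ndarray
    column_labels: list[str]
    require_intercept: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design matrix must be 2-dimensional")
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("column_labels length does not match columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains missing or non-finite entries")
        if self.require_intercept:
            n_intercept = int(np.sum(np.all(self.values == 1.0, axis=0)))
            if n_intercept != 1:
                raise ValueError(
                    f"expected exactly one intercept column, found {n_intercept}"
                )


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit on the log-odds scale."""

    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    column_labels: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class AdjustedPValues:
    """Raw and multiplicity-adjusted p-values over a family of size ``m``.

    ``m`` may exceed the number of supplied p-values when only the smallest
    members of a larger family are supplied (e.g. a printed top-10 of a
    112-test family). Unsupplied values are then treated as no smaller than
    the largest supplied one; ``exact`` marks the entries that are provably
    unaffected by that assumption (adjusted value <= max supplied raw p).
    """

    raw: np.ndarray
    adjusted: np.ndarray
    m: int
    method: str
    exact: np.ndarray | None = None
    note: str = ""


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, DesignMatrix):
        return X.values, list(X.column_labels)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe log-likelihood: -sum log(1+exp(-(2y-1) eta))
    s = (2.0 * y - 1.0) * eta
    return float(-np.sum(np.logaddexp(0.0, -s)))


def fit_logistic(
    X,
    y,
    offset: np.ndarray | None = None,
    *,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
) -> LogisticFit:
    """Maximize the Bernoulli log-likelihood with linear predictor
    ``offset + X @ beta``.

    Newton-Raphson with step-halving; the covariance is the inverse observed
    information at the maximum. Convergence is declared when the maximum
    absolute score drops below ``score_tol`` or the relative change in
    log-likelihood falls below ``loglik_tol``. Fits hitting the iteration
    limit, or converging with any ``|coefficient|`` above
    ``SEPARATION_BOUND`` (quasi-complete separation), carry
    ``converged=False``.

    Raises
    ------
    ValueError
        ``"collinear design"`` for rank-deficient ``X``; ``"degenerate
        response"`` when ``y`` is constant.
    """
    Xv, labels = _as_design(X)
    y = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if y.shape != (n,):
        raise ValueError("response length does not match design rows")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("degenerate response")
    if np.linalg.matrix_rank(Xv) < p:
        raise ValueError("collinear design")
    if offset is None:
        off = np.zeros(n)
    else:
        off = np.asarray(offset, dtype=float)
        if off.shape != (n,):
            raise ValueError("offset length does not match response")
        if not np.all(np.isfinite(off)):
            raise ValueError("offset contains non-finite entries")

    beta = np.zeros(p)
    eta = off + Xv @ beta
    ll = _bernoulli_loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        score = Xv.T @ (y - mu)
        w = mu * (1.0 - mu)
        info = (Xv * w[:, None]).T @ Xv
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break  # information singular: separation / degenerate weights
        # step-halving until the likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            beta_new = beta + factor * step
            ll_new = _bernoulli_loglik(y, off + Xv @ beta_new)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, eta = beta_new, off + Xv @ beta_new
        ll_prev, ll = ll, ll_new
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        if abs(ll - ll_prev) < loglik_tol * (abs(ll_prev) + 1e-300):
            converged = True
            break
    if np.any(np.abs(beta) > SEPARATION_BOUND):
        converged = False

    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = (Xv * w[:, None]).T @ Xv
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return LogisticFit(
        coefficients=beta,
        covariance=cov,
        log_likelihood=ll,
        converged=converged,
        n_iter=it,
        column_labels=labels,
    )


def likelihood_ratio_test(
    full: LogisticFit, reduced: LogisticFit, df: int, *, tol: float = 1e-6
) -> LRTResult:
    """Chi-square LRT of a reduced model nested within a full model.

    The statistic is ``2 * (l_full - l_reduced)`` clipped at zero; a negative
    value beyond ``tol`` indicates the fits are not nested (or one failed)
    and raises.
    """
    if df < 1:
        raise ValueError("df must be a positive integer")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -tol:
        raise ValueError("non-nested fits")
    stat = max(stat, 0.0)
    return LRTResult(statistic=stat, df=df, p_value=float(sps.chi2.sf(stat, df)))


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory interval ``estimate +/- z(level) * se`` (log scale for
    odds ratios; callers exponentiate)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if se <= 0:
        raise ValueError("se must be positive")
    z = sps.norm.ppf(0.5 + level / 2.0)
    return (estimate - z * se, estimate + z * se)


def combine_component_pvalues(p_e_alone: float, p_eplusp: float) -> float:
    """Combine two independent 1-df test p-values into a 2-df chi-square p.

    Each p is converted to its chi-square(1) quantile at ``1 - p``, the two
    quantiles are summed, and the chi-square(2) upper tail of the sum is
    returned. When the raw statistics are available callers may sum those
    directly; the two routes agree by construction.
    """
    for p in (p_e_alone, p_eplusp):
        if not 0.0 < p <= 1.0:
            raise ValueError("degenerate p-value")
    stat = sps.chi2.isf(p_e_alone, 1) + sps.chi2.isf(p_eplusp, 1)
    return float(sps.chi2.sf(stat, 2))


def bh_adjust(pvalues, m: int | None = None) -> AdjustedPValues:
    """Benjamini-Hochberg step-up adjusted p-values over a family of size m.

    Adjusted value at sorted rank ``i`` is ``min_{j >= i} p(j) * m / j``
    capped at 1. With ``m`` larger than the number of supplied p-values the
    unsupplied (larger) members of the family cannot lower the adjusted value
    at rank ``i`` below ``max(raw)``; entries already at or below that bound
    are exact regardless of the unprinted values and are flagged in
    ``exact``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-d vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValueError("family size m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, n + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(n)
    adjusted[order] = adj_sorted
    exact = None
    note = ""
    if m > n:
        exact = adjusted <= np.max(p)
        note = (
            f"family size {m} exceeds the {n} supplied p-values; unsupplied "
            "values treated as >= max(raw). Entries with adjusted <= max(raw) "
            "are exact; others are upper bounds."
        )
    return AdjustedPValues(
        raw=p, adjusted=adjusted, m=int(m), method="BH", exact=exact, note=note
    )


def bonferroni_adjust(pvalues, m: int | None = None) -> AdjustedPValues:
    """Bonferroni adjustment: ``min(p * m, 1)``."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-d vector")
    n = p.size
    if m is None:
        m = n
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return AdjustedPValues(
        raw=p, adjusted=np.minimum(p * m, 1.0), m=int(m), method="Bonferroni"
    )
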