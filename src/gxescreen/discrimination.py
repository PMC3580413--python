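"""Discrimination assessment: does adding flagged SNPs (main effects and
treatment-interaction terms) to a covariate risk model improve the ability
to tell cases from controls?

AUC is the Mann-Whitney concordance probability of the fitted risk scores;
confidence intervals and the test for an AUC increase come from a pair
bootstrap that resamples matched case-control pairs as units, preserving
the 1:1 design. Apparent (in-sample) AUC is reported, as is conventional
for descriptive model comparison on the discovery sample — it is optimistic
for SNPs selected in the same data, which is exactly why the comparison is
descriptive rather than confirmatory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata

from .simulate import GenotypeMatrix
from .stage1 import build_covariate_design
from .stats_core import fit_logistic

__all__ = [
    "RiskModelSpec",
    "AUCResult",
    "AUCComparison",
    "auc",
    "build_risk_design",
    "fit_and_score",
    "bootstrap_auc_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class RiskModelSpec:
    """Which terms enter the risk model.

    SNPs are coded with indicator variables for one and for two minor
    alleles; when ``include_interactions`` is set, each indicator is also
    crossed with the subject's hormone-trial active-assignment indicator.
    """

    covariates: list
    include_snps: list = field(default_factory=list)
    include_interactions: bool = False

    def __post_init__(self) -> None:
        if self.include_interactions and not self.include_snps:
            raise ValueError("interactions require SNP main effects")


@dataclass
class AUCResult:
    auc: float
    ci: tuple
    n_boot: int
    seed: int


@dataclass
class AUCComparison:
    delta: float
    ci: tuple
    p_value: float
    n_boot: int
    seed: int
    n_dropped_replicates: int = 0


def auc(scores, labels) -> float:
    """Mann-Whitney concordance: probability a random case outscores a
    random control, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def build_risk_design(
    data: pd.DataFrame, spec: RiskModelSpec, genotypes: GenotypeMatrix | None = None
) -> np.ndarray:
    """Intercept + covariates + SNP genotype indicators (1 and 2 minor
    alleles) + optional SNP-by-HT-assignment interaction indicators.

    Indicator or interaction columns that are constant in this sample (e.g.
    no minor-allele homozygotes) carry no information and are skipped."""
    cols = [np.ones(len(data))]
    Z = build_covariate_design(data, spec.covariates)
    cols.extend(Z[c].to_numpy() for c in Z.columns)
    if spec.include_snps:
        if genotypes is None:
            raise ValueError("genotypes required when include_snps is nonempty")
        z_ht = np.nan_to_num(data["z_ht"].to_numpy(dtype=float))
        for rsid in spec.include_snps:
            g = genotypes.column(rsid)
            g = np.where(np.isnan(g), np.nanmean(g), g)
            for lev in (1, 2):
                ind = (g == lev).astype(float)
                for term in ([ind, ind * z_ht] if spec.include_interactions
                             else [ind]):
                    if term.std() > 0:
                        cols.append(term)
                    else:
                        logger.info(
                            "%s: dropping empty level-%d term from risk model",
                            rsid, lev,
                        )
    return np.column_stack(cols)


def _pair_resample(data: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Row indices of a bootstrap resample drawn pair-by-pair."""
    pair_ids = data["pair_id"].to_numpy()
    unique = np.unique(pair_ids)
    drawn = rng.choice(unique, size=len(unique), replace=True)
    members = {pid: np.flatnonzero(pair_ids == pid) for pid in unique}
    return np.concatenate([members[pid] for pid in drawn])


def fit_and_score(
    data: pd.DataFrame,
    spec: RiskModelSpec,
    genotypes: GenotypeMatrix | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, AUCResult]:
    """Fit the risk model, score every subject, and report apparent AUC with
    a percentile pair-bootstrap confidence interval.

    ``data`` is the matched case-control table with ``stroke`` and
    ``pair_id`` columns. Separation raises with the model's columns listed.
    """
    y = data["stroke"].to_numpy(dtype=float)
    X = build_risk_design(data, spec, genotypes)
    fit = fit_logistic(X, y)
    if not fit.converged:
        raise ValueError(
            "risk model separated; terms: covariates="
            f"{spec.covariates} snps={spec.include_snps}"
        )
    scores = expit(X @ fit.coefficients)
    a = auc(scores, y)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = _pair_resample(data, rng)
        try:
            fb = fit_logistic(X[idx], y[idx])
        except ValueError:  # resample emptied a rare column
            continue
        if not fb.converged:
            continue
        boots.append(auc(expit(X[idx] @ fb.coefficients), y[idx]))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (min(float(lo), a), max(float(hi), a))
    else:
        ci = (np.nan, np.nan)
    return scores, AUCResult(auc=a, ci=ci, n_boot=n_boot, seed=seed)


def bootstrap_auc_comparison(
    data: pd.DataFrame,
    spec_base: RiskModelSpec,
    spec_extended: RiskModelSpec,
    genotypes: GenotypeMatrix | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> AUCComparison:
    """Bootstrap test for the AUC increase of an extended over a base model.

    Matched pairs are the resampling unit; both models are refit on every
    replicate and ``delta = AUC_ext - AUC_base`` collected. The CI is
    percentile; the two-sided p-value uses a normal approximation to the
    bootstrap distribution of delta. Replicates where either refit separates
    are dropped and counted.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is small; bootstrap p will be unstable", n_boot)
    y = data["stroke"].to_numpy(dtype=float)
    X_base = build_risk_design(data, spec_base, genotypes)
    X_ext = build_risk_design(data, spec_extended, genotypes)
    fb = fit_logistic(X_base, y)
    fe = fit_logistic(X_ext, y)
    delta = auc(expit(X_ext @ fe.coefficients), y) - auc(
        expit(X_base @ fb.coefficients), y
    )
    rng = np.random.default_rng(seed)
    deltas = []
    dropped = 0
    for _ in range(n_boot):
        idx = _pair_resample(data, rng)
        try:
            rb = fit_logistic(X_base[idx], y[idx])
            re = fit_logistic(X_ext[idx], y[idx])
        except ValueError:  # resample emptied a rare column
            dropped += 1
            continue
        if not (rb.converged and re.converged):
            dropped += 1
            continue
        deltas.append(
            auc(expit(X_ext[idx] @ re.coefficients), y[idx])
            - auc(expit(X_base[idx] @ rb.coefficients), y[idx])
        )
    deltas = np.asarray(deltas)
    if deltas.size >= 2 and np.std(deltas, ddof=1) > 0:
        lo, hi = np.percentile(deltas, [2.5, 97.5])
        ci = (float(lo), float(hi))
        p = float(2 * norm.sf(abs(delta) / np.std(deltas, ddof=1)))
    else:
        ci, p = (np.nan, np.nan), 1.0
    return AUCComparison(
        delta=float(delta), ci=ci, p_value=min(p, 1.0), n_boot=n_boot, seed=seed,
        n_dropped_replicates=dropped,
    )
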