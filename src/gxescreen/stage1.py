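"""Stage 1: per-SNP marginal association screen on the matched case-control
sample.

Each SNP is tested in an additive (minor-allele count) logistic model of
case status on genotype plus confounders, matching variables, randomization
assignments and the top genotype principal components (population
stratification adjustment). SNPs with a two-sided p-value below the screen
threshold form the family tested for treatment interaction in stage 2 —
the stage-1 and stage-2 statistics are asymptotically independent, which is
what licenses restricting the multiplicity correction to the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import GenotypeMatrix
from .stats_core import fit_logistic, likelihood_ratio_test

__all__ = [
    "PCScores",
    "Stage1Result",
    "compute_genotype_pcs",
    "ld_pruned",
    "marginal_scan",
    "build_covariate_design",
    "stage1_table",
]

logger = logging.getLogger(__name__)


@dataclass
class PCScores:
    scores: np.ndarray  # subjects x k
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class Stage1Result:
    rsid: str
    beta: float
    se: float
    or_: float
    p_value: float
    n_used: int
    passes: bool
    flipped: bool = False  # genotype recoded so the counted allele is minor


def compute_genotype_pcs(genotypes: GenotypeMatrix, k: int) -> PCScores:
    """Top-k principal components of the genotype correlation structure.

    Missing genotypes are imputed to the per-SNP mean; columns are centered
    and scaled to unit variance (monomorphic columns dropped with a log
    entry); subject scores come from the singular value decomposition. Sign
    convention: the first nonzero loading of each component is positive.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    X = genotypes.values.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.info("dropping %d monomorphic SNP(s) before PCA", (~keep).sum())
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    max_k = min(X.shape)
    if k > max_k:
        raise ValueError(f"k={k} exceeds available rank {max_k}")
    if k == 0:
        return PCScores(
            scores=np.empty((X.shape[0], 0)), explained_variance=np.empty(0)
        )
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: first nonzero loading of each component positive
    for i in range(k):
        nz = np.nonzero(np.abs(Vt[i]) > 1e-12)[0]
        if nz.size and Vt[i, nz[0]] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U[:, :k] * S[:k]
    var = S**2 / (X.shape[0] - 1)
    return PCScores(scores=scores, explained_variance=var[:k])


def ld_pruned(genotypes: GenotypeMatrix, r2_threshold: float = 0.2) -> GenotypeMatrix:
    """Greedy LD pruning: keep each SNP only if its r^2 with every
    previously kept SNP stays below the threshold.

    Small panels need this before PCA — a high-LD pair contributes twice the
    variance of a lone SNP, so its shared variation would surface as a
    principal component of its own and the PC adjustment would absorb the
    very genotype being tested.
    """
    X = genotypes.values
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    Xf = X.copy()
    Xf[nan_idx] = np.take(col_mean, nan_idx[1])
    kept: list[int] = []
    for j in range(Xf.shape[1]):
        if Xf[:, j].std() == 0:
            continue
        ok = True
        for i in kept:
            r = np.corrcoef(Xf[:, i], Xf[:, j])[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    if len(kept) < X.shape[1]:
        logger.info("LD pruning kept %d of %d SNPs for PCA", len(kept), X.shape[1])
    return GenotypeMatrix(
        values=X[:, kept],
        snps=[genotypes.snps[j] for j in kept],
        subject_ids=genotypes.subject_ids,
    )


def build_covariate_design(pheno: pd.DataFrame, covariates: list) -> pd.DataFrame:
    """Numeric-encode a covariate column list: categorical (object/string)
    columns become drop-first dummies, booleans become 0/1, randomization
    indicators have non-members filled with 0. Columns constant in this
    sample carry no information and are dropped with a log entry."""
    out = {}
    for col in covariates:
        if col not in pheno.columns:
            raise ValueError(f"covariate column {col!r} not found")
        s = pheno[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            for c in dummies.columns:
                out[c] = dummies[c].to_numpy()
        else:
            x = s.to_numpy(dtype=float)
            if col.startswith("z_"):
                x = np.nan_to_num(x)
            out[col] = x
    dropped = [c for c, x in out.items() if np.nanstd(x) == 0]
    if dropped:
        logger.info("dropping constant covariate column(s): %s", ", ".join(dropped))
    return pd.DataFrame(
        {c: x for c, x in out.items() if c not in dropped}, index=pheno.index
    )


def ensure_minor_coding(g: np.ndarray) -> tuple[np.ndarray, bool]:
    """Recode an allele-count vector so it counts the minor allele in this
    sample; exact 0.5 frequency keeps the supplied coding."""
    freq = np.nanmean(g) / 2.0
    if freq > 0.5:
        return 2.0 - g, True
    return g, False


def marginal_scan(
    casecontrol: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: list,
    pcs: PCScores | None = None,
    threshold: float = 0.05,
    test: str = "wald",
) -> list:
    """Per-SNP marginal logistic screen of case status on allele count plus
    covariates and PC scores.

    ``casecontrol`` must carry a boolean ``stroke`` column and be row-aligned
    with ``genotypes``. Missing genotypes are handled complete-case per SNP.
    The default p-value is the two-sided Wald test on the genotype
    coefficient; ``test="lrt"`` swaps in the 1-df likelihood-ratio test.
    Separated or non-converged fits yield NA p and ``passes=False``.
    """
    if test not in ("wald", "lrt"):
        raise ValueError("test must be 'wald' or 'lrt'")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if len(casecontrol) != genotypes.values.shape[0]:
        raise ValueError("phenotype rows are not aligned with genotype rows")
    y_all = casecontrol["stroke"].to_numpy(dtype=float)
    Z = build_covariate_design(casecontrol, covariates).to_numpy()
    if pcs is not None and pcs.k > 0:
        Z = np.hstack([Z, pcs.scores])
    base = np.hstack([np.ones((len(y_all), 1)), Z])

    results = []
    for j, spec in enumerate(genotypes.snps):
        g = genotypes.values[:, j]
        mask = ~np.isnan(g)
        gj, flipped = ensure_minor_coding(g[mask])
        if flipped:
            logger.info("%s: counted allele was major in sample; recoded", spec.rsid)
        n_used = int(mask.sum())
        X = np.hstack([base[mask], gj[:, None]])
        y = y_all[mask]
        try:
            fit = fit_logistic(X, y)
            if not fit.converged:
                raise ArithmeticError("separation or non-convergence")
            beta = float(fit.coefficients[-1])
            se = float(fit.se[-1])
            if test == "wald":
                p = float(2 * sps.norm.sf(abs(beta) / se))
            else:
                reduced = fit_logistic(base[mask], y)
                p = likelihood_ratio_test(fit, reduced, df=1).p_value
            results.append(
                Stage1Result(
                    rsid=spec.rsid, beta=beta, se=se, or_=float(np.exp(beta)),
                    p_value=p, n_used=n_used, passes=bool(p < threshold),
                    flipped=flipped,
                )
            )
        except (ValueError, ArithmeticError) as exc:
            logger.warning("%s: stage-1 fit failed (%s); reported NA", spec.rsid, exc)
            results.append(
                Stage1Result(
                    rsid=spec.rsid, beta=np.nan, se=np.nan, or_=np.nan,
                    p_value=np.nan, n_used=n_used, passes=False, flipped=flipped,
                )
            )
    return results


def stage1_table(results: list) -> pd.DataFrame:
    """Ranked TSV-shaped table: rsid / beta / se / OR / p / n / passes."""
    df = pd.DataFrame(
        {
            "rsid": [r.rsid for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "OR": [r.or_ for r in results],
            "p": [r.p_value for r in results],
            "n": [r.n_used for r in results],
            "passes": [r.passes for r in results],
        }
    )
    return df.sort_values("p", na_position="last", kind="stable").reset_index(drop=True)
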