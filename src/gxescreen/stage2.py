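"""Stage 2: case-only interaction testing among stage-1 survivors.

Within each hormone trial's cases, active-versus-placebo assignment Z is
regressed on minor-allele count G in an offset logistic model

    logit Pr(Z = 1 | G) = log(q / (1 - q)) + beta0 + beta2 * G

where q is the design fraction randomized to active treatment — a known
constant of the trial, never estimated from the cases. Randomization makes
G and Z independent in the source population, so beta2 estimates the
genotype-by-treatment interaction log-odds ratio (under a rare outcome)
with substantially less variance than a case-control product-term model.

The two trials enroll non-overlapping women, so their 1-df likelihood-ratio
statistics are independent and sum to a 2-df chi-square statistic for
interaction with hormone therapy overall. False-discovery-rate control is
applied over the stage-1 survivors only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import GenotypeMatrix
from .stats_core import bh_adjust, bonferroni_adjust, fit_logistic, likelihood_ratio_test

__all__ = [
    "ComponentTestResult",
    "CombinedInteractionResult",
    "case_only_component_test",
    "combined_ht_test",
    "run_stage2",
    "stage2_table",
]

logger = logging.getLogger(__name__)

HT_TRIALS = ("E-alone", "E+P")


@dataclass
class ComponentTestResult:
    trial: str
    rsid: str
    beta2_hat: float
    se: float
    lrt_statistic: float
    p_value: float
    n_cases_used: int
    converged: bool = True


@dataclass
class CombinedInteractionResult:
    rsid: str
    chi2_2df: float
    p_combined: float
    p_e_alone: float
    p_eplusp: float
    fdr: float = np.nan
    bonferroni: float = np.nan
    rank: int = 0
    partial: bool = False  # one component unusable; 1-df fallback


def case_only_offset(q: float, n: int) -> np.ndarray:
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return np.full(n, np.log(q / (1.0 - q)))


def case_only_component_test(
    z, g, q: float, *, trial: str = "", rsid: str = ""
) -> ComponentTestResult:
    """1-df case-only likelihood-ratio test of beta2 = 0 within one trial.

    ``z`` is the active-assignment indicator and ``g`` the minor-allele
    count, both over that trial's cases only; missing genotypes are handled
    complete-case. Raises ``"monomorphic"`` when the genotype does not vary
    among these cases; separation yields an NA result flagged not converged.
    """
    z = np.asarray(z, dtype=float)
    g = np.asarray(g, dtype=float)
    mask = ~np.isnan(g)
    z, g = z[mask], g[mask]
    n = len(z)
    if n == 0 or np.nanstd(g) == 0:
        raise ValueError("monomorphic")
    offset = case_only_offset(q, n)
    X_full = np.column_stack([np.ones(n), g])
    try:
        full = fit_logistic(X_full, z, offset=offset)
        reduced = fit_logistic(np.ones((n, 1)), z, offset=offset)
    except ValueError as exc:
        if "degenerate response" in str(exc):
            logger.warning("%s/%s: constant assignment among cases; NA", trial, rsid)
            return ComponentTestResult(
                trial, rsid, np.nan, np.nan, np.nan, np.nan, n, converged=False
            )
        raise
    if not (full.converged and reduced.converged):
        logger.warning("%s/%s: case-only fit separated; NA reported", trial, rsid)
        return ComponentTestResult(
            trial, rsid, np.nan, np.nan, np.nan, np.nan, n, converged=False
        )
    lrt = likelihood_ratio_test(full, reduced, df=1)
    return ComponentTestResult(
        trial=trial,
        rsid=rsid,
        beta2_hat=float(full.coefficients[1]),
        se=float(full.se[1]),
        lrt_statistic=lrt.statistic,
        p_value=lrt.p_value,
        n_cases_used=n,
    )


def combined_ht_test(
    res_e: ComponentTestResult, res_ep: ComponentTestResult
) -> CombinedInteractionResult:
    """Sum the two independent 1-df statistics into a 2-df chi-square test.

    When one component is NA (separated / untestable) the result degrades to
    the surviving component's 1-df p-value, flagged ``partial``.
    """
    if res_e.rsid != res_ep.rsid:
        raise ValueError("component results are for different SNPs")
    ok_e = res_e.converged and np.isfinite(res_e.lrt_statistic)
    ok_ep = res_ep.converged and np.isfinite(res_ep.lrt_statistic)
    if ok_e and ok_ep:
        stat = res_e.lrt_statistic + res_ep.lrt_statistic
        p = float(sps.chi2.sf(stat, 2))
        partial = False
    elif ok_e or ok_ep:
        surv = res_e if ok_e else res_ep
        stat, p, partial = surv.lrt_statistic, surv.p_value, True
        logger.warning("%s: one component NA; 1-df fallback", res_e.rsid)
    else:
        stat, p, partial = np.nan, np.nan, True
    return CombinedInteractionResult(
        rsid=res_e.rsid,
        chi2_2df=stat,
        p_combined=p,
        p_e_alone=res_e.p_value,
        p_eplusp=res_ep.p_value,
        partial=partial,
    )


def run_stage2(
    pass_list: list,
    casecontrol: pd.DataFrame,
    genotypes: GenotypeMatrix,
    q_by_trial: dict,
    fdr_threshold: float = 0.05,
) -> list:
    """Component + combined tests for every stage-1 survivor, with BH-FDR and
    Bonferroni over the survivor family.

    ``pass_list`` holds Stage1Result objects with ``passes=True`` (others are
    ignored); ``casecontrol`` is the matched-sample phenotype table aligned
    row-wise with ``genotypes``. Results come back ranked by combined p.
    """
    survivors = [r for r in pass_list if getattr(r, "passes", False)]
    if not survivors:
        logger.warning("empty stage-1 pass list; stage 2 has nothing to test")
        return []
    m = len(survivors)
    cases_mask = {}
    z_by_trial = {}
    stroke = casecontrol["stroke"].to_numpy(dtype=bool)
    for trial in HT_TRIALS:
        mask = stroke & (casecontrol["ht_trial"].to_numpy() == trial)
        cases_mask[trial] = mask
        z_by_trial[trial] = casecontrol["z_ht"].to_numpy(dtype=float)[mask]

    results = []
    for s1 in survivors:
        g_full = genotypes.column(s1.rsid)
        if getattr(s1, "flipped", False):
            g_full = 2.0 - g_full
        comps = {}
        for trial in HT_TRIALS:
            g = g_full[cases_mask[trial]]
            try:
                comps[trial] = case_only_component_test(
                    z_by_trial[trial], g, q_by_trial[trial], trial=trial,
                    rsid=s1.rsid,
                )
            except ValueError as exc:
                logger.warning("%s/%s: %s; component NA", trial, s1.rsid, exc)
                comps[trial] = ComponentTestResult(
                    trial, s1.rsid, np.nan, np.nan, np.nan, np.nan, 0,
                    converged=False,
                )
        results.append(combined_ht_test(comps["E-alone"], comps["E+P"]))

    ps = np.array([r.p_combined for r in results])
    finite = np.isfinite(ps)
    if finite.any():
        adj = bh_adjust(ps[finite], m=m)
        bon = bonferroni_adjust(ps[finite], m=m)
        it = iter(range(finite.sum()))
        for r, ok in zip(results, finite):
            if ok:
                i = next(it)
                r.fdr = float(adj.adjusted[i])
                r.bonferroni = float(bon.adjusted[i])
    order = np.argsort(np.where(finite, ps, np.inf), kind="stable")
    ranked = [results[i] for i in order]
    for rank, r in enumerate(ranked, start=1):
        r.rank = rank
    n_hits = sum(1 for r in ranked if np.isfinite(r.fdr) and r.fdr < fdr_threshold)
    logger.info("stage 2: %d SNPs tested, %d below FDR %.3g", m, n_hits, fdr_threshold)
    return ranked


def stage2_table(
    results: list, stage1_results: list | None = None,
    genotypes: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Ranked table mirroring the screen's reporting layout: rank, rsid, SNP
    metadata, sample MAF, marginal OR and p, combined interaction p, FDR,
    Bonferroni, and the per-component p-values."""
    s1 = {r.rsid: r for r in (stage1_results or [])}
    meta = {}
    if genotypes is not None:
        mafs = genotypes.maf()
        for j, spec in enumerate(genotypes.snps):
            meta[spec.rsid] = (
                spec.chromosome, spec.position,
                f"{spec.ref_allele}/{spec.alt_allele}", mafs[j],
            )
    rows = []
    for r in results:
        chrom, pos, alleles, maf = meta.get(r.rsid, ("", np.nan, "", np.nan))
        m1 = s1.get(r.rsid)
        rows.append(
            {
                "rank": r.rank,
                "rsid": r.rsid,
                "chr": chrom,
                "position": pos,
                "alleles": alleles,
                "maf": maf,
                "marginal_or": m1.or_ if m1 else np.nan,
                "marginal_p": m1.p_value if m1 else np.nan,
                "interaction_p": r.p_combined,
                "interaction_fdr": r.fdr,
                "bonferroni": r.bonferroni,
                "p_e_alone": r.p_e_alone,
                "p_eplusp": r.p_eplusp,
                "partial": r.partial,
            }
        )
    return pd.DataFrame(rows)
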