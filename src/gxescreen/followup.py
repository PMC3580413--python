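"""Follow-up characterization of flagged SNPs: genotype-stratified
intervention odds ratios, 1-df/2-df interaction likelihood-ratio tests,
stroke-subtype subsetting, and joint two-SNP case-only models.

Within one trial's cases, the treatment-versus-placebo odds ratio at
genotype level g is recoverable from case-only counts as
``(a/b) / (q/(1-q))`` where a and b are treated and placebo case counts at
that level. Empty cells are reported as NA — small genotype strata (e.g.
rare homozygotes among hemorrhagic cases) make this routine, and an NA is
more honest than a continuity-corrected number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import (
    LRTResult,
    fit_logistic,
    likelihood_ratio_test,
    wald_ci,
)
from .stage2 import case_only_offset

__all__ = [
    "StratifiedORRow",
    "TrendTestResult",
    "genotype_stratified_or",
    "interaction_trend_tests",
    "subtype_subset",
    "joint_two_snp_test",
    "followup_block",
]

logger = logging.getLogger(__name__)


@dataclass
class StratifiedORRow:
    genotype_level: int  # minor-allele count 0, 1 or 2
    or_: float  # NaN when a cell is empty
    ci: tuple  # (lower, upper), NaN pair when OR is NA
    n_treated: int
    n_placebo: int


@dataclass
class TrendTestResult:
    p_1df: float  # additive (linear allele-count) coding
    p_2df: float  # indicator coding for 1 and 2 minor alleles
    subtype_scope: str = "all"
    df_2: int = 2  # collapses below 2 when a genotype cell is empty


def _clean(z, g):
    z = np.asarray(z, dtype=float)
    g = np.asarray(g, dtype=float)
    mask = ~np.isnan(g)
    return z[mask], g[mask]


def genotype_stratified_or(z, g, q: float, level: float = 0.95) -> list:
    """Intervention odds ratio and Wald CI at 0, 1 and 2 minor alleles.

    At each genotype level with treated count a and placebo count b:
    ``or_ = (a/b) / (q/(1-q))`` and the CI is
    ``exp(log or_ +/- z(level) * sqrt(1/a + 1/b))``. Either count at zero
    gives an NA row (counts still reported); no continuity correction.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    z, g = _clean(z, g)
    rows = []
    for lev in (0, 1, 2):
        at = g == lev
        a = int(np.sum(at & (z == 1)))
        b = int(np.sum(at & (z == 0)))
        if a == 0 or b == 0:
            rows.append(StratifiedORRow(lev, np.nan, (np.nan, np.nan), a, b))
            continue
        or_ = (a / b) / (q / (1.0 - q))
        se = np.sqrt(1.0 / a + 1.0 / b)
        lo, hi = wald_ci(np.log(or_), se, level)
        rows.append(StratifiedORRow(lev, or_, (np.exp(lo), np.exp(hi)), a, b))
    return rows


def _indicator_design(g: np.ndarray) -> tuple[np.ndarray, int]:
    """Intercept + indicators for the non-empty heterozygote/homozygote
    levels; returns the design and the number of indicator columns."""
    cols = [np.ones(len(g))]
    k = 0
    for lev in (1, 2):
        ind = (g == lev).astype(float)
        if ind.any():
            cols.append(ind)
            k += 1
    return np.column_stack(cols), k


def interaction_trend_tests(
    z, g, q: float, subtype_scope: str = "all"
) -> TrendTestResult:
    """1-df (additive) and 2-df (indicator) case-only interaction LRTs.

    When a genotype cell is empty the indicator model loses that column and
    the nominal 2-df test collapses to the remaining degrees of freedom; with
    only one genotype contrast left the two tests coincide exactly.
    """
    z, g = _clean(z, g)
    if len(g) == 0 or np.std(g) == 0:
        raise ValueError("monomorphic")
    n = len(z)
    offset = case_only_offset(q, n)
    reduced = fit_logistic(np.ones((n, 1)), z, offset=offset)
    additive = fit_logistic(np.column_stack([np.ones(n), g]), z, offset=offset)
    # a one-armed genotype cell separates the indicator (and sometimes the
    # additive) fit; its likelihood still converges to a finite limit, so
    # the LRT below is the limiting deviance — the OR cell itself is
    # reported NA by genotype_stratified_or
    p_1df = likelihood_ratio_test(additive, reduced, df=1).p_value
    X_ind, df2 = _indicator_design(g)
    if df2 == 1:
        # single contrast: indicator and additive models span the same space
        p_2df = p_1df
    else:
        indicator = fit_logistic(X_ind, z, offset=offset)
        p_2df = likelihood_ratio_test(indicator, reduced, df=df2).p_value
    return TrendTestResult(
        p_1df=p_1df, p_2df=p_2df, subtype_scope=subtype_scope, df_2=df2
    )


def subtype_subset(cases: pd.DataFrame, subtype: str) -> pd.DataFrame:
    """Restrict a case table by stroke subtype.

    ``"all"`` keeps every case, including the unclassified "other" category;
    a named subtype filters exactly on the ``subtype`` column.
    """
    if subtype == "all":
        return cases
    if subtype not in ("ischemic", "hemorrhagic", "other"):
        raise ValueError(f"unknown subtype {subtype!r}")
    return cases[cases["subtype"] == subtype]


def joint_two_snp_test(
    z, g1, g2, q: float, coding: str = "additive"
) -> dict:
    """Joint case-only model containing both SNPs; per-SNP LRT dropping only
    that SNP's term(s).

    Additive coding uses one linear allele-count term per SNP (1-df tests,
    "monotone" interaction); indicator coding uses separate terms for one
    and two minor alleles (2-df tests, fewer when a cell is empty). Perfectly
    correlated genotype vectors are rejected as ``"collinear SNPs"``.
    """
    if coding not in ("additive", "indicator"):
        raise ValueError("coding must be 'additive' or 'indicator'")
    z = np.asarray(z, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = ~np.isnan(g1) & ~np.isnan(g2)
    z, g1, g2 = z[mask], g1[mask], g2[mask]
    for g in (g1, g2):
        if len(g) == 0 or np.std(g) == 0:
            raise ValueError("monomorphic")
    r = np.corrcoef(g1, g2)[0, 1]
    if abs(r) > 1.0 - 1e-10:
        raise ValueError("collinear SNPs")
    n = len(z)
    offset = case_only_offset(q, n)

    def terms(g: np.ndarray) -> list:
        if coding == "additive":
            return [g]
        return [(g == lev).astype(float) for lev in (1, 2) if (g == lev).any()]

    t1, t2 = terms(g1), terms(g2)
    X_full = np.column_stack([np.ones(n), *t1, *t2])
    full = fit_logistic(X_full, z, offset=offset)
    out = {}
    for name, own, other in (("snp1", t1, t2), ("snp2", t2, t1)):
        X_red = np.column_stack([np.ones(n), *other])
        reduced = fit_logistic(X_red, z, offset=offset)
        out[name] = likelihood_ratio_test(full, reduced, df=len(own))
    return out


def followup_block(
    cases: pd.DataFrame,
    genotype: np.ndarray,
    q: float,
    trial: str,
    rsid: str,
    scopes: tuple = ("all", "ischemic", "hemorrhagic"),
    alleles: tuple | None = None,
) -> pd.DataFrame:
    """One trial-by-SNP block of the follow-up table: per subtype scope, the
    case count, OR (CI) at each genotype level, and the 2-df/1-df p-values.

    ``cases`` must carry ``z`` (assignment) and ``subtype`` columns aligned
    with ``genotype``.
    """
    rows = []
    work = cases.assign(_g=genotype)
    for scope in scopes:
        sub = subtype_subset(work, scope)
        z = sub["z"].to_numpy(dtype=float)
        g = sub["_g"].to_numpy(dtype=float)
        n_cases = int(len(sub))
        try:
            strat = genotype_stratified_or(z, g, q)
            trend = interaction_trend_tests(z, g, q, subtype_scope=scope)
            p1, p2 = trend.p_1df, trend.p_2df
        except ValueError as exc:
            logger.warning("%s/%s/%s: %s; NA row", trial, rsid, scope, exc)
            strat = [
                StratifiedORRow(lev, np.nan, (np.nan, np.nan), 0, 0)
                for lev in (0, 1, 2)
            ]
            p1 = p2 = np.nan
        row = {"trial": trial, "rsid": rsid, "scope": scope, "n_cases": n_cases}
        for sr in strat:
            label = f"g{sr.genotype_level}"
            if alleles is not None and alleles[0] != alleles[1]:
                ref, alt = alleles
                label = {0: ref + ref, 1: ref + alt, 2: alt + alt}[sr.genotype_level]
            row[f"or_{label}"] = sr.or_
            row[f"ci_{label}_lo"] = sr.ci[0]
            row[f"ci_{label}_hi"] = sr.ci[1]
            row[f"n_treated_{label}"] = sr.n_treated
            row[f"n_placebo_{label}"] = sr.n_placebo
        row["p_2df"] = p2
        row["p_1df"] = p1
        rows.append(row)
    return pd.DataFrame(rows)
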