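"""Tests for genotype-stratified odds ratios, trend tests, subtype
subsetting and joint two-SNP case-only models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit, logit

from gxescreen.followup import (
    followup_block,
    genotype_stratified_or,
    interaction_trend_tests,
    joint_two_snp_test,
    subtype_subset,
)
from gxescreen.stage2 import case_only_offset
from gxescreen.stats_core import fit_logistic


def _counts_to_vectors(table):
    zs, gs = [], []
    for g, (a, b) in table.items():
        zs += [1.0] * a + [0.0] * b
        gs += [float(g)] * (a + b)
    return np.array(zs), np.array(gs)


def _caseonly_draw(rng, n, maf, q, beta2, beta0=0.0):
    """Draw (z, g) directly from the case-only model logit P(Z=1|G) =
    log(q/(1-q)) + beta0 + beta2 * G."""
    g = rng.binomial(2, maf, n).astype(float)
    p = expit(logit(q) + beta0 + beta2 * g)
    z = (rng.random(n) < p).astype(float)
    return z, g


class TestStratifiedOR:
    def test_symmetric_counts(self):
        z, g = _counts_to_vectors({0: (15, 15), 1: (8, 8), 2: (2, 2)})
        rows = genotype_stratified_or(z, g, q=0.5)
        for r in rows:
            assert r.or_ == pytest.approx(1.0)

    def test_closed_form_example(self):
        z, g = _counts_to_vectors({0: (20, 10), 1: (1, 1), 2: (1, 1)})
        r0 = genotype_stratified_or(z, g, q=0.5)[0]
        assert r0.or_ == pytest.approx(2.0)
        assert r0.ci[0] == pytest.approx(0.936, abs=1e-3)
        assert r0.ci[1] == pytest.approx(4.273, abs=1e-3)

    def test_empty_cell_reports_na(self):
        z, g = _counts_to_vectors({0: (20, 15), 1: (5, 3), 2: (2, 0)})
        r2 = genotype_stratified_or(z, g, q=0.5)[2]
        assert np.isnan(r2.or_) and np.isnan(r2.ci[0]) and np.isnan(r2.ci[1])
        assert (r2.n_treated, r2.n_placebo) == (2, 0)

    def test_q_scales_the_or(self):
        z, g = _counts_to_vectors({0: (20, 10), 1: (1, 1), 2: (1, 1)})
        r = genotype_stratified_or(z, g, q=0.4)[0]
        assert r.or_ == pytest.approx((20 / 10) / (0.4 / 0.6))

    def test_matches_no_intercept_indicator_fit(self):
        """Two routes, one estimand: raw count ratios equal the exponentiated
        coefficients of an offset logistic fit on genotype-level indicators
        with no intercept, to 1e-6."""
        rng = np.random.default_rng(12)
        z, g = _caseonly_draw(rng, 400, 0.35, 0.5, beta2=-0.6, beta0=0.3)
        rows = genotype_stratified_or(z, g, q=0.5)
        X = np.column_stack([(g == lev).astype(float) for lev in (0, 1, 2)])
        fit = fit_logistic(X, z, offset=case_only_offset(0.5, len(z)))
        for j, r in enumerate(rows):
            assert np.log(r.or_) == pytest.approx(fit.coefficients[j], abs=1e-6)


class TestTrendTests:
    def test_balanced_counts_give_unit_pvalues(self):
        z, g = _counts_to_vectors({0: (20, 20), 1: (10, 10), 2: (4, 4)})
        res = interaction_trend_tests(z, g, q=0.5)
        assert res.p_1df == pytest.approx(1.0)
        assert res.p_2df == pytest.approx(1.0)

    def test_empty_homozygote_cell_collapses_2df(self):
        z, g = _counts_to_vectors({0: (25, 18), 1: (6, 11)})  # no G=2 cases
        res = interaction_trend_tests(z, g, q=0.5)
        assert res.df_2 == 1
        assert res.p_2df == pytest.approx(res.p_1df)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            interaction_trend_tests(np.array([1.0, 0.0]), np.zeros(2), q=0.5)

    def test_linear_alternative_favors_1df(self):
        """Under a monotone interaction (log-OR -0.6 per allele) the additive
        1-df test is at least as significant as the 2-df test in >= 70% of
        replicates at 400 cases."""
        rng = np.random.default_rng(14)
        wins = 0
        for _ in range(200):
            z, g = _caseonly_draw(rng, 400, 0.3, 0.5, beta2=-0.6)
            res = interaction_trend_tests(z, g, q=0.5)
            wins += res.p_1df <= res.p_2df
        assert wins >= 140

    def test_allele_flip_equivariance(self):
        """Recoding G -> 2-G mirrors the stratified ORs and leaves both LRT
        p-values unchanged."""
        rng = np.random.default_rng(15)
        z, g = _caseonly_draw(rng, 300, 0.4, 0.5, beta2=0.5)
        rows = genotype_stratified_or(z, g, q=0.5)
        rows_flip = genotype_stratified_or(z, 2.0 - g, q=0.5)
        for lev in (0, 1, 2):
            a, b = rows[lev], rows_flip[2 - lev]
            if np.isnan(a.or_):
                assert np.isnan(b.or_)
            else:
                assert a.or_ == pytest.approx(b.or_)
        t = interaction_trend_tests(z, g, q=0.5)
        t_flip = interaction_trend_tests(z, 2.0 - g, q=0.5)
        assert t.p_1df == pytest.approx(t_flip.p_1df, abs=1e-9)
        assert t.p_2df == pytest.approx(t_flip.p_2df, abs=1e-9)

    def test_additive_or_between_adjacent_ratios(self):
        """exp(beta2) lies between or(1)/or(0) and or(2)/or(1) when all cells
        are nonempty and the stratified ORs are monotone."""
        z, g = _counts_to_vectors({0: (40, 20), 1: (30, 25), 2: (10, 14)})
        rows = genotype_stratified_or(z, g, q=0.5)
        ratios = sorted([rows[1].or_ / rows[0].or_, rows[2].or_ / rows[1].or_])
        X = np.column_stack([np.ones(len(g)), g])
        fit = fit_logistic(X, z, offset=case_only_offset(0.5, len(z)))
        assert ratios[0] <= np.exp(fit.coefficients[1]) <= ratios[1]


class TestSubtypes:
    def test_partition(self, tiny_dataset):
        out = tiny_dataset["outcomes"]
        cases = out[out.stroke]
        n_all = len(subtype_subset(cases, "all"))
        parts = sum(
            len(subtype_subset(cases, s))
            for s in ("ischemic", "hemorrhagic", "other")
        )
        assert n_all == parts == len(cases)

    def test_missing_subtype_gives_empty(self):
        cases = pd.DataFrame({"subtype": ["other", "other"], "stroke": [True, True]})
        assert len(subtype_subset(cases, "ischemic")) == 0

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError):
            subtype_subset(pd.DataFrame({"subtype": []}), "lacunar")


class TestJointTwoSnp:
    def test_identical_genotypes_rejected(self):
        rng = np.random.default_rng(16)
        z, g = _caseonly_draw(rng, 100, 0.3, 0.5, beta2=0.0)
        with pytest.raises(ValueError, match="collinear"):
            joint_two_snp_test(z, g, g.copy(), q=0.5)

    def test_null_second_snp_leaves_first_p_stable(self):
        """Adding an independent null SNP to the model shifts the first
        SNP's p by little (median |difference| <= 0.05 over 200 draws)."""
        rng = np.random.default_rng(17)
        diffs = []
        for _ in range(200):
            z, g1 = _caseonly_draw(rng, 300, 0.3, 0.5, beta2=-0.5)
            g2 = rng.binomial(2, 0.3, 300).astype(float)
            joint = joint_two_snp_test(z, g1, g2, q=0.5)["snp1"].p_value
            single = interaction_trend_tests(z, g1, q=0.5).p_1df
            diffs.append(abs(joint - single))
        assert np.median(diffs) <= 0.05

    def test_opposite_sign_interactions_both_detected(self):
        """Two SNPs with opposite-sign interactions: both 1-df joint tests
        reject at 0.05 in >= 80% of replicates at 600 cases."""
        rng = np.random.default_rng(18)
        both = 0
        for _ in range(100):
            g1 = rng.binomial(2, 0.3, 600).astype(float)
            g2 = rng.binomial(2, 0.3, 600).astype(float)
            p = expit(0.0 + 0.55 * g1 - 0.55 * g2)  # q=0.5 offset is 0
            z = (rng.random(600) < p).astype(float)
            res = joint_two_snp_test(z, g1, g2, q=0.5)
            both += (res["snp1"].p_value < 0.05) and (res["snp2"].p_value < 0.05)
        assert both >= 80

    def test_indicator_coding_df(self):
        rng = np.random.default_rng(19)
        z, g1 = _caseonly_draw(rng, 400, 0.4, 0.5, beta2=0.3)
        g2 = rng.binomial(2, 0.4, 400).astype(float)
        res = joint_two_snp_test(z, g1, g2, q=0.5, coding="indicator")
        assert res["snp1"].df == 2
        assert res["snp2"].df == 2


class TestFollowupBlock:
    def test_na_convention_and_2df_collapse(self):
        """An empty G=2 cell yields an NA OR cell and identical p-2df/p-1df,
        mirroring the sparse hemorrhagic rows of small trials."""
        z, g = _counts_to_vectors({0: (30, 22), 1: (6, 9)})
        cases = pd.DataFrame({
            "subtype": ["hemorrhagic"] * len(z),
            "z": z,
        })
        block = followup_block(cases, g, q=0.5, trial="E+P", rsid="rs1",
                               scopes=("hemorrhagic",), alleles=("G", "A"))
        row = block.iloc[0]
        assert np.isnan(row["or_AA"])
        assert np.isnan(row["ci_AA_lo"]) and np.isnan(row["ci_AA_hi"])
        assert row["p_2df"] == pytest.approx(row["p_1df"])
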