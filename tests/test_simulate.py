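"""Tests for the synthetic cohort/genotype/outcome/matching generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from gxescreen.simulate import (
    CohortDesign,
    EffectConfig,
    SnpSpec,
    assign_cohort_and_trials,
    generate_genotypes,
    make_fixture,
    select_matched_controls,
    simulate_outcomes,
    simulate_trial_members,
)
from gxescreen.stats_core import fit_logistic


def _snp(rsid="rs1", maf=0.3, **kw):
    return SnpSpec(rsid, "1", 1000, "A", "G", maf, **kw)


class TestGenotypes:
    def test_maf_without_structure(self):
        g = generate_genotypes(20000, [_snp(maf=0.09)], np.zeros(20000), seed=1)
        assert np.nanmean(g.values) / 2 == pytest.approx(0.09, abs=0.005)

    def test_hwe_within_subpopulation(self):
        g = generate_genotypes(50000, [_snp(maf=0.3)], np.zeros(50000), seed=2)
        counts = np.bincount(g.values[:, 0].astype(int), minlength=3) / 50000
        expected = np.array([0.49, 0.42, 0.09])
        assert counts == pytest.approx(expected, abs=0.01)

    def test_perfect_ld_partner_is_copy(self):
        snps = [
            _snp("a", 0.2, ld_partner="b", target_r2=1.0),
            SnpSpec("b", "1", 2000, "A", "G", 0.2, ld_partner="a", target_r2=1.0),
        ]
        g = generate_genotypes(500, snps, np.zeros(500), seed=3)
        r = np.corrcoef(g.values[:, 0], g.values[:, 1])[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_ld_pair_reaches_target_r2(self):
        snps = [
            _snp("a", 0.3, ld_partner="b", target_r2=0.98),
            SnpSpec("b", "1", 2000, "A", "G", 0.3, ld_partner="a", target_r2=0.98),
        ]
        g = generate_genotypes(30000, snps, np.zeros(30000), seed=4)
        r2 = np.corrcoef(g.values[:, 0], g.values[:, 1])[0, 1] ** 2
        assert r2 == pytest.approx(0.98, abs=0.02)

    def test_balding_nichols_spreads_frequencies(self):
        labels = np.repeat([0, 1, 2, 3], 2000)
        g = generate_genotypes(8000, [_snp(maf=0.3, fst=0.2)], labels, seed=5)
        freqs = [np.nanmean(g.values[labels == k, 0]) / 2 for k in range(4)]
        assert np.std(freqs) > 0.02  # drift across subpopulations

    def test_deterministic_under_seed(self):
        snps = [_snp("a", 0.2), _snp("b", 0.4)]
        snps[1].position = 2000
        a = generate_genotypes(300, snps, np.zeros(300), seed=9)
        b = generate_genotypes(300, snps, np.zeros(300), seed=9)
        assert np.array_equal(a.values, b.values)

    def test_duplicate_rsid_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            generate_genotypes(10, [_snp("x"), _snp("x")], np.zeros(10), seed=0)

    def test_nonreciprocal_ld_rejected(self):
        snps = [_snp("a", 0.2, ld_partner="b", target_r2=0.9), _snp("b", 0.2)]
        with pytest.raises(ValueError, match="reciprocal"):
            generate_genotypes(10, snps, np.zeros(10), seed=0)

    def test_missingness_cap(self):
        g = generate_genotypes(5000, [_snp(missing_rate=0.1)], np.zeros(5000), seed=6)
        frac = np.isnan(g.values).mean()
        assert frac == pytest.approx(0.1, abs=0.02)


class TestCohortAssignment:
    def test_randomization_fraction(self):
        design = CohortDesign(os_fraction=0.0, ht_participation=1.0)
        subj = assign_cohort_and_trials(20000, design, seed=1)
        z = subj.loc[subj.ht_trial != "none", "z_ht"]
        assert z.mean() == pytest.approx(0.5, abs=0.015)

    def test_hysterectomy_routes_trials(self):
        subj = assign_cohort_and_trials(5000, CohortDesign(), seed=2)
        assert (subj.loc[subj.ht_trial == "E-alone", "hysterectomy"]).all()
        assert (~subj.loc[subj.ht_trial == "E+P", "hysterectomy"]).all()

    def test_no_hysterectomy_means_no_e_alone(self):
        subj = assign_cohort_and_trials(
            3000, CohortDesign(hysterectomy_prevalence=0.0), seed=3
        )
        assert (subj.ht_trial != "E-alone").all()

    def test_pure_observational_has_no_assignments(self):
        subj = assign_cohort_and_trials(1000, CohortDesign(os_fraction=1.0), seed=4)
        assert subj[["z_ht", "z_dm", "z_cad"]].isna().all().all()

    def test_ct_members_join_a_component(self):
        subj = assign_cohort_and_trials(5000, CohortDesign(), seed=5)
        ct = subj[subj.cohort == "CT"]
        assert (ct.in_ht | ct.in_dm).all()


class TestOutcomes:
    def test_baseline_rate(self, tiny_dataset):
        n = 50000
        design = CohortDesign()
        subj = assign_cohort_and_trials(n, design, seed=7)
        geno = generate_genotypes(n, [_snp()], subj.subpopulation.to_numpy(), seed=7)
        eff = EffectConfig(baseline_logodds=float(logit(0.05)))
        out = simulate_outcomes(subj, geno, eff, seed=7)
        assert out.stroke.mean() == pytest.approx(0.05, abs=0.004)

    def test_subtype_iff_stroke(self, tiny_dataset):
        out = tiny_dataset["outcomes"]
        assert ((out.subtype == "none") == (~out.stroke)).all()

    def test_unknown_rsid_rejected(self):
        subj = assign_cohort_and_trials(50, CohortDesign(), seed=8)
        geno = generate_genotypes(50, [_snp()], subj.subpopulation.to_numpy(), seed=8)
        eff = EffectConfig(snp_marginal_logodds={"nope": 0.5})
        with pytest.raises(ValueError, match="nope"):
            simulate_outcomes(subj, geno, eff, seed=8)

    def test_deterministic_under_seed(self, tiny_dataset):
        from gxescreen.simulate import generate_dataset

        again = generate_dataset("tiny", seed=11)
        pd.testing.assert_frame_equal(tiny_dataset["outcomes"], again["outcomes"])

    def test_generating_model_is_recoverable(self):
        """Refitting the generating logistic model recovers the interaction
        log-OR within its 95% Wald interval in >= 90/100 replicates."""
        rng = np.random.default_rng(42)
        truth = -0.8
        covered = 0
        for _ in range(100):
            g, z, case = simulate_trial_members(
                6000, 0.25, 0.5, float(logit(0.05)), np.log(1.2), np.log(1.4),
                truth, rng=rng,
            )
            X = np.column_stack([np.ones(len(g)), g, z, g * z])
            fit = fit_logistic(X, case.astype(float))
            lo = fit.coefficients[3] - 1.96 * fit.se[3]
            hi = fit.coefficients[3] + 1.96 * fit.se[3]
            covered += lo <= truth <= hi
        assert covered >= 90

    def test_randomization_independent_of_genotype(self):
        """|mean corr(G, Z)| < 0.01 over 200 replicates — the premise that
        makes case-only interaction testing valid."""
        rng = np.random.default_rng(13)
        corrs = [
            np.corrcoef(*simulate_trial_members(
                2000, 0.3, 0.5, float(logit(0.05)), rng=rng)[:2])[0, 1]
            for _ in range(200)
        ]
        assert abs(np.mean(corrs)) < 0.01


class TestMatching:
    def test_postconditions(self, f13_dataset):
        subj = f13_dataset["subjects"].set_index("subject_id")
        out = f13_dataset["outcomes"].set_index("subject_id")
        matched = f13_dataset["matched"]
        n_cases = int(out.stroke.sum())
        assert len(matched.pairs) + len(matched.dropped_cases) == n_cases
        controls = [c for _, c in matched.pairs]
        assert len(set(controls)) == len(controls)  # no control reuse
        for case_id, control_id in matched.pairs[:200]:
            for factor in ("ethnicity", "cohort", "in_ht", "in_dm", "in_cad",
                           "hysterectomy", "prevalent_stroke"):
                assert subj.loc[case_id, factor] == subj.loc[control_id, factor]
            assert abs(subj.loc[case_id, "age"] - subj.loc[control_id, "age"]) <= 2.0
            assert not out.loc[control_id, "stroke"]
            assert out.loc[case_id, "stroke"]

    def test_component_counts_mirror(self, f13_dataset):
        """Equal case and control counts within every trial component."""
        subj = f13_dataset["subjects"].set_index("subject_id")
        matched = f13_dataset["matched"]
        for comp in ("in_ht", "in_dm", "in_cad"):
            n_case = sum(subj.loc[c, comp] for c, _ in matched.pairs)
            n_ctrl = sum(subj.loc[c, comp] for _, c in matched.pairs)
            assert n_case == n_ctrl

    def test_unmatchable_case_is_dropped(self):
        subjects = pd.DataFrame(
            {
                "subject_id": ["c1", "p1", "p2"],
                "ethnicity": ["unique", "white", "white"],
                "age": [60.0, 60.0, 61.0],
            }
        )
        outcomes = pd.DataFrame(
            {"subject_id": ["c1", "p1", "p2"], "stroke": [True, False, False]}
        )
        matched = select_matched_controls(
            subjects, outcomes, matching_factors=["ethnicity"], seed=1
        )
        assert matched.pairs == []
        assert matched.dropped_cases == ["c1"]


class TestFixtures:
    def test_tiny_roundtrip(self, tmp_path):
        from gxescreen.io import read_genotypes, read_phenotypes

        paths = make_fixture("tiny", seed=2, outdir=tmp_path)
        pheno = read_phenotypes(paths["phenotypes"])
        geno = read_genotypes(paths["genotypes"])
        assert len(pheno) <= 200
        assert len(geno.snps) <= 20
        assert geno.subject_ids == pheno.subject_id.tolist()

    def test_byte_identical_under_seed(self, tmp_path):
        p1 = make_fixture("tiny", seed=4, outdir=tmp_path / "a")
        p2 = make_fixture("tiny", seed=4, outdir=tmp_path / "b")
        for key in ("phenotypes", "genotypes", "pairs"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_f13a1_like_manifest_and_realized_ld(self, tmp_path, f13_dataset):
        import json

        paths = make_fixture("f13a1_like", seed=2, outdir=tmp_path)
        manifest = json.loads(paths["manifest"].read_text())
        pair = [s for s in manifest["snps"] if s["rsid"] == "rs_f13_a"][0]
        assert pair["base_maf"] == pytest.approx(0.09)
        assert pair["target_r2"] > 0.98
        assert manifest["effects"]["interaction_logodds"]["rs_f13_a|E+P"] < 0
        gm = f13_dataset["genotypes"]
        r2 = np.corrcoef(gm.column("rs_f13_a"), gm.column("rs_f13_b"))[0, 1] ** 2
        assert r2 > 0.95

    def test_unknown_preset_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="preset"):
            make_fixture("nope", seed=1, outdir=tmp_path)
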