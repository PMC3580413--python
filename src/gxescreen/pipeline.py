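"""End-to-end orchestration: simulate (or load) -> matched sample -> stage-1
marginal screen -> stage-2 case-only interaction tests -> follow-up tables
-> AUC comparison, with file outputs, a manifest, and full seed control.

Every stage writes a TSV; the manifest records the configuration, all
derived seeds, and per-stage counts, so a re-run with the same
configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discrimination import RiskModelSpec, bootstrap_auc_comparison, fit_and_score
from .followup import followup_block, joint_two_snp_test
from .io import read_genotypes, read_phenotypes
from .simulate import GenotypeMatrix, make_fixture, select_matched_controls
from .stage1 import (
    Stage1Result,
    compute_genotype_pcs,
    ld_pruned,
    marginal_scan,
    stage1_table,
)
from .stage2 import HT_TRIALS, run_stage2, stage2_table

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_COVARIATES", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "stage1", "stage2", "followup", "auc")

# confounders + matching variables + randomization assignments; genotype PCs
# are appended by the stage-1 scan itself
DEFAULT_COVARIATES = [
    "age",
    "ethnicity",
    "cohort",
    "in_ht",
    "in_dm",
    "in_cad",
    "hysterectomy",
    "prevalent_stroke",
    "followup_year",
    "smoking",
    "physical_functioning",
    "diabetes",
    "hypertension",
    "aspirin",
    "statin",
    "z_ealone",
    "z_ep",
    "z_dm",
    "z_cad",
]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; ``seed`` drives every random stage."""

    outdir: str = "gxescreen_out"
    profile: str | None = None  # simulation preset; alternatively file inputs:
    phenotypes: str | None = None
    genotypes: str | None = None
    snp_metadata: str | None = None
    pairs: str | None = None
    genotype_format: str = "tsv"
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    k_pcs: int = 10
    stage1_threshold: float = 0.05
    stage1_test: str = "wald"
    fdr_threshold: float = 0.05
    q_by_trial: dict = field(
        default_factory=lambda: {"E-alone": 0.5, "E+P": 0.5, "DM": 0.4, "CaD": 0.5}
    )
    subtype_scopes: tuple = ("all", "ischemic", "hemorrhagic")
    n_boot: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("stage1_threshold", "fdr_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.profile is None and (self.phenotypes is None or self.genotypes is None):
            raise ValueError("either a simulation profile or input files are required")
        if self.profile is not None and self.seed is None:
            raise ValueError("seed is mandatory when simulating")


def _stage_seeds(master: int) -> dict:
    """Derive one independent child seed per random stage from the master
    seed (numpy SeedSequence spawning, stage order fixed)."""
    children = np.random.SeedSequence(master).spawn(3)
    names = ("simulate", "match", "bootstrap")
    return {
        name: int(c.generate_state(1)[0] % 2**31) for name, c in zip(names, children)
    }


def _add_assignment_columns(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-component active-assignment indicators, zero for non-members."""
    out = pheno.copy()
    trial = out["ht_trial"].to_numpy()
    z_ht = np.nan_to_num(out["z_ht"].to_numpy(dtype=float))
    out["z_ealone"] = np.where(trial == "E-alone", z_ht, 0.0)
    out["z_ep"] = np.where(trial == "E+P", z_ht, 0.0)
    for col in ("z_dm", "z_cad"):
        out[col] = np.nan_to_num(out[col].to_numpy(dtype=float))
    return out


def _matched_sample(
    pheno: pd.DataFrame, genotypes: GenotypeMatrix, pairs: pd.DataFrame
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Restrict to matched pairs, add pair ids, align genotype rows."""
    case_ids = pairs["case_id"].tolist()
    control_ids = pairs["control_id"].tolist()
    order = case_ids + control_ids
    pair_id = list(range(len(case_ids))) * 2
    sub = pheno.set_index("subject_id").loc[order].reset_index()
    sub["pair_id"] = pair_id
    row_of = {sid: i for i, sid in enumerate(genotypes.subject_ids)}
    idx = [row_of[sid] for sid in order]
    gm = GenotypeMatrix(
        values=genotypes.values[idx],
        snps=genotypes.snps,
        subject_ids=order,
    )
    return sub, gm


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def run_pipeline(config: PipelineConfig, through: str = "auc") -> dict:
    """Execute the pipeline up to and including stage ``through``.

    Earlier stages always run (they are cheap and deterministic under the
    configured seed), so each CLI subcommand is self-contained. Returns a
    dict of output paths and in-memory results; writes ``manifest.json``
    with configuration, derived seeds and per-stage counts.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    last = STAGES.index(through)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed if config.seed is not None else 0)
    counts: dict = {}
    out: dict = {"outdir": outdir}

    # -- simulate or load -------------------------------------------------
    if config.profile is not None:
        paths = make_fixture(config.profile, seeds["simulate"], outdir / "data")
        pheno = read_phenotypes(paths["phenotypes"])
        genotypes = read_genotypes(paths["genotypes"], metadata=paths["snps"])
        pairs = pd.read_csv(paths["pairs"], sep="\t")
        out["data"] = paths
    else:
        pheno = read_phenotypes(config.phenotypes)
        genotypes = read_genotypes(
            config.genotypes, fmt=config.genotype_format,
            metadata=config.snp_metadata,
        )
        if config.pairs is not None:
            pairs = pd.read_csv(config.pairs, sep="\t")
        else:
            subjects = pheno.drop(columns=["stroke", "subtype", "event_year"],
                                  errors="ignore")
            outcomes = pheno[["subject_id", "stroke", "subtype", "followup_year"]]
            matched = select_matched_controls(
                subjects, outcomes.assign(
                    event_year=pheno.get("event_year", np.nan)),
                seed=seeds["match"],
            )
            pairs = pd.DataFrame(matched.pairs, columns=["case_id", "control_id"])
    pheno = _add_assignment_columns(pheno)
    counts["n_subjects"] = len(pheno)
    counts["n_cases_total"] = int(pheno["stroke"].sum())
    counts["n_pairs"] = len(pairs)
    counts["n_snps"] = len(genotypes.snps)
    logger.info("data: %(n_subjects)d subjects, %(n_pairs)d matched pairs, "
                "%(n_snps)d SNPs", counts)
    sample, gm = _matched_sample(pheno, genotypes, pairs)
    out["sample"], out["genotypes"] = sample, gm
    if last < 1:
        _write_manifest(outdir, config, seeds, counts)
        return out

    # -- stage 1 ----------------------------------------------------------
    pca_panel = ld_pruned(gm, r2_threshold=0.2)
    k = min(config.k_pcs, max(np.linalg.matrix_rank(
        np.nan_to_num(pca_panel.values
                      - np.nanmean(pca_panel.values, axis=0))) - 1, 0))
    pcs = compute_genotype_pcs(pca_panel, k) if k > 0 else None
    s1 = marginal_scan(
        sample, gm, config.covariates, pcs=pcs,
        threshold=config.stage1_threshold, test=config.stage1_test,
    )
    t1 = stage1_table(s1)
    t1["flipped"] = t1["rsid"].map({r.rsid: r.flipped for r in s1})
    out["stage1"] = s1
    out["stage1_path"] = outdir / "stage1.tsv"
    _write(t1, out["stage1_path"])
    counts["k_pcs_used"] = k
    counts["stage1_n_pass"] = int(sum(r.passes for r in s1))
    logger.info("stage1: %d/%d SNPs pass p<%g", counts["stage1_n_pass"],
                len(s1), config.stage1_threshold)
    if last < 2:
        _write_manifest(outdir, config, seeds, counts)
        return out

    # -- stage 2 ----------------------------------------------------------
    s2 = run_stage2(s1, sample, gm, config.q_by_trial, config.fdr_threshold)
    out["stage2"] = s2
    out["stage2_path"] = outdir / "stage2.tsv"
    _write(stage2_table(s2, s1, gm), out["stage2_path"])
    counts["stage2_family_size"] = counts["stage1_n_pass"]
    flagged = [r.rsid for r in s2
               if np.isfinite(r.fdr) and r.fdr < config.fdr_threshold]
    counts["stage2_n_flagged"] = len(flagged)
    logger.info("stage2: %d flagged at FDR<%g", len(flagged), config.fdr_threshold)
    if last < 3:
        _write_manifest(outdir, config, seeds, counts)
        return out

    # -- follow-up --------------------------------------------------------
    def _dedupe_ld(rsids: list, r2_cap: float = 0.8, cap: int = 2) -> list:
        """Keep at most ``cap`` ranked SNPs, one per LD cluster."""
        chosen: list = []
        for rsid in rsids:
            g = np.nan_to_num(gm.column(rsid))
            if all(
                np.corrcoef(g, np.nan_to_num(gm.column(o)))[0, 1] ** 2 < r2_cap
                for o in chosen
            ):
                chosen.append(rsid)
            if len(chosen) == cap:
                break
        return chosen

    targets = flagged or [r.rsid for r in s2[:1]]
    if not flagged and targets:
        logger.info("followup: nothing flagged; describing top-ranked SNP only")
    flips = {r.rsid: r.flipped for r in s1}
    spec_by_id = {s.rsid: s for s in gm.snps}
    blocks = []
    for rsid in targets:
        g_full = gm.column(rsid)
        if flips.get(rsid):
            g_full = 2.0 - g_full
        for trial in HT_TRIALS:
            mask = sample["stroke"].to_numpy(dtype=bool) & (
                sample["ht_trial"].to_numpy() == trial)
            cases = sample[mask][["subtype"]].assign(
                z=sample["z_ht"].to_numpy(dtype=float)[mask])
            spec = spec_by_id[rsid]
            blocks.append(
                followup_block(
                    cases, g_full[mask], config.q_by_trial[trial], trial, rsid,
                    scopes=tuple(config.subtype_scopes),
                    alleles=(spec.ref_allele, spec.alt_allele),
                )
            )
    ftab = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame(
        columns=["trial", "rsid", "scope", "n_cases", "p_2df", "p_1df"])
    out["followup_path"] = outdir / "followup.tsv"
    _write(ftab, out["followup_path"])
    counts["followup_n_snps"] = len(targets)

    # joint two-SNP case-only model for the top pair of distinct signals
    distinct = _dedupe_ld(targets)
    if len(distinct) >= 2:
        joint_rows = []
        r1, r2 = distinct[0], distinct[1]
        g1 = gm.column(r1)
        g2 = gm.column(r2)
        for trial in HT_TRIALS:
            mask = sample["stroke"].to_numpy(dtype=bool) & (
                sample["ht_trial"].to_numpy() == trial)
            z = sample["z_ht"].to_numpy(dtype=float)[mask]
            for coding in ("additive", "indicator"):
                try:
                    res = joint_two_snp_test(
                        z, g1[mask], g2[mask], config.q_by_trial[trial], coding)
                except ValueError as exc:
                    logger.info("joint %s/%s in %s skipped: %s", r1, r2, trial, exc)
                    continue
                for name, rsid in (("snp1", r1), ("snp2", r2)):
                    joint_rows.append(
                        {"trial": trial, "coding": coding, "rsid": rsid,
                         "statistic": res[name].statistic, "df": res[name].df,
                         "p": res[name].p_value})
        if joint_rows:
            out["joint_path"] = outdir / "joint.tsv"
            _write(pd.DataFrame(joint_rows), out["joint_path"])
    if last < 4:
        _write_manifest(outdir, config, seeds, counts)
        return out

    # -- discrimination ---------------------------------------------------
    base = RiskModelSpec(covariates=list(config.covariates))
    rows = []
    try:
        _, auc_base = fit_and_score(sample, base, gm, n_boot=config.n_boot,
                                    seed=seeds["bootstrap"])
        base_ok = True
        rows.append({"model": "covariates", "auc": auc_base.auc,
                     "ci_lo": auc_base.ci[0], "ci_hi": auc_base.ci[1],
                     "delta": np.nan, "p": np.nan, "n_boot": config.n_boot,
                     "seed": seeds["bootstrap"]})
        counts["auc_base"] = auc_base.auc
    except ValueError as exc:
        logger.warning("base risk model unusable on this sample: %s", exc)
        base_ok = False
        rows.append({"model": "covariates", "auc": np.nan, "ci_lo": np.nan,
                     "ci_hi": np.nan, "delta": np.nan, "p": np.nan,
                     "n_boot": config.n_boot, "seed": seeds["bootstrap"]})
    if targets and base_ok:
        # one representative SNP per LD cluster, mirroring the follow-up
        ext = RiskModelSpec(covariates=list(config.covariates),
                            include_snps=_dedupe_ld(targets),
                            include_interactions=True)
        try:
            _, auc_ext = fit_and_score(sample, ext, gm, n_boot=config.n_boot,
                                       seed=seeds["bootstrap"])
            comp = bootstrap_auc_comparison(sample, base, ext, gm,
                                            n_boot=config.n_boot,
                                            seed=seeds["bootstrap"])
            rows.append({"model": "covariates+snps+interactions",
                         "auc": auc_ext.auc, "ci_lo": auc_ext.ci[0],
                         "ci_hi": auc_ext.ci[1], "delta": comp.delta,
                         "p": comp.p_value, "n_boot": config.n_boot,
                         "seed": seeds["bootstrap"]})
            counts["auc_delta"] = comp.delta
        except ValueError as exc:
            logger.warning("extended risk model skipped: %s", exc)
    out["auc_path"] = outdir / "auc.tsv"
    _write(pd.DataFrame(rows), out["auc_path"])
    _write_manifest(outdir, config, seeds, counts)
    return out


def _write_manifest(outdir: Path, config: PipelineConfig, seeds: dict,
                    counts: dict) -> None:
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "derived_seeds": seeds,
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
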