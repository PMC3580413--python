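"""Synthetic cohort, genotype, randomization, outcome and matched-set
generation.

The generator emulates the design of a large postmenopausal cohort split
into an observational study (OS) and a clinical-trial (CT) arm. CT members
belong to a hormone-therapy (HT) component and/or a dietary-modification
(DM) component, with later randomization into a calcium/vitamin-D (CaD)
component. The HT component comprises two non-overlapping trials: an
estrogen-alone trial (E-alone) restricted to hysterectomized women and an
estrogen-plus-progestin trial (E+P) for women with a uterus. Each trial
randomizes a known fraction ``q`` to active treatment.

Genotypes follow the Balding-Nichols model: within each subpopulation a
SNP's allele frequency is a Beta draw around its base minor-allele frequency
with spread governed by Fst, and genotypes are Hardy-Weinberg
(binomial(2, freq)) within subpopulation. High-LD pairs are generated by
haplotype copying with a flip probability calibrated to the target r^2.

Stroke outcomes come from a logistic model with covariate, SNP-marginal,
treatment-main and SNP x treatment interaction terms, so every downstream
stage of the screen can be tested against a known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SnpSpec",
    "CohortDesign",
    "EffectConfig",
    "GenotypeMatrix",
    "MatchedSet",
    "generate_genotypes",
    "assign_cohort_and_trials",
    "simulate_outcomes",
    "select_matched_controls",
    "simulate_trial_members",
    "simulate_trial_cases",
    "make_fixture",
    "PRESETS",
]

TRIALS = ("E-alone", "E+P", "DM", "CaD")
SUBTYPES = ("ischemic", "hemorrhagic", "other")
FOLLOWUP_YEARS = 9.0


@dataclass
class SnpSpec:
    """Metadata and generative parameters for one simulated SNP."""

    rsid: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    base_maf: float
    fst: float = 0.0
    ld_partner: str | None = None
    target_r2: float | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.rsid}: position must be positive (1-based)")
        if not 0.0 < self.base_maf <= 0.5:
            raise ValueError(f"{self.rsid}: base_maf must be in (0, 0.5]")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"{self.rsid}: fst must be in [0, 1)")
        if (self.ld_partner is None) != (self.target_r2 is None):
            raise ValueError(f"{self.rsid}: ld_partner and target_r2 go together")
        if self.target_r2 is not None and not 0.0 < self.target_r2 <= 1.0:
            raise ValueError(f"{self.rsid}: target_r2 must be in (0, 1]")


@dataclass
class CohortDesign:
    """Cohort composition and randomization design.

    ``q_by_trial`` is the design fraction assigned to active treatment in
    each randomized component; it is a known constant of the trial, supplied
    here and never estimated from the data downstream.
    """

    os_fraction: float = 0.25
    hysterectomy_prevalence: float = 0.35
    ht_participation: float = 0.40  # among CT members
    dm_participation: float = 0.70
    cad_participation: float = 0.55
    q_by_trial: dict = field(
        default_factory=lambda: {"E-alone": 0.5, "E+P": 0.5, "DM": 0.4, "CaD": 0.5}
    )
    subpopulation_probs: tuple = (0.8, 0.2)
    age_range: tuple = (50.0, 79.0)
    smoking_probs: tuple = (0.5, 0.4, 0.1)  # never / past / current
    diabetes_prev: float = 0.06
    hypertension_prev: float = 0.35
    aspirin_prev: float = 0.20
    statin_prev: float = 0.12
    prevalent_stroke_prev: float = 0.015

    def __post_init__(self) -> None:
        for name in (
            "os_fraction",
            "hysterectomy_prevalence",
            "ht_participation",
            "dm_participation",
            "cad_participation",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        for trial, q in self.q_by_trial.items():
            if not 0.0 < q < 1.0:
                raise ValueError(f"q for {trial} must be in (0, 1)")
        if abs(sum(self.subpopulation_probs) - 1.0) > 1e-9:
            raise ValueError("subpopulation_probs must sum to 1")


@dataclass
class EffectConfig:
    """Log-odds effects of the stroke-generating logistic model.

    ``covariate_logodds`` keys are subject columns; the ``age`` effect is per
    year centered at 65. ``interaction_logodds`` keys are ``(rsid, trial)``
    pairs; a nonzero entry is exactly the quantity the case-only test
    estimates (under a rare outcome).
    """

    baseline_logodds: float = float(logit(0.05))
    covariate_logodds: dict = field(default_factory=dict)
    snp_marginal_logodds: dict = field(default_factory=dict)
    trial_main_logodds: dict = field(default_factory=dict)
    interaction_logodds: dict = field(default_factory=dict)
    subtype_probs: tuple = (0.66, 0.17, 0.17)  # ischemic / hemorrhagic / other

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_probs) - 1.0) > 1e-9:
            raise ValueError("subtype_probs must sum to 1")
        for trial in list(self.trial_main_logodds) + [
            t for (_, t) in self.interaction_logodds
        ]:
            if trial not in TRIALS:
                raise ValueError(f"unknown trial {trial!r}")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele counts (0/1/2), NaN for missing."""

    values: np.ndarray
    snps: list
    subject_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ok = np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype values must be 0, 1, 2 or missing")

    @property
    def rsids(self) -> list:
        return [s.rsid for s in self.snps]

    def column(self, rsid: str) -> np.ndarray:
        return self.values[:, self.rsids.index(rsid)]

    def maf(self) -> np.ndarray:
        """Sample minor-allele frequency per SNP (over non-missing calls)."""
        return np.nanmean(self.values, axis=0) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.rsids)


@dataclass
class MatchedSet:
    """One-to-one matched case-control pairs within exact strata."""

    pairs: list  # (case_id, control_id)
    stratum_keys: list
    dropped_cases: list


def generate_genotypes(
    n_subjects: int,
    snps: list,
    subpopulation_labels,
    seed: int,
) -> GenotypeMatrix:
    """Draw genotypes under Balding-Nichols population structure.

    Per subpopulation ``k`` each SNP's allele frequency is drawn once from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with ``p = base_maf`` and ``F = fst``
    (``F = 0`` pins the frequency at ``base_maf``); genotypes are then
    binomial(2, freq) within subpopulation (Hardy-Weinberg). LD partners are
    built by copying the anchor's two haplotype alleles with retention
    probability ``sqrt(target_r2)`` and an independent redraw otherwise, so
    the allele-level correlation is ``sqrt(target_r2)`` and the genotype
    r^2 approaches ``target_r2``.
    """
    labels = np.asarray(subpopulation_labels)
    if labels.shape != (n_subjects,):
        raise ValueError("subpopulation_labels length must equal n_subjects")
    rsids = [s.rsid for s in snps]
    if len(set(rsids)) != len(rsids):
        raise ValueError("duplicate rsid in SNP list")
    by_id = {s.rsid: s for s in snps}
    for s in snps:
        if s.ld_partner is not None:
            partner = by_id.get(s.ld_partner)
            if partner is None or partner.ld_partner != s.rsid:
                raise ValueError(f"LD pairing for {s.rsid} is not reciprocal")
            if partner.target_r2 != s.target_r2:
                raise ValueError(f"LD pair {s.rsid}/{s.ld_partner}: target_r2 differs")

    rng = np.random.default_rng(seed)
    subpops = np.unique(labels)
    values = np.empty((n_subjects, len(snps)))
    done: dict[str, np.ndarray] = {}  # rsid -> haplotype alleles (n, 2)

    def subpop_freqs(spec: SnpSpec) -> dict:
        freqs = {}
        for k in subpops:
            if spec.fst > 0:
                a = spec.base_maf * (1 - spec.fst) / spec.fst
                b = (1 - spec.base_maf) * (1 - spec.fst) / spec.fst
                freqs[k] = float(np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6))
            else:
                freqs[k] = spec.base_maf
        return freqs

    for j, spec in enumerate(snps):
        if spec.rsid in done:
            hap = done[spec.rsid]
        else:
            freqs = subpop_freqs(spec)
            f = np.array([freqs[k] for k in labels])
            hap = (rng.random((n_subjects, 2)) < f[:, None]).astype(float)
            done[spec.rsid] = hap
            if spec.ld_partner is not None:
                # partner shares the anchor's subpopulation frequencies
                eps = 1.0 - np.sqrt(spec.target_r2)
                keep = rng.random((n_subjects, 2)) >= eps
                fresh = (rng.random((n_subjects, 2)) < f[:, None]).astype(float)
                done[spec.ld_partner] = np.where(keep, hap, fresh)
        g = hap.sum(axis=1)
        if spec.missing_rate > 0:
            g = g.copy()
            g[rng.random(n_subjects) < spec.missing_rate] = np.nan
        values[:, j] = g

    subject_ids = [f"S{i + 1:06d}" for i in range(n_subjects)]
    return GenotypeMatrix(values=values, snps=list(snps), subject_ids=subject_ids)


def assign_cohort_and_trials(
    n_subjects: int, design: CohortDesign, seed: int
) -> pd.DataFrame:
    """Build the subject table: cohort split, trial memberships, randomization
    indicators and baseline covariates.

    Hysterectomy routes HT-component members into the E-alone trial; women
    with a uterus go to E+P. CT members not drawn into HT or DM are placed in
    DM (every CT member joins at least one of the two). OS subjects carry no
    randomization indicators (NaN).
    """
    rng = np.random.default_rng(seed)
    n = n_subjects
    subject_id = [f"S{i + 1:06d}" for i in range(n)]
    subpopulation = rng.choice(
        len(design.subpopulation_probs), size=n, p=design.subpopulation_probs
    )
    # ethnicity tracks subpopulation so genotype PCs have a real confounder
    eth_minor = rng.choice(["black", "hispanic", "other"], size=n, p=[0.5, 0.3, 0.2])
    ethnicity = np.where(subpopulation == 0, "white", eth_minor)
    cohort = np.where(rng.random(n) < design.os_fraction, "OS", "CT")
    hysterectomy = rng.random(n) < design.hysterectomy_prevalence

    is_ct = cohort == "CT"
    in_ht = is_ct & (rng.random(n) < design.ht_participation)
    in_dm = is_ct & (rng.random(n) < design.dm_participation)
    in_dm |= is_ct & ~in_ht & ~in_dm  # CT members join HT or DM or both
    in_cad = is_ct & (rng.random(n) < design.cad_participation)

    ht_trial = np.full(n, "none", dtype=object)
    ht_trial[in_ht & hysterectomy] = "E-alone"
    ht_trial[in_ht & ~hysterectomy] = "E+P"

    z_ht = np.full(n, np.nan)
    for trial in ("E-alone", "E+P"):
        mask = ht_trial == trial
        z_ht[mask] = rng.random(mask.sum()) < design.q_by_trial[trial]
    z_dm = np.full(n, np.nan)
    z_dm[in_dm] = rng.random(in_dm.sum()) < design.q_by_trial["DM"]
    z_cad = np.full(n, np.nan)
    z_cad[in_cad] = rng.random(in_cad.sum()) < design.q_by_trial["CaD"]

    lo, hi = design.age_range
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "subpopulation": subpopulation,
            "cohort": cohort,
            "age": np.round(rng.uniform(lo, hi, n), 1),
            "ethnicity": ethnicity,
            "hysterectomy": hysterectomy,
            "prevalent_stroke": rng.random(n) < design.prevalent_stroke_prev,
            "smoking": rng.choice(3, size=n, p=design.smoking_probs),
            "diabetes": rng.random(n) < design.diabetes_prev,
            "hypertension": rng.random(n) < design.hypertension_prev,
            "aspirin": rng.random(n) < design.aspirin_prev,
            "statin": rng.random(n) < design.statin_prev,
            "physical_functioning": np.round(
                np.clip(rng.normal(85, 15, n), 0, 100), 1
            ),
            "in_ht": in_ht,
            "in_dm": in_dm,
            "in_cad": in_cad,
            "ht_trial": ht_trial,
            "z_ht": z_ht,
            "z_dm": z_dm,
            "z_cad": z_cad,
        }
    )


def _trial_z(subjects: pd.DataFrame, trial: str) -> np.ndarray:
    """Active-treatment indicator for one trial, 0 for non-members."""
    if trial in ("E-alone", "E+P"):
        z = np.where(subjects["ht_trial"].to_numpy() == trial, subjects["z_ht"], 0.0)
    elif trial == "DM":
        z = subjects["z_dm"].to_numpy()
    elif trial == "CaD":
        z = subjects["z_cad"].to_numpy()
    else:
        raise ValueError(f"unknown trial {trial!r}")
    return np.nan_to_num(np.asarray(z, dtype=float))


def simulate_outcomes(
    subjects: pd.DataFrame,
    genotypes: GenotypeMatrix,
    effects: EffectConfig,
    seed: int,
) -> pd.DataFrame:
    """Draw stroke outcomes from the generating logistic model.

    The linear predictor is baseline + covariate terms + SNP marginal terms +
    treatment main terms + SNP x treatment interactions; stroke is Bernoulli
    of its expit. Subtypes are multinomial among cases. ``followup_year`` is
    the matching reference time: the event year for cases and a random
    at-risk year over the same follow-up window for non-cases. Missing
    genotypes contribute their SNP's mean count to the risk score.
    """
    n = len(subjects)
    if genotypes.subject_ids != list(subjects["subject_id"]):
        raise ValueError("genotype rows are not aligned with the subject table")
    rng = np.random.default_rng(seed)
    lp = np.full(n, effects.baseline_logodds)
    for col, coef in effects.covariate_logodds.items():
        if col not in subjects.columns:
            raise ValueError(f"unknown covariate {col!r}")
        x = subjects[col].to_numpy(dtype=float)
        if col == "age":
            x = x - 65.0
        lp += coef * x
    rsids = genotypes.rsids
    for rsid, coef in effects.snp_marginal_logodds.items():
        if rsid not in rsids:
            raise ValueError(f"unknown rsid {rsid!r} in snp_marginal_logodds")
        g = genotypes.column(rsid)
        g = np.where(np.isnan(g), np.nanmean(g), g)
        lp += coef * g
    for trial, coef in effects.trial_main_logodds.items():
        lp += coef * _trial_z(subjects, trial)
    for (rsid, trial), coef in effects.interaction_logodds.items():
        if rsid not in rsids:
            raise ValueError(f"unknown rsid {rsid!r} in interaction_logodds")
        g = genotypes.column(rsid)
        g = np.where(np.isnan(g), np.nanmean(g), g)
        lp += coef * g * _trial_z(subjects, trial)

    stroke = rng.random(n) < expit(lp)
    subtype = np.full(n, "none", dtype=object)
    n_cases = int(stroke.sum())
    subtype[stroke] = rng.choice(SUBTYPES, size=n_cases, p=effects.subtype_probs)
    event_year = np.full(n, np.nan)
    event_year[stroke] = rng.uniform(0, FOLLOWUP_YEARS, n_cases)
    followup_year = rng.uniform(0, FOLLOWUP_YEARS, n)
    followup_year[stroke] = event_year[stroke]
    return pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "stroke": stroke,
            "subtype": subtype,
            "event_year": np.round(event_year, 3),
            "followup_year": np.round(followup_year, 3),
        }
    )


DEFAULT_MATCHING_FACTORS = [
    "ethnicity",
    "cohort",
    "in_ht",
    "in_dm",
    "in_cad",
    "hysterectomy",
    "prevalent_stroke",
    "followup_year",
]


def select_matched_controls(
    subjects: pd.DataFrame,
    outcomes: pd.DataFrame,
    matching_factors: list | None = None,
    age_caliper: float = 2.0,
    seed: int = 0,
    year_band: float = 1.0,
) -> MatchedSet:
    """Greedy one-to-one nearest-age matching within exact strata.

    Categorical factors must agree exactly; ``followup_year``, when listed,
    is matched on ``year_band``-wide bands; age must agree within
    ``age_caliper`` years. Cases are processed in a seed-randomized order and
    controls are drawn without replacement from the non-cases. A case with an
    empty risk set is dropped (reported, never a crash).
    """
    factors = list(
        DEFAULT_MATCHING_FACTORS if matching_factors is None else matching_factors
    )
    df = subjects.merge(outcomes, on="subject_id", validate="one_to_one")
    key_cols = []
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"matching factor {f!r} is not a subject field")
        if f == "followup_year":
            df["_year_band"] = np.floor(df["followup_year"] / year_band).astype(int)
            key_cols.append("_year_band")
        else:
            key_cols.append(f)
    keys = list(zip(*(df[c] for c in key_cols))) if key_cols else [()] * len(df)
    df = df.assign(_key=pd.Series(keys, index=df.index).astype(str))

    rng = np.random.default_rng(seed)
    cases = df[df["stroke"]]
    pool = df[~df["stroke"]]
    pool_by_key: dict[str, list] = {}
    for key, grp in pool.groupby("_key"):
        pool_by_key[key] = list(zip(grp["age"], grp["subject_id"]))

    pairs, stratum_keys, dropped = [], [], []
    for idx in rng.permutation(len(cases)):
        row = cases.iloc[idx]
        avail = pool_by_key.get(row["_key"], [])
        best, best_gap = None, None
        for i, (age, _cid) in enumerate(avail):
            gap = abs(age - row["age"])
            if gap <= age_caliper and (best_gap is None or gap < best_gap):
                best, best_gap = i, gap
        if best is None:
            dropped.append(row["subject_id"])
        else:
            _, control_id = avail.pop(best)
            pairs.append((row["subject_id"], control_id))
            stratum_keys.append(row["_key"])
    return MatchedSet(pairs=pairs, stratum_keys=stratum_keys, dropped_cases=dropped)


# ---------------------------------------------------------------------------
# fast single-trial replicate generators (property tests, calibration studies)
# ---------------------------------------------------------------------------

def simulate_trial_members(
    n_members: int,
    maf: float,
    q: float,
    baseline_logodds: float,
    snp_logodds: float = 0.0,
    trial_logodds: float = 0.0,
    interaction_logodds: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Genotype, assignment and case status for members of a single trial.

    A stripped-down draw from the same generating model as
    :func:`simulate_outcomes` (one SNP, one trial, no covariates), returning
    ``(G, Z, case)`` arrays. Used for calibration and power studies where the
    full cohort machinery would only add noise-free bookkeeping.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    g = rng.binomial(2, maf, n_members).astype(float)
    z = (rng.random(n_members) < q).astype(float)
    lp = baseline_logodds + snp_logodds * g + trial_logodds * z
    lp = lp + interaction_logodds * g * z
    case = rng.random(n_members) < expit(lp)
    return g, z, case


def simulate_trial_cases(
    n_cases: int,
    maf: float,
    q: float,
    baseline_logodds: float,
    snp_logodds: float = 0.0,
    trial_logodds: float = 0.0,
    interaction_logodds: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Exactly ``n_cases`` cases from a single trial: ``(G, Z)`` among cases."""
    if rng is None:
        rng = np.random.default_rng(seed)
    gs, zs = [], []
    have = 0
    p_case = float(expit(baseline_logodds)) or 1e-4
    while have < n_cases:
        batch = max(int(1.5 * (n_cases - have) / p_case), 200)
        g, z, case = simulate_trial_members(
            batch, maf, q, baseline_logodds, snp_logodds, trial_logodds,
            interaction_logodds, rng=rng,
        )
        gs.append(g[case])
        zs.append(z[case])
        have += int(case.sum())
    g = np.concatenate(gs)[:n_cases]
    z = np.concatenate(zs)[:n_cases]
    return g, z


# ---------------------------------------------------------------------------
# named presets and on-disk fixtures
# ---------------------------------------------------------------------------

def _grid_snps(n: int, maf: float = 0.25, fst: float = 0.02) -> list:
    return [
        SnpSpec(
            rsid=f"rs{9000 + i}",
            chromosome=str(1 + i % 22),
            position=1_000_000 + 50_000 * i,
            ref_allele="A",
            alt_allele="G",
            base_maf=maf,
            fst=fst,
        )
        for i in range(n)
    ]


def _preset_tiny() -> dict:
    snps = _grid_snps(8, maf=0.3, fst=0.0) + [
        SnpSpec("rs_pair_a", "6", 6_231_297, "G", "A", 0.2,
                ld_partner="rs_pair_b", target_r2=0.99),
        SnpSpec("rs_pair_b", "6", 6_233_241, "G", "A", 0.2,
                ld_partner="rs_pair_a", target_r2=0.99),
    ]
    effects = EffectConfig(
        baseline_logodds=float(logit(0.15)),
        trial_main_logodds={"E-alone": np.log(1.4), "E+P": np.log(1.4)},
    )
    return {"n_subjects": 200, "snps": snps, "design": CohortDesign(),
            "effects": effects,
            # a 200-subject smoke fixture cannot fill fine-grained strata
            "matching_factors": ["ethnicity", "cohort", "prevalent_stroke"],
            "age_caliper": 5.0}


def _preset_null() -> dict:
    """Treatment and SNP main effects present, all interactions zero."""
    snps = _grid_snps(12)
    effects = EffectConfig(
        baseline_logodds=float(logit(0.05)),
        covariate_logodds={"diabetes": 0.5, "hypertension": 0.4,
                           "prevalent_stroke": 1.0, "age": 0.03},
        snp_marginal_logodds={"rs9000": float(np.log(1.2))},
        trial_main_logodds={"E-alone": float(np.log(1.4)),
                            "E+P": float(np.log(1.4))},
    )
    return {"n_subjects": 6000, "snps": snps, "design": CohortDesign(),
            "effects": effects}


def _preset_f13a1_like() -> dict:
    """A planted low-MAF LD pair whose minor allele attenuates the E+P
    treatment effect (and, less strongly, E-alone).

    Effect sizes are scaled up relative to a full-size cohort because the
    preset runs at a few hundred matched pairs.
    """
    snps = _grid_snps(48) + [
        SnpSpec("rs_f13_a", "6", 6_231_297, "G", "A", 0.09,
                ld_partner="rs_f13_b", target_r2=0.985),
        SnpSpec("rs_f13_b", "6", 6_233_241, "G", "A", 0.09,
                ld_partner="rs_f13_a", target_r2=0.985),
    ]
    effects = EffectConfig(
        baseline_logodds=float(logit(0.055)),
        covariate_logodds={"diabetes": 0.5, "hypertension": 0.4,
                           "prevalent_stroke": 1.0, "age": 0.03},
        snp_marginal_logodds={"rs_f13_a": float(np.log(1.6))},
        trial_main_logodds={"E-alone": float(np.log(1.5)),
                            "E+P": float(np.log(1.5))},
        interaction_logodds={("rs_f13_a", "E+P"): -0.9,
                             ("rs_f13_a", "E-alone"): -0.4},
    )
    return {"n_subjects": 9000, "snps": snps, "design": CohortDesign(),
            "effects": effects}


def _preset_pcsk9_like() -> dict:
    """A planted common LD pair with opposite-sign interactions across the
    two hormone trials (positive for E+P, negative for E-alone)."""
    snps = _grid_snps(48) + [
        SnpSpec("rs_pcsk9_a", "1", 55_299_911, "A", "G", 0.34,
                ld_partner="rs_pcsk9_b", target_r2=0.985),
        SnpSpec("rs_pcsk9_b", "1", 55_297_430, "A", "G", 0.34,
                ld_partner="rs_pcsk9_a", target_r2=0.985),
    ]
    effects = EffectConfig(
        baseline_logodds=float(logit(0.055)),
        covariate_logodds={"diabetes": 0.5, "hypertension": 0.4,
                           "prevalent_stroke": 1.0, "age": 0.03},
        snp_marginal_logodds={"rs_pcsk9_a": float(np.log(0.7))},
        trial_main_logodds={"E-alone": float(np.log(1.5)),
                            "E+P": float(np.log(1.5))},
        interaction_logodds={("rs_pcsk9_a", "E+P"): 0.5,
                             ("rs_pcsk9_a", "E-alone"): -0.45},
    )
    return {"n_subjects": 9000, "snps": snps, "design": CohortDesign(),
            "effects": effects}


PRESETS = {
    "tiny": _preset_tiny,
    "null": _preset_null,
    "f13a1_like": _preset_f13a1_like,
    "pcsk9_like": _preset_pcsk9_like,
}


def generate_dataset(profile: str, seed: int) -> dict:
    """Run a named preset end to end in memory.

    Returns a dict with ``subjects``, ``genotypes``, ``outcomes``,
    ``matched``, ``design``, ``effects`` and ``snps``.
    """
    if profile not in PRESETS:
        raise ValueError(f"unknown preset {profile!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[profile]()
    ss = np.random.SeedSequence(seed)
    s_cohort, s_geno, s_outcome, s_match = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)
    )
    subjects = assign_cohort_and_trials(cfg["n_subjects"], cfg["design"], s_cohort)
    genotypes = generate_genotypes(
        cfg["n_subjects"], cfg["snps"], subjects["subpopulation"].to_numpy(), s_geno
    )
    outcomes = simulate_outcomes(subjects, genotypes, cfg["effects"], s_outcome)
    matched = select_matched_controls(
        subjects,
        outcomes,
        matching_factors=cfg.get("matching_factors"),
        age_caliper=cfg.get("age_caliper", 2.0),
        seed=s_match,
    )
    return {
        "subjects": subjects,
        "genotypes": genotypes,
        "outcomes": outcomes,
        "matched": matched,
        "design": cfg["design"],
        "effects": cfg["effects"],
        "snps": cfg["snps"],
    }


def make_fixture(
    profile: str, seed: int, outdir, write_vcf: bool = False
) -> dict:
    """Write a preset dataset to disk: phenotype TSV, genotype TSV, matched
    pairs TSV, a JSON manifest recording every parameter and seed, and
    optionally a VCF 4.2 genotype file. Byte-identical for identical
    preset + seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(profile, seed)
    pheno = data["subjects"].merge(data["outcomes"], on="subject_id")
    paths = {
        "phenotypes": outdir / "phenotypes.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "snps": outdir / "snps.tsv",
        "pairs": outdir / "matched_pairs.tsv",
        "manifest": outdir / "manifest.json",
    }
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.6g")
    gdf = data["genotypes"].to_dataframe()
    gdf.index.name = "subject_id"
    gdf.to_csv(paths["genotypes"], sep="\t", na_rep="NA", float_format="%.0f")
    pd.DataFrame(
        data["matched"].pairs, columns=["case_id", "control_id"]
    ).to_csv(paths["pairs"], sep="\t", index=False)
    pd.DataFrame([asdict(s) for s in data["snps"]]).to_csv(
        paths["snps"], sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )
    effects = data["effects"]
    manifest = {
        "profile": profile,
        "seed": seed,
        "n_subjects": len(data["subjects"]),
        "n_cases": int(data["outcomes"]["stroke"].sum()),
        "n_pairs": len(data["matched"].pairs),
        "n_dropped_cases": len(data["matched"].dropped_cases),
        "design": asdict(data["design"]),
        "effects": {
            "baseline_logodds": effects.baseline_logodds,
            "covariate_logodds": effects.covariate_logodds,
            "snp_marginal_logodds": effects.snp_marginal_logodds,
            "trial_main_logodds": effects.trial_main_logodds,
            "interaction_logodds": {
                f"{rsid}|{trial}": v
                for (rsid, trial), v in effects.interaction_logodds.items()
            },
            "subtype_probs": list(effects.subtype_probs),
        },
        "snps": [asdict(s) for s in data["snps"]],
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if write_vcf:
        paths["vcf"] = outdir / "genotypes.vcf"
        _write_vcf(paths["vcf"], data["genotypes"])
    return paths


def _write_vcf(path, genotypes: GenotypeMatrix) -> None:
    """Minimal VCF 4.2 with GT fields; ALT is the minor allele by spec."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.subject_ids),
    ]
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, s in enumerate(genotypes.snps):
        col = genotypes.values[:, j]
        gts = ["./." if np.isnan(v) else gt_code[v] for v in col]
        lines.append(
            f"{s.chromosome}\t{s.position}\t{s.rsid}\t{s.ref_allele}\t"
            f"{s.alt_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")
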