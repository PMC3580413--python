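"""Readers for phenotype tables and genotype matrices (TSV, optional VCF)."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix, SnpSpec

__all__ = ["read_phenotypes", "read_genotypes", "MANDATORY_PHENOTYPE_COLUMNS"]

logger = logging.getLogger(__name__)

MANDATORY_PHENOTYPE_COLUMNS = [
    "subject_id",
    "cohort",
    "age",
    "ethnicity",
    "hysterectomy",
    "prevalent_stroke",
    "in_ht",
    "in_dm",
    "in_cad",
    "ht_trial",
    "z_ht",
    "stroke",
    "subtype",
    "followup_year",
]


def read_phenotypes(path) -> pd.DataFrame:
    """Load the per-subject phenotype/outcome table (one row per subject)."""
    df = pd.read_csv(path, sep="\t")
    for col in MANDATORY_PHENOTYPE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"phenotype file is missing mandatory column {col!r}")
    return df


def _spec_from_observed(rsid: str, j: int, counts: np.ndarray) -> SnpSpec:
    freq = float(np.nanmean(counts) / 2.0) if np.isfinite(counts).any() else 0.0
    maf = min(freq, 1.0 - freq)
    return SnpSpec(
        rsid=rsid,
        chromosome="NA",
        position=j + 1,
        ref_allele="N",
        alt_allele="N",
        base_maf=float(np.clip(maf, 1e-6, 0.5)),
    )


def read_snp_metadata(path) -> list:
    """Load a SNP metadata sidecar (one row per SNP, SnpSpec columns)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    specs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for opt in ("ld_partner", "target_r2"):
            if pd.isna(d.get(opt)):
                d[opt] = None
        d.setdefault("fst", 0.0)
        if pd.isna(d.get("fst")):
            d["fst"] = 0.0
        if pd.isna(d.get("missing_rate", 0.0)):
            d["missing_rate"] = 0.0
        specs.append(SnpSpec(**{k: v for k, v in d.items()
                                if k in SnpSpec.__dataclass_fields__}))
    return specs


def read_genotypes(path, fmt: str = "tsv", metadata=None) -> GenotypeMatrix:
    """Load a genotype matrix of minor-allele counts.

    TSV: subjects as rows (first column subject_id), rsids as columns,
    values 0/1/2/NA; ``metadata`` optionally points at a SNP sidecar table
    restoring chromosome/position/allele information. VCF: GT fields are
    converted to ALT-allele counts and re-oriented to count the minor allele
    when ALT is the major allele in the sample (logged); half-calls and
    ``./.`` become missing.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        values = df.to_numpy(dtype=float)
        if metadata is not None:
            by_id = {s.rsid: s for s in read_snp_metadata(metadata)}
            missing = [r for r in df.columns if r not in by_id]
            if missing:
                raise ValueError(
                    f"SNP metadata lacks entries for: {', '.join(missing[:5])}"
                )
            snps = [by_id[rsid] for rsid in df.columns]
        else:
            snps = [
                _spec_from_observed(rsid, j, values[:, j])
                for j, rsid in enumerate(df.columns)
            ]
        return GenotypeMatrix(
            values=values, snps=snps, subject_ids=[str(s) for s in df.index]
        )
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    snps, cols = [], []
    for i, variant in enumerate(vcf, start=1):
        try:
            alt = variant.ALT[0] if variant.ALT else "N"
            # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown/missing
            gt = np.asarray(variant.gt_types, dtype=float)
            counts = np.select(
                [gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan
            )
            ref, alt_allele = variant.REF, alt
            alt_freq = np.nanmean(counts) / 2.0 if np.isfinite(counts).any() else 0.0
            if alt_freq > 0.5:
                counts = 2.0 - counts
                ref, alt_allele = alt, variant.REF
                logger.info(
                    "%s: ALT is the major allele (freq %.3f); counts re-oriented "
                    "to the minor allele", variant.ID, alt_freq,
                )
            snps.append(
                SnpSpec(
                    rsid=variant.ID or f"var{i}",
                    chromosome=str(variant.CHROM),
                    position=int(variant.POS),
                    ref_allele=str(ref),
                    alt_allele=str(alt_allele),
                    base_maf=float(np.clip(min(alt_freq, 1 - alt_freq), 1e-6, 0.5)),
                )
            )
            cols.append(counts)
        except Exception as exc:
            raise ValueError(f"malformed VCF record at data line {i}: {exc}") from exc
    if not cols:
        raise ValueError("VCF contains no variant records")
    return GenotypeMatrix(
        values=np.column_stack(cols), snps=snps, subject_ids=subject_ids
    )
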