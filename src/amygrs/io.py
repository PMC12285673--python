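"""Reading and writing cohort genotype/phenotype files.

Supported genotype formats are VCF v4.2 (GT hard calls with an optional DS
fractional-dosage FORMAT field, parsed with cyvcf2) and the PLINK ``.traw``
transposed text dialect (one row per variant, one column per sample,
``NA`` = missing).  Dosages count the effect allele, which is the VCF ALT
allele / the traw COUNTED allele.  Phenotypes and covariates travel in a
tab-delimited table keyed by ``sample_id``; samples are intersected between
the two files with the order taken from the phenotype table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import CohortDataset, DataError, VARIANT_META_COLUMNS

logger = logging.getLogger(__name__)

TRAW_FIXED_COLUMNS = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]


class FormatError(DataError):
    """Malformed genotype or phenotype file."""


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "phenotype", "age", "sex"):
        if col not in df.columns:
            raise FormatError(f"phenotype table {path} lacks column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"phenotype table {path} has duplicate sample ids")
    return df


def write_phenotypes(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# traw
# ---------------------------------------------------------------------------

def write_traw(data: CohortDataset, path: str | Path) -> None:
    """Write dosages as PLINK-style transposed text (variant-major)."""
    v = data.variants
    out = pd.DataFrame({
        "CHR": v["chrom"], "SNP": v["variant_id"], "(C)M": 0,
        "POS": v["pos"], "COUNTED": v["effect_allele"], "ALT": v["other_allele"],
    })
    dos = pd.DataFrame(data.dosages.T, columns=list(data.sample_ids))
    pd.concat([out, dos], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_traw(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Parse a .traw file into (dosages, variant table, sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    except Exception as exc:  # noqa: BLE001 - report file context
        raise FormatError(f"cannot parse traw file {path}: {exc}") from None
    missing = [c for c in TRAW_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"traw file {path} lacks columns {missing}")
    sample_cols = [c for c in df.columns if c not in TRAW_FIXED_COLUMNS]
    if not sample_cols:
        raise FormatError(f"traw file {path} has no sample columns")
    variants = pd.DataFrame({
        "variant_id": df["SNP"].astype(str),
        "chrom": df["CHR"],
        "pos": df["POS"].astype(int),
        "effect_allele": df["COUNTED"].astype(str),
        "other_allele": df["ALT"].astype(str),
    })
    dosages = df[sample_cols].to_numpy(dtype=float).T
    return dosages, variants, [str(c) for c in sample_cols]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(data: CohortDataset, path: str | Path, dosage_field: bool = True) -> None:
    """Write v4.2 VCF: GT from rounded dosage, DS with the fractional value.

    The ALT allele is the effect allele, so a DS/GT dosage is directly the
    effect-allele count.
    """
    path = Path(path)
    sample_ids = list(data.sample_ids)
    hard = data.hard_calls()
    order = range(data.n_variants)  # dataset order, so round-trips preserve it
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosage_field:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Effect allele dosage">\n')
        for chrom in sorted(set(data.variants["chrom"])):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        fmt = "GT:DS" if dosage_field else "GT"
        for j in order:
            v = data.variants.iloc[j]
            fields = [str(v["chrom"]), str(v["pos"]), str(v["variant_id"]),
                      str(v["other_allele"]), str(v["effect_allele"]),
                      ".", "PASS", ".", fmt]
            for i in range(data.n_samples):
                d = data.dosages[i, j]
                if np.isnan(d):
                    fields.append("./.:." if dosage_field else "./.")
                    continue
                gt = gt_map[int(hard[i, j])]
                fields.append(f"{gt}:{d:.4g}" if dosage_field else gt)
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Parse a VCF into (dosages, variant table, sample ids).

    If a DS FORMAT field is present its value is used as the dosage;
    otherwise the dosage is the ALT-allele count of the GT call.  Only
    biallelic records are accepted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, metas = [], []
    for rec_no, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise FormatError(
                f"{path}: record {rec_no} ({rec.ID}) is not biallelic")
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            vals = ds.astype(float).reshape(-1)
            vals = np.where((vals < -0.5) | (vals > 2.5), np.nan, vals)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = rec.gt_types.astype(float)
            vals = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        rows.append(vals)
        metas.append((rec.ID, rec.CHROM, rec.POS, rec.ALT[0], rec.REF))
    if not rows:
        raise FormatError(f"{path}: no variant records")
    variants = pd.DataFrame(metas, columns=VARIANT_META_COLUMNS)
    variants["variant_id"] = variants["variant_id"].astype(str)
    return np.asarray(rows, dtype=float).T, variants, sample_ids


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def read_cohort(genotype_path: str | Path, phenotype_path: str | Path,
                fmt: str = "traw", cohort_name: str | None = None,
                phenotype_type: str = "quantitative") -> CohortDataset:
    """Read genotypes + phenotypes into a :class:`CohortDataset`.

    Samples are the intersection of the two files, in phenotype-table order;
    samples present in only one file are dropped with a logged warning.
    """
    if fmt == "traw":
        dosages, variants, geno_samples = read_traw(genotype_path)
    elif fmt == "vcf":
        dosages, variants, geno_samples = read_vcf(genotype_path)
    else:
        raise FormatError(f"unknown genotype format {fmt!r} (use 'vcf' or 'traw')")
    if variants["variant_id"].duplicated().any():
        raise FormatError(f"{genotype_path}: duplicate variant ids")

    pheno = read_phenotypes(phenotype_path)
    geno_index = {s: i for i, s in enumerate(geno_samples)}
    in_both = pheno["sample_id"].isin(geno_index)
    if not in_both.any():
        raise FormatError(
            f"no overlapping samples between {genotype_path} and {phenotype_path}")
    n_pheno_only = int((~in_both).sum())
    n_geno_only = len(geno_samples) - int(in_both.sum())
    if n_pheno_only or n_geno_only:
        logger.warning(
            "sample intersection: dropped %d phenotype-only and %d genotype-only samples",
            n_pheno_only, n_geno_only)
    pheno = pheno.loc[in_both].reset_index(drop=True)
    rows = [geno_index[s] for s in pheno["sample_id"]]
    return CohortDataset(
        cohort_name=cohort_name or Path(str(genotype_path)).stem,
        dosages=dosages[rows],
        variants=variants,
        samples=pheno,
        phenotype_type=phenotype_type,
    )


def write_cohort(data: CohortDataset, genotype_path: str | Path,
                 phenotype_path: str | Path, fmt: str = "traw") -> None:
    """Write a cohort's genotype and phenotype files."""
    if fmt == "traw":
        write_traw(data, genotype_path)
    elif fmt == "vcf":
        write_vcf(data, genotype_path)
    else:
        raise FormatError(f"unknown genotype format {fmt!r} (use 'vcf' or 'traw')")
    write_phenotypes(data.samples, phenotype_path)
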