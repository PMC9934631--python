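"""Readers/writers for the external formats and dataset-level validation.

VCF is read through cyvcf2 (VCFv4.2 subset, GT and/or DS FORMAT fields);
all tabular formats go through pandas.  Coordinate conventions are owned by
:mod:`stimqtl.types`: BED intervals 0-based half-open, variants 1-based.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    CountMatrix,
    GenomicInterval,
    GenotypeMatrix,
    GwasSumstats,
    SampleSheet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_sumstats",
    "write_sumstats",
    "normalize_contig",
    "validate_dataset",
    "ValidationReport",
]


# ---------------------------------------------------------------------------
# contig naming

def normalize_contig(name: str, style: str = "chr") -> str:
    """Map between ``chrN`` and ``N`` contig naming.

    ``style='chr'`` adds the prefix, ``style='plain'`` strips it.
    """
    if style == "chr":
        return name if name.startswith("chr") else f"chr{name}"
    if style == "plain":
        return name[3:] if name.startswith("chr") else name
    raise ValueError(f"unknown contig style {style!r}")


def _check_not_mixed(contigs: "pd.Series | list[str]", what: str) -> None:
    names = pd.Series(list(contigs)).astype(str)
    has_chr = names.str.startswith("chr")
    if has_chr.any() and (~has_chr).any():
        raise ValueError(f"mixed contig naming within {what} (chrN and N)")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str, contig_style: str | None = None,
             min_impute_r2: float | None = None,
             r2_info_key: str = "R2") -> GenotypeMatrix:
    """Read a biallelic VCF into a :class:`GenotypeMatrix`.

    Dosage comes from the DS FORMAT field when present, otherwise from the
    GT allele count; missing genotypes become NaN.  Multiallelic records are
    skipped with a logged count.  When ``min_impute_r2`` is given, variants
    whose INFO ``r2_info_key`` falls below it are dropped; variants lacking
    the key are kept (a log line notes how many lacked it).
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, dosages = [], []
    n_multi = n_no_r2 = n_low_r2 = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        r2 = v.INFO.get(r2_info_key)
        if min_impute_r2 is not None:
            if r2 is None:
                n_no_r2 += 1
            elif float(r2) < min_impute_r2:
                n_low_r2 += 1
                continue
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d = np.where((d < 0) | (d > 2), np.nan, d)
        else:
            gt = np.asarray(v.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            d = gt.sum(axis=1)
        info = {} if r2 is None else {r2_info_key: float(r2)}
        rows.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF,
                     v.ALT[0], info))
        dosages.append(d)
    if n_multi:
        logger.warning("skipped %d multiallelic records in %s", n_multi, path)
    if min_impute_r2 is not None and n_no_r2:
        logger.info("%d variants lack INFO/%s; imputation filter skipped for them",
                    n_no_r2, r2_info_key)
    if n_low_r2:
        logger.info("dropped %d variants with %s < %s", n_low_r2, r2_info_key,
                    min_impute_r2)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt",
                                           "info"])
    _check_not_mixed(variants["chrom"], os.path.basename(path))
    if contig_style is not None:
        variants["chrom"] = [normalize_contig(c, contig_style)
                             for c in variants["chrom"]]
    dosage = (np.vstack(dosages) if dosages
              else np.empty((0, len(samples))))
    return GenotypeMatrix(variants, samples, dosage)


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write the canonical dialect: VCFv4.2, GT:DS, hard GT from rounded DS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i, row in gm.variants.iterrows():
            cells = []
            for d in gm.dosage[i]:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    g = int(round(d))
                    gt = ["0/0", "0/1", "1/1"][min(g, 2)]
                    cells.append(f"{gt}:{d:.17g}")
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT:DS\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str, contig_style: str | None = None) -> list[GenomicInterval]:
    """Read BED3-BED6; output sorted by (chrom, start)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}")
            if contig_style is not None:
                chrom = normalize_contig(chrom, contig_style)
            name = parts[3] if len(parts) > 3 else "."
            score = (float(parts[4]) if len(parts) > 4 and parts[4] != "."
                     else None)
            strand = parts[5] if len(parts) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, name, score,
                                             strand))
    _check_not_mixed([iv.chrom for iv in intervals], os.path.basename(path))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:.17g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}"
                     f"\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# tabular formats

def read_counts(path: str) -> CountMatrix:
    """TSV, first column = feature id, remaining header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric count values")
    if np.any(arr != np.floor(arr)):
        raise ValueError(f"{path}: non-integer count values")
    if arr.min(initial=0) < 0:
        raise ValueError(f"{path}: negative count values")
    return CountMatrix(df.index.astype(str).tolist(),
                       df.columns.astype(str).tolist(),
                       arr.astype(np.int64))


def write_counts(cm: CountMatrix, path: str) -> None:
    cm.to_frame().rename_axis("feature_id").to_csv(path, sep="\t")


def read_sample_sheet(path: str,
                      conditions: list[str] | None = None) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    return SampleSheet(df, conditions=conditions)


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


_MA_ALIASES = {"SNP": "id", "A1": "effect_allele", "A2": "other_allele",
               "b": "beta", "N": "n", "Chr": "chrom", "BP": "pos",
               "chr": "chrom", "bp": "pos", "P": "p"}


def read_sumstats(path: str,
                  variants: pd.DataFrame | None = None) -> GwasSumstats:
    """Read GWAS summary statistics.

    Accepts the canonical column set or the COJO ``.ma`` dialect
    (``SNP A1 A2 freq b se p N``); when the file lacks coordinates they are
    filled by joining ``variants`` (a frame with id/chrom/pos) on id.
    """
    df = pd.read_csv(path, sep=r"\s+")
    df = df.rename(columns=_MA_ALIASES)
    if "chrom" not in df.columns or "pos" not in df.columns:
        if variants is None:
            raise ValueError(
                f"{path}: no coordinates and no variant table to join")
        coords = variants[["id", "chrom", "pos"]]
        df = df.merge(coords, on="id", how="left")
        if df["pos"].isna().any():
            missing = df.loc[df["pos"].isna(), "id"].head().tolist()
            raise ValueError(f"{path}: ids not found in variant table: {missing}")
        df["pos"] = df["pos"].astype(int)
    return GwasSumstats(df)


def write_sumstats(ss: GwasSumstats, path: str) -> None:
    cols = GwasSumstats.COLUMNS
    ss.table[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dataset-level validation

@dataclass
class ValidationReport:
    """Cross-file consistency summary; analysis proceeds on intersections."""

    atac_samples: list[str] = field(default_factory=list)
    rna_samples: list[str] = field(default_factory=list)
    atac_missing: list[str] = field(default_factory=list)
    rna_missing: list[str] = field(default_factory=list)
    genotype_missing: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.warnings


def validate_dataset(genotypes: GenotypeMatrix,
                     sheet: SampleSheet,
                     atac: CountMatrix | None = None,
                     rna: CountMatrix | None = None) -> ValidationReport:
    """Reconcile sample sets across assays; hard error on empty intersection.

    ATAC/RNA sample sets may differ per donor and condition (missingness is
    expected); a sample present in only one assay is retained for that
    assay's analyses and reported for the other.
    """
    rep = ValidationReport()
    donors = set(sheet.table["donor_id"])
    geno_donors = set(genotypes.samples)
    rep.genotype_missing = sorted(donors - geno_donors)
    if rep.genotype_missing:
        rep.warnings.append(
            f"{len(rep.genotype_missing)} donors lack genotypes")
    sheet_samples = set(sheet.samples)

    styles = set()
    for contigs in (genotypes.variants["chrom"],):
        styles |= {c.startswith("chr") for c in pd.unique(contigs)}
    if len(styles) > 1:
        raise ValueError("mixed contig naming across dataset")

    for name, cm in (("atac", atac), ("rna", rna)):
        if cm is None:
            continue
        present = [s for s in cm.samples if s in sheet_samples]
        orphan = [s for s in cm.samples if s not in sheet_samples]
        if orphan:
            rep.warnings.append(
                f"{len(orphan)} {name} samples absent from sample sheet")
        setattr(rep, f"{name}_samples", present)
        if not present:
            raise ValueError(f"empty sample intersection for {name}")
    if atac is not None and rna is not None:
        atac_set, rna_set = set(rep.atac_samples), set(rep.rna_samples)
        rep.atac_missing = sorted(rna_set - atac_set)
        rep.rna_missing = sorted(atac_set - rna_set)
        if rep.atac_missing:
            rep.warnings.append(
                f"{len(rep.atac_missing)} samples are RNA-only "
                "(retained for eQTL analyses)")
        if rep.rna_missing:
            rep.warnings.append(
                f"{len(rep.rna_missing)} samples are ATAC-only "
                "(retained for caQTL analyses)")
    return rep
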