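"""Core domain containers shared across the pipeline.

Coordinate conventions: genomic intervals (peaks, genes, annotation tracks)
are 0-based half-open as in BED; variant positions are 1-based as in VCF.
A variant at 1-based position ``p`` falls inside interval ``[s, e)`` iff
``s < p <= e``.  The TSS of a gene is a single base: the interval start for
``+`` strand genes and the interval end for ``-`` strand genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "VariantRecord",
    "GenotypeMatrix",
    "CountMatrix",
    "SampleSheet",
    "GwasSumstats",
    "variant_in_interval",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need end > start >= 0)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Strand-aware single-base anchor (1-based position).

        For ``+``/unstranded features this is ``start + 1``; for ``-`` it is
        ``end`` (the last covered base, 1-based).
        """
        return self.end if self.strand == "-" else self.start + 1

    def contains_variant(self, pos: int) -> bool:
        """Whether a 1-based variant position lies inside the interval."""
        return self.start < pos <= self.end


def variant_in_interval(start: int, end: int, pos: int) -> bool:
    """1-based ``pos`` inside 0-based half-open ``[start, end)``."""
    return start < pos <= end


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant, 1-based position."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if "," in self.alt:
            raise ValueError(f"multiallelic variant {self.id} not allowed")


class GenotypeMatrix:
    """Variants x samples dosage matrix with variant metadata.

    Dosages are reals in [0, 2] (expected alternate-allele count); missing
    genotypes are NaN.  ``variants`` is a DataFrame with columns
    ``chrom, pos, id, ref, alt`` in matrix row order.
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        samples: Sequence[str],
        dosage: np.ndarray,
    ) -> None:
        variants = variants.reset_index(drop=True)
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(variants), len(samples)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        if variants["id"].duplicated().any():
            dup = variants.loc[variants["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids in genotype matrix")
        with np.errstate(invalid="ignore"):
            if np.nanmin(dosage, initial=0.0) < 0 or np.nanmax(dosage, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        self.variants = variants
        self.samples = list(samples)
        self.dosage = dosage

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing samples."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def subset_samples(self, samples: Iterable[str]) -> "GenotypeMatrix":
        samples = list(samples)
        idx = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return GenotypeMatrix(self.variants.copy(), samples, self.dosage[:, cols])

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            rows = np.flatnonzero(mask)
        else:
            rows = mask
        return GenotypeMatrix(
            self.variants.iloc[rows].reset_index(drop=True),
            list(self.samples),
            self.dosage[rows],
        )

    def row_of(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if len(hits) == 0:
            raise KeyError(f"variant {variant_id!r} not found")
        return int(hits[0])


class CountMatrix:
    """Features x samples non-negative integer counts."""

    def __init__(
        self,
        features: Sequence[str],
        samples: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(features), len(samples)):
            raise ValueError(
                f"count shape {counts.shape} does not match "
                f"{len(features)} features x {len(samples)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")
        if len(set(features)) != len(features):
            raise ValueError("duplicate feature ids")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        self.features = list(features)
        self.samples = list(samples)
        self.counts = counts.astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.features, columns=self.samples)

    def subset_samples(self, samples: Iterable[str]) -> "CountMatrix":
        samples = list(samples)
        idx = {s: i for i, s in enumerate(self.samples)}
        cols = [idx[s] for s in samples]
        return CountMatrix(list(self.features), samples, self.counts[:, cols])


class SampleSheet:
    """Sample -> donor / condition / numeric covariates mapping.

    Encodes the paired design: one sample per (donor, condition).
    """

    REQUIRED = ("sample_id", "donor_id", "condition")

    def __init__(self, table: pd.DataFrame, conditions: Sequence[str] | None = None):
        for col in self.REQUIRED:
            if col not in table.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        table = table.reset_index(drop=True)
        if table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        dup = table.duplicated(subset=["donor_id", "condition"])
        if dup.any():
            pair = table.loc[dup, ["donor_id", "condition"]].iloc[0].tolist()
            raise ValueError(f"duplicate (donor, condition) pair {pair}")
        declared = list(conditions) if conditions is not None else sorted(
            table["condition"].unique()
        )
        unknown = set(table["condition"]) - set(declared)
        if unknown:
            raise ValueError(f"undeclared condition labels {sorted(unknown)}")
        self.table = table
        self.conditions = declared

    @property
    def samples(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.REQUIRED]

    def subset(self, samples: Iterable[str]) -> "SampleSheet":
        keep = self.table[self.table["sample_id"].isin(set(samples))]
        return SampleSheet(keep.copy(), conditions=self.conditions)

    def condition_samples(self, condition: str) -> list[str]:
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        t = self.table
        return t.loc[t["condition"] == condition, "sample_id"].tolist()

    def donor_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["donor_id"]))


class GwasSumstats:
    """GWAS summary statistics (COJO ``.ma``-style)."""

    COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele",
               "freq", "beta", "se", "p", "n"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"sumstats missing columns {missing}")
        table = table.reset_index(drop=True).copy()
        if ((table["p"] <= 0) | (table["p"] > 1)).any():
            raise ValueError("p must lie in (0, 1]")
        if (table["se"] <= 0).any():
            raise ValueError("se must be positive")
        table["z"] = table["beta"] / table["se"]
        self.table = table

    def __len__(self) -> int:
        return len(self.table)
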