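"""Runs of homozygosity (ROH) from ordered genotype dosages.

A PLINK-style sliding-window scan: windows of a fixed number of consecutive
SNPs on one chromosome are tagged *homozygous-compatible* when they contain
at most ``max_het_per_window`` heterozygotes and ``max_missing_per_window``
missing genotypes.  Each SNP is marked homozygous when the fraction of
compatible windows among those overlapping it reaches ``hit_fraction``;
maximal runs of marked SNPs that satisfy the minimum SNP count and minimum
physical length become ROH intervals.  Long ROH are the genomic signature of
consanguinity and localize recessive candidate variants.

Interval length is computed as ``end - start`` in base pairs (the difference
of the printed endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .io import CohortData, VariantRecord

__all__ = ["RohParams", "RohInterval", "detect_roh", "detect_roh_cohort", "variant_in_roh"]


@dataclass(frozen=True)
class RohParams:
    """Scan parameters; defaults follow common PLINK usage."""

    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    hit_fraction: float = 0.05
    min_length_bp: int = 1_000_000
    min_snps: int = 50


@dataclass(frozen=True)
class RohInterval:
    sample_id: str
    chrom: str
    start: int  # 1-based, closed
    end: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"ROH interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def _scan_chrom(
    sample_id: str,
    chrom: str,
    pos: np.ndarray,
    dos: np.ndarray,
    params: RohParams,
) -> list[RohInterval]:
    m = pos.size
    w = params.window_snps
    if m < w:
        return []
    het = (dos == 1.0).astype(int)
    miss = np.isnan(dos).astype(int)
    # windows start at 0 .. m-w; compatibility per window via cumulative sums
    chet = np.concatenate([[0], np.cumsum(het)])
    cmiss = np.concatenate([[0], np.cumsum(miss)])
    starts = np.arange(0, m - w + 1)
    ok = (chet[starts + w] - chet[starts] <= params.max_het_per_window) & (
        cmiss[starts + w] - cmiss[starts] <= params.max_missing_per_window
    )
    # for SNP i, windows covering it start in [i-w+1, i] clipped to valid range
    cok = np.concatenate([[0], np.cumsum(ok.astype(int))])
    lo = np.clip(np.arange(m) - w + 1, 0, starts.size - 1)
    hi = np.clip(np.arange(m), 0, starts.size - 1)
    n_cov = hi - lo + 1
    n_ok = cok[hi + 1] - cok[lo]
    marked = (n_ok / n_cov) >= params.hit_fraction

    intervals: list[RohInterval] = []
    i = 0
    while i < m:
        if not marked[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and marked[j + 1]:
            j += 1
        n_snps = j - i + 1
        length = int(pos[j] - pos[i])
        if n_snps >= params.min_snps and length >= params.min_length_bp:
            intervals.append(
                RohInterval(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[j]),
                    n_snps=n_snps,
                )
            )
        i = j + 1
    return intervals


def detect_roh(
    variants: Sequence[VariantRecord],
    dosages: np.ndarray,
    sample_id: str = "sample",
    params: RohParams | None = None,
) -> list[RohInterval]:
    """Detect ROH intervals for one sample.

    ``variants`` must be sorted by (chromosome, position); ``dosages`` is the
    matching 1-D vector with entries in {0, 1, 2, NaN}.  Chromosomes are
    scanned independently, so intervals are unaffected by variants on other
    chromosomes, and detected intervals are disjoint within a chromosome.
    """
    p = params or RohParams()
    dosages = np.asarray(dosages, dtype=float)
    if dosages.shape != (len(variants),):
        raise ValidationError("dosage vector length must match variant count")
    chroms = [v.chrom for v in variants]
    pos = np.array([v.pos for v in variants], dtype=np.int64)
    for k in range(1, len(variants)):
        if chroms[k] == chroms[k - 1] and pos[k] < pos[k - 1]:
            raise ValidationError(
                f"variants not sorted by position on {chroms[k]} near index {k}"
            )
    out: list[RohInterval] = []
    k = 0
    while k < len(variants):
        j = k
        while j + 1 < len(variants) and chroms[j + 1] == chroms[k]:
            j += 1
        out.extend(
            _scan_chrom(sample_id, chroms[k], pos[k : j + 1], dosages[k : j + 1], p)
        )
        k = j + 1
    return out


def detect_roh_cohort(
    cohort: CohortData, params: RohParams | None = None
) -> list[RohInterval]:
    """Run the ROH scan for every sample in a cohort."""
    order = sorted(
        range(cohort.n_variants),
        key=lambda j: (cohort.variants[j].chrom, cohort.variants[j].pos),
    )
    variants = [cohort.variants[j] for j in order]
    out: list[RohInterval] = []
    for i, s in enumerate(cohort.samples):
        out.extend(
            detect_roh(variants, cohort.dosages[i, order], s.sample_id, params)
        )
    return out


def variant_in_roh(
    variant: VariantRecord, intervals: Sequence[RohInterval]
) -> RohInterval | None:
    """The interval containing the variant (closed endpoints), or ``None``."""
    for iv in intervals:
        if iv.contains(variant.chrom, variant.pos):
            return iv
    return None
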