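"""Cohort input/output: genotypes, annotations, sample metadata, result tables.

Coordinates are 1-based fully-closed positions on hg19-style chromosome
labels, passed through verbatim.  Multi-allelic VCF sites are split into one
biallelic record per alternate allele; the dosage of a split record is the
count of that alternate allele in the genotype, irrespective of phase.
Missing genotypes become missing dosages (NaN); haploid genotypes are
rejected because the panel is autosomal.

All tables are UTF-8 tab-delimited text; ``.`` denotes a missing value in
outputs, and ``NA`` / ``.`` / the empty string parse as missing in inputs.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExonicFunction",
    "VariantRecord",
    "VariantAnnotation",
    "SampleInfo",
    "CohortData",
    "PREDICTOR_NAMES",
    "read_cohort_vcf",
    "read_annotations",
    "read_sample_table",
    "write_findings",
    "read_findings",
    "write_burden_table",
    "read_burden_table",
    "write_roh_table",
]

#: The seven computational pathogenicity predictors consulted for
#: supporting-evidence counts.  CADD is carried as a numeric phred score and
#: binarized downstream; the other six are categorical calls.
PREDICTOR_NAMES = (
    "CADD",
    "SIFT",
    "LRT",
    "MutationAssessor",
    "PolyPhen2-HVAR",
    "PolyPhen2-HDIV",
    "MutationTaster",
)

#: categorical predictors expected as annotation columns (CADD is numeric)
CATEGORICAL_PREDICTORS = PREDICTOR_NAMES[1:]

_PREDICTOR_COLUMNS = {
    "SIFT": "sift",
    "LRT": "lrt",
    "MutationAssessor": "mutation_assessor",
    "PolyPhen2-HVAR": "polyphen2_hvar",
    "PolyPhen2-HDIV": "polyphen2_hdiv",
    "MutationTaster": "mutation_taster",
}


class ExonicFunction(str, enum.Enum):
    MISSENSE = "missense"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT = "frameshift"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


# a few ANNOVAR-style spellings accepted on input
_EXONIC_ALIASES = {
    "nonsynonymous snv": ExonicFunction.MISSENSE,
    "nonsynonymous": ExonicFunction.MISSENSE,
    "synonymous snv": ExonicFunction.SYNONYMOUS,
    "frameshift insertion": ExonicFunction.FRAMESHIFT,
    "frameshift deletion": ExonicFunction.FRAMESHIFT,
    "stop gain": ExonicFunction.STOPGAIN,
    "stop loss": ExonicFunction.STOPLOSS,
}


def parse_exonic_function(token: str) -> ExonicFunction:
    t = token.strip().lower()
    try:
        return ExonicFunction(t)
    except ValueError:
        pass
    if t in _EXONIC_ALIASES:
        return _EXONIC_ALIASES[t]
    raise SchemaError(f"unknown exonic_function token: {token!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One normalized biallelic variant."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or set(allele) - set("ACGT"):
                raise ValidationError(
                    f"{label} allele must be a non-empty A/C/G/T string, got {allele!r}"
                )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical at {self.chrom}:{self.pos}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class VariantAnnotation:
    """Functional annotation for one variant (ANNOVAR-style fields)."""

    variant_id: str
    gene: str
    exonic_function: ExonicFunction
    splice_offset: int | None = None
    maf_exome_eas: float | None = None
    maf_genome_eas: float | None = None
    reve: float | None = None
    cadd: float | None = None
    #: categorical predictor calls: name -> "damaging" | "tolerated" | None
    predictor_calls: dict[str, str | None] = field(default_factory=dict)
    nucleotide_change: str | None = None
    protein_change: str | None = None

    def __post_init__(self) -> None:
        for maf, label in (
            (self.maf_exome_eas, "maf_exome_eas"),
            (self.maf_genome_eas, "maf_genome_eas"),
        ):
            if maf is not None and not (0.0 <= maf <= 1.0):
                raise ValidationError(
                    f"{label} outside [0,1] for {self.variant_id}: {maf}"
                )
        if self.reve is not None and not (0.0 <= self.reve <= 1.0):
            raise ValidationError(f"reve outside [0,1] for {self.variant_id}: {self.reve}")
        if self.cadd is not None and self.cadd < 0:
            raise ValidationError(f"cadd must be >= 0 for {self.variant_id}: {self.cadd}")
        unknown = set(self.predictor_calls) - set(PREDICTOR_NAMES)
        if unknown:
            raise ValidationError(
                f"unknown predictor names for {self.variant_id}: {sorted(unknown)}"
            )


class Status(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


class Subgroup(str, enum.Enum):
    SEOPD = "sEOPD"
    SLOPD = "sLOPD"
    FPD_AR = "FPD_AR"
    FPD_AD = "FPD_AD"
    CONTROL1 = "control1"
    CONTROL2 = "control2"


_CONTROL_SUBGROUPS = {Subgroup.CONTROL1, Subgroup.CONTROL2}


@dataclass
class SampleInfo:
    sample_id: str
    status: Status
    subgroup: Subgroup
    age: float | None = None
    sex: str | None = None  # "male" | "female" | None
    pcs: tuple[float, ...] = (0.0,) * 5

    def __post_init__(self) -> None:
        if len(self.pcs) != 5:
            raise ValidationError(
                f"sample {self.sample_id}: expected 5 principal components, "
                f"got {len(self.pcs)}"
            )
        is_ctrl_sub = self.subgroup in _CONTROL_SUBGROUPS
        if is_ctrl_sub != (self.status is Status.CONTROL):
            raise ValidationError(
                f"sample {self.sample_id}: status {self.status.value!r} inconsistent "
                f"with subgroup {self.subgroup.value!r}"
            )
        if self.sex not in (None, "male", "female"):
            raise ValidationError(
                f"sample {self.sample_id}: sex must be male/female/missing, got {self.sex!r}"
            )


@dataclass
class CohortData:
    """Samples x variants dosage matrix joined to metadata and annotations.

    ``dosages`` is a float array with entries in {0, 1, 2} and NaN for
    missing genotypes; rows follow ``samples`` order, columns ``variants``.
    """

    samples: list[SampleInfo]
    variants: list[VariantRecord]
    dosages: np.ndarray
    annotations: dict[str, VariantAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValidationError(
                f"dosage entries must be 0/1/2/missing; offending entry at "
                f"sample {self.samples[bad[0]].sample_id}, "
                f"variant {self.variants[bad[1]].id}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def case_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if s.status is Status.CASE], dtype=int
        )

    def control_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if s.status is Status.CONTROL],
            dtype=int,
        )

    def annotated_variant_indices(self) -> list[int]:
        """Indices of variants with an annotation entry.

        Variants observed in genotypes but lacking annotation are excluded
        from all analyses; the exclusion is logged.
        """
        kept, dropped = [], []
        for j, v in enumerate(self.variants):
            (kept if v.id in self.annotations else dropped).append(j)
        if dropped:
            logger.warning(
                "%d variant(s) without annotation excluded from analysis: %s",
                len(dropped),
                ", ".join(self.variants[j].id for j in dropped[:10]),
            )
        return kept

    def subset_samples(self, indices: Sequence[int]) -> "CohortData":
        idx = list(indices)
        return CohortData(
            samples=[self.samples[i] for i in idx],
            variants=self.variants,
            dosages=self.dosages[idx, :],
            annotations=self.annotations,
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_sample_table(path: str | Path) -> list[SampleInfo]:
    """Read a sample metadata TSV.

    Required columns: ``sample_id``, ``status``, ``subgroup``, ``age``,
    ``sex``, ``pc1`` .. ``pc5``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA", ".", ""])
    required = ["sample_id", "status", "subgroup", "age", "sex"] + [
        f"pc{i}" for i in range(1, 6)
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"sample table missing column(s): {missing}")
    samples = []
    for _, row in df.iterrows():
        try:
            status = Status(str(row["status"]).strip().lower())
        except ValueError:
            raise SchemaError(
                f"sample {row['sample_id']}: unknown status {row['status']!r}"
            ) from None
        try:
            subgroup = Subgroup(str(row["subgroup"]).strip())
        except ValueError:
            raise SchemaError(
                f"sample {row['sample_id']}: unknown subgroup {row['subgroup']!r}"
            ) from None
        sex = None if pd.isna(row["sex"]) else str(row["sex"]).strip().lower()
        age = None if pd.isna(row["age"]) else float(row["age"])
        pcs = tuple(float(row[f"pc{i}"]) for i in range(1, 6))
        samples.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                status=status,
                subgroup=subgroup,
                age=age,
                sex=sex,
                pcs=pcs,
            )
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_id(s) in sample table: {dupes}")
    return samples


def read_cohort_vcf(vcf_path: str | Path, sample_table_path: str | Path) -> CohortData:
    """Read genotypes from a VCF 4.x file joined to a sample metadata table.

    Multi-allelic sites are split into one biallelic record per alternate
    allele; the dosage of each record counts that allele in the unphased
    genotype.  Sample order follows the sample table (restricted to samples
    present in the VCF).  Returns a :class:`CohortData` without annotations.
    """
    table = read_sample_table(sample_table_path)
    vcf = VCF(str(vcf_path), gts012=False)
    vcf_samples = list(vcf.samples)
    table_ids = {s.sample_id for s in table}
    absent = [s for s in vcf_samples if s not in table_ids]
    if absent:
        raise ValidationError(
            f"VCF sample(s) absent from sample table: {absent[:20]}"
        )
    samples = [s for s in table if s.sample_id in set(vcf_samples)]
    vcf_col = {sid: k for k, sid in enumerate(vcf_samples)}
    reorder = [vcf_col[s.sample_id] for s in samples]

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for v in vcf:
        gts = v.genotypes  # list of [allele1, allele2, ..., phased]
        alleles = []
        for k, gt in enumerate(gts):
            if len(gt) != 3:  # ploidy != 2 (last element is the phase flag)
                raise ValidationError(
                    f"non-diploid genotype for sample {vcf_samples[k]} at "
                    f"{v.CHROM}:{v.POS}; the autosomal panel requires diploid GTs"
                )
            alleles.append((gt[0], gt[1]))
        for ai, alt in enumerate(v.ALT, start=1):
            rec = VariantRecord(chrom=str(v.CHROM), pos=int(v.POS), ref=v.REF, alt=alt)
            dos = np.empty(len(gts), dtype=float)
            for k, (a1, a2) in enumerate(alleles):
                if a1 < 0 or a2 < 0:
                    dos[k] = np.nan
                else:
                    dos[k] = float((a1 == ai) + (a2 == ai))
            variants.append(rec)
            rows.append(dos[reorder])
    dosages = (
        np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=float)
    )
    return CohortData(samples=samples, variants=variants, dosages=dosages)


_ANNOT_REQUIRED = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "exonic_function",
    "splice_offset",
    "maf_exome_eas",
    "maf_genome_eas",
    "reve",
    "cadd",
] + list(_PREDICTOR_COLUMNS.values())


def _parse_call(value) -> str | None:
    if pd.isna(value):
        return None
    t = str(value).strip().lower()
    if t in ("damaging", "d"):
        return "damaging"
    if t in ("tolerated", "t", "benign", "neutral", "n"):
        return "tolerated"
    raise SchemaError(f"unknown predictor call {value!r} (expected damaging/tolerated)")


def read_annotations(tsv_path: str | Path) -> dict[str, VariantAnnotation]:
    """Read an ANNOVAR-style variant annotation TSV keyed by chrom:pos:ref:alt."""
    df = pd.read_csv(
        tsv_path,
        sep="\t",
        dtype={"chrom": str, "ref": str, "alt": str, "gene": str},
        na_values=["NA", ".", ""],
        keep_default_na=True,
    )
    missing = [c for c in _ANNOT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table missing column(s): {missing}")
    out: dict[str, VariantAnnotation] = {}
    for _, row in df.iterrows():
        vid = f"{row['chrom']}:{int(row['pos'])}:{row['ref']}:{row['alt']}"
        if vid in out:
            raise ValidationError(f"duplicate variant key in annotation table: {vid}")
        calls = {
            name: _parse_call(row[col]) for name, col in _PREDICTOR_COLUMNS.items()
        }
        ann = VariantAnnotation(
            variant_id=vid,
            gene=str(row["gene"]).strip(),
            exonic_function=parse_exonic_function(str(row["exonic_function"])),
            splice_offset=None
            if pd.isna(row["splice_offset"])
            else int(row["splice_offset"]),
            maf_exome_eas=None
            if pd.isna(row["maf_exome_eas"])
            else float(row["maf_exome_eas"]),
            maf_genome_eas=None
            if pd.isna(row["maf_genome_eas"])
            else float(row["maf_genome_eas"]),
            reve=None if pd.isna(row["reve"]) else float(row["reve"]),
            cadd=None if pd.isna(row["cadd"]) else float(row["cadd"]),
            predictor_calls=calls,
            nucleotide_change=(
                None
                if "nucleotide_change" not in df.columns
                or pd.isna(row.get("nucleotide_change"))
                else str(row["nucleotide_change"])
            ),
            protein_change=(
                None
                if "protein_change" not in df.columns
                or pd.isna(row.get("protein_change"))
                else str(row["protein_change"])
            ),
        )
        out[vid] = ann
    return out


# ---------------------------------------------------------------------------
# writers (and their round-trip readers)
# ---------------------------------------------------------------------------

_FINDINGS_COLUMNS = [
    "sample_id",
    "gene",
    "model",
    "variant_ids",
    "nucleotide_changes",
    "protein_changes",
    "zygosity",
    "maf_exome_eas",
    "maf_genome_eas",
    "cadd",
    "reve",
    "predictor_support",
    "acmg",
    "screened_out",
    "screen_reason",
]


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_findings(findings, path: str | Path) -> None:
    """Write candidate findings to a TSV, one row per finding.

    Multi-variant (compound-heterozygous) findings join their per-variant
    fields with commas.  Row order is deterministic: (gene, sample_id, first
    variant position).
    """
    from .prioritize import CandidateFinding  # local import to avoid a cycle

    rows = []
    for f in findings:
        if not isinstance(f, CandidateFinding):
            raise ValidationError(f"expected CandidateFinding, got {type(f).__name__}")
        rows.append(f)
    rows.sort(key=lambda f: (f.gene, f.sample_id, f.variant_ids[0]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_FINDINGS_COLUMNS) + "\n")
        for f in rows:
            anns = f.annotations
            fh.write(
                "\t".join(
                    [
                        f.sample_id,
                        f.gene,
                        f.model.value,
                        ",".join(f.variant_ids),
                        ",".join(_fmt(a.nucleotide_change) for a in anns),
                        ",".join(_fmt(a.protein_change) for a in anns),
                        ",".join(f.zygosity),
                        ",".join(_fmt(a.maf_exome_eas) for a in anns),
                        ",".join(_fmt(a.maf_genome_eas) for a in anns),
                        ",".join(_fmt(a.cadd) for a in anns),
                        ",".join(_fmt(a.reve) for a in anns),
                        ",".join(str(s) for s in f.predictor_support),
                        _fmt(None if f.acmg is None else f.acmg.value),
                        _fmt(f.screened_out),
                        _fmt(f.screen_reason),
                    ]
                )
                + "\n"
            )


def read_findings(path: str | Path) -> pd.DataFrame:
    """Read back a findings TSV as a DataFrame (strings preserved verbatim)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _FINDINGS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"findings table missing column(s): {missing}")
    return df


_BURDEN_COLUMNS = [
    "gene",
    "cohort",
    "patient_subgroup",
    "variant_subgroup",
    "maf_threshold",
    "n_variants",
    "case_carriers",
    "control_carriers",
    "statistic",
    "rho_opt",
    "p_value",
    "tested",
    "suggestive",
    "significant",
]


def write_burden_table(results, path: str | Path) -> None:
    """Write gene x variant-subgroup burden results to a TSV.

    P-values are written with ``repr`` so they round-trip at full float
    precision; untested cells carry ``.`` in the statistic columns.
    """
    rows = sorted(
        results,
        key=lambda r: (r.gene, r.cohort, r.patient_subgroup, r.variant_subgroup, r.maf_threshold),
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_BURDEN_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.gene,
                        r.cohort,
                        r.patient_subgroup,
                        r.variant_subgroup,
                        _fmt(r.maf_threshold),
                        str(r.n_variants),
                        str(r.case_carriers),
                        str(r.control_carriers),
                        _fmt(r.statistic),
                        _fmt(r.rho_opt),
                        _fmt(r.p_value),
                        _fmt(r.tested),
                        _fmt(r.suggestive),
                        _fmt(r.significant),
                    ]
                )
                + "\n"
            )


def read_burden_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _BURDEN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"burden table missing column(s): {missing}")
    return df


def write_roh_table(intervals, path: str | Path) -> None:
    cols = ["sample_id", "chrom", "start", "end", "n_snps", "length_mb"]
    rows = sorted(intervals, key=lambda iv: (iv.sample_id, iv.chrom, iv.start))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for iv in rows:
            fh.write(
                f"{iv.sample_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.n_snps}\t"
                f"{iv.length_mb!r}\n"
            )
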