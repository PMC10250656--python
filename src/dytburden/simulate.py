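"""Synthetic case-control cohorts and fixtures for the analysis pipeline.

Two generators live here:

* :func:`simulate_cohort` — a configurable cohort simulator.  Genotypes are
  drawn under Hardy-Weinberg equilibrium at each variant's simulated
  population frequency; case status follows a logistic model with optional
  per-gene carrier effects and covariates (age, sex, five principal
  components).  The simulated population frequency doubles as the
  "gnomAD" annotation frequency, so rarity filters behave as they would on
  real annotations.  Everything is deterministic under the configured seed.

* :func:`make_paper_fixture` — small hand-built cohorts that encode the
  worked examples this package's candidate filters are calibrated against:
  the recessive findings table (``table1_ar``), the dominant findings table
  (``table2_ad``), and a consanguineous sample with an embedded homozygous
  tract (``roh_case``).  Each fixture adds *decoy* variants engineered to
  fail exactly one filter each, so tests localize filter bugs.

Neither generator models linkage disequilibrium, phasing, sequencing error,
or pedigrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .io import (
    CATEGORICAL_PREDICTORS,
    CohortData,
    ExonicFunction,
    SampleInfo,
    Status,
    Subgroup,
    VariantAnnotation,
    VariantRecord,
)
from .panel import GenePanel, Inheritance, PanelGene, load_panel

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "simulate_cohort_data",
    "make_paper_fixture",
    "make_paper_fixture_data",
    "write_vcf",
    "write_sample_table",
    "write_annotation_table",
    "PAPER_SUBGROUP_SIZES",
    "paper_scale_config",
    "TABLE1_DECOYS",
    "TABLE2_DECOYS",
]

#: Subgroup sizes of the study cohorts this simulator emulates (cases were
#: sporadic early-onset, sporadic late-onset, and familial recessive /
#: dominant probands; two control groups were sequenced on matching
#: platforms).
PAPER_SUBGROUP_SIZES = {
    "sEOPD": 1508,
    "sLOPD": 1962,
    "FPD_AR": 153,
    "FPD_AD": 336,
    "control1": 1652,
    "control2": 1279,
}


@dataclass
class SimConfig:
    """Simulation settings; defaults are desk-scale (200 vs 200, 10 genes)."""

    n_cases: int = 200
    n_controls: int = 200
    genes: list[PanelGene] | None = None  # None -> first 10 default-panel genes
    variants_per_gene: float = 30.0  # Poisson mean, min 1 per gene
    maf_range: tuple[float, float] = (1e-4, 0.01)  # log-uniform population MAF
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 0.45,
            "Dmis": 0.20,
            "LoF": 0.10,
            "synonymous": 0.25,
        }
    )
    effect_spec: dict[str, float] = field(default_factory=dict)  # gene -> log-OR
    age_mean: float = 43.0
    age_sd: float = 8.0
    covariate_coefs: tuple[float, float] = (0.0, 0.0)  # (age per-sd, sex) log-OR
    maf_missing_rate: float = 0.0
    case_subgroup: Subgroup = Subgroup.SEOPD
    control_subgroup: Subgroup = Subgroup.CONTROL1
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("n_cases and n_controls must be >= 1")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 or p > 1 for p in self.class_mix.values()):
            raise ValidationError("class_mix proportions must lie in [0,1] and sum to 1")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] < 0.5):
            raise ValidationError("maf_range must satisfy 0 < lo <= hi < 0.5")


def paper_scale_config(cohort: int = 1, scale: float = 1.0, seed: int = 0) -> SimConfig:
    """A study-shaped configuration: cohort 1 is early-onset cases vs control
    group 1 (1,508 vs 1,652), cohort 2 late-onset vs control group 2
    (1,962 vs 1,279); ``scale`` shrinks both groups proportionally."""
    if cohort == 1:
        nca, nco = PAPER_SUBGROUP_SIZES["sEOPD"], PAPER_SUBGROUP_SIZES["control1"]
        sub, ctl, age = Subgroup.SEOPD, Subgroup.CONTROL1, 43.0
    elif cohort == 2:
        nca, nco = PAPER_SUBGROUP_SIZES["sLOPD"], PAPER_SUBGROUP_SIZES["control2"]
        sub, ctl, age = Subgroup.SLOPD, Subgroup.CONTROL2, 62.0
    else:
        raise ValidationError("cohort must be 1 or 2")
    return SimConfig(
        n_cases=max(1, round(nca * scale)),
        n_controls=max(1, round(nco * scale)),
        case_subgroup=sub,
        control_subgroup=ctl,
        age_mean=age,
        seed=seed,
    )


_CLASS_ORDER = ("missense", "Dmis", "LoF", "synonymous")
_LOF_KINDS = (ExonicFunction.STOPGAIN, ExonicFunction.FRAMESHIFT, ExonicFunction.SPLICING)
_BASES = ("A", "C", "G", "T")


def _draw_variant_annotations(cfg: SimConfig, genes: list[PanelGene], rng):
    """Variant records + annotations + population frequencies, gene by gene."""
    records: list[VariantRecord] = []
    anns: dict[str, VariantAnnotation] = {}
    freqs: list[float] = []
    lo, hi = cfg.maf_range
    probs = [cfg.class_mix.get(c, 0.0) for c in _CLASS_ORDER]
    for g_idx, gene in enumerate(genes):
        m = max(1, int(rng.poisson(cfg.variants_per_gene)))
        chrom = f"chr{(g_idx % 22) + 1}"
        base = 1_000_000 + 10_000_000 * g_idx
        pos = np.sort(rng.choice(np.arange(base, base + 200_000), size=m, replace=False))
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rec = VariantRecord(chrom=chrom, pos=int(p), ref=_BASES[ref], alt=_BASES[alt])
            f = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
            cls = _CLASS_ORDER[rng.choice(4, p=probs)]
            reve = None
            splice_offset = None
            if cls == "missense":
                func = ExonicFunction.MISSENSE
                reve = float(rng.uniform(0.0, 0.6999))
            elif cls == "Dmis":
                func = ExonicFunction.MISSENSE
                reve = float(rng.uniform(0.7, 1.0))
            elif cls == "LoF":
                func = _LOF_KINDS[rng.integers(3)]
                if func is ExonicFunction.SPLICING:
                    splice_offset = int(rng.choice([-2, -1, 1, 2]))
            else:
                func = ExonicFunction.SYNONYMOUS
            damaging = cls in ("Dmis", "LoF")
            cadd = float(max(0.0, rng.normal(27.0, 4.0) if damaging else rng.normal(10.0, 5.0)))
            calls = {
                name: ("damaging" if rng.random() < (0.9 if damaging else 0.2) else "tolerated")
                for name in CATEGORICAL_PREDICTORS
            }
            maf_e = None if rng.random() < cfg.maf_missing_rate else f
            maf_g = None if rng.random() < cfg.maf_missing_rate else f
            anns[rec.id] = VariantAnnotation(
                variant_id=rec.id,
                gene=gene.symbol,
                exonic_function=func,
                splice_offset=splice_offset,
                maf_exome_eas=maf_e,
                maf_genome_eas=maf_g,
                reve=reve,
                cadd=round(cadd, 1),
                predictor_calls=calls,
            )
            records.append(rec)
            freqs.append(f)
    return records, anns, np.array(freqs)


def simulate_cohort_data(config: SimConfig) -> CohortData:
    """Simulate a cohort in memory; see the module docstring for the model."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.genes if cfg.genes is not None else list(load_panel())[:10]
    records, anns, freqs = _draw_variant_annotations(cfg, genes, rng)
    m = len(records)

    from .classify import classify  # deferred: classify depends on io types only

    deleterious = np.array([classify(anns[r.id]).is_deleterious for r in records])
    gene_of = np.array([anns[r.id].gene for r in records])

    n_target = cfg.n_cases + cfg.n_controls
    n_pool = int(math.ceil(n_target * 2.5)) + 50
    G = rng.binomial(2, freqs[None, :], size=(n_pool, m)).astype(float)

    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n_pool)
    sex = rng.integers(0, 2, size=n_pool)  # 1 = male
    pcs = rng.standard_normal(size=(n_pool, 5))

    eta = np.zeros(n_pool)
    for gene_sym, beta in cfg.effect_spec.items():
        cols = np.nonzero((gene_of == gene_sym) & deleterious)[0]
        if cols.size:
            carrier = (G[:, cols] >= 1).any(axis=1)
            eta += beta * carrier
    b_age, b_sex = cfg.covariate_coefs
    eta += b_age * (age - cfg.age_mean) / cfg.age_sd + b_sex * sex
    prob = 1.0 / (1.0 + np.exp(-eta))
    status = rng.random(n_pool) < prob
    case_rows = np.nonzero(status)[0][: cfg.n_cases]
    ctrl_rows = np.nonzero(~status)[0][: cfg.n_controls]
    if case_rows.size < cfg.n_cases or ctrl_rows.size < cfg.n_controls:
        raise ValidationError(
            "infeasible configuration: simulated pool cannot supply the requested "
            "numbers of cases and controls (extreme effect sizes?)"
        )

    samples: list[SampleInfo] = []
    rows = []
    for k, i in enumerate(case_rows, start=1):
        samples.append(
            SampleInfo(
                sample_id=f"CASE-{k:04d}",
                status=Status.CASE,
                subgroup=cfg.case_subgroup,
                age=round(float(age[i]), 1),
                sex="male" if sex[i] else "female",
                pcs=tuple(round(float(x), 4) for x in pcs[i]),
            )
        )
        rows.append(G[i])
    for k, i in enumerate(ctrl_rows, start=1):
        samples.append(
            SampleInfo(
                sample_id=f"CTRL-{k:04d}",
                status=Status.CONTROL,
                subgroup=cfg.control_subgroup,
                age=round(float(age[i]), 1),
                sex="male" if sex[i] else "female",
                pcs=tuple(round(float(x), 4) for x in pcs[i]),
            )
        )
        rows.append(G[i])
    return CohortData(
        samples=samples,
        variants=records,
        dosages=np.vstack(rows),
        annotations=anns,
    )


# ---------------------------------------------------------------------------
# text writers (the exact formats the readers consume)
# ---------------------------------------------------------------------------


def _dosage_to_gt(d: float) -> str:
    if np.isnan(d):
        return "./."
    return {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}[float(d)]


def write_vcf(cohort: CohortData, path: str | Path) -> None:
    """Emit a minimal GT-only VCF 4.2 for a biallelic cohort."""
    chroms = []
    for v in cohort.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    order = sorted(
        range(cohort.n_variants),
        key=lambda j: (chroms.index(cohort.variants[j].chrom), cohort.variants[j].pos),
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        for j in order:
            v = cohort.variants[j]
            gts = "\t".join(_dosage_to_gt(d) for d in cohort.dosages[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_sample_table(samples: list[SampleInfo], path: str | Path) -> None:
    cols = ["sample_id", "status", "subgroup", "age", "sex"] + [f"pc{i}" for i in range(1, 6)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in samples:
            fh.write(
                "\t".join(
                    [
                        s.sample_id,
                        s.status.value,
                        s.subgroup.value,
                        "." if s.age is None else repr(s.age),
                        "." if s.sex is None else s.sex,
                        *[repr(p) for p in s.pcs],
                    ]
                )
                + "\n"
            )


_PREDICTOR_COLS = {
    "SIFT": "sift",
    "LRT": "lrt",
    "MutationAssessor": "mutation_assessor",
    "PolyPhen2-HVAR": "polyphen2_hvar",
    "PolyPhen2-HDIV": "polyphen2_hdiv",
    "MutationTaster": "mutation_taster",
}


def write_annotation_table(
    annotations: dict[str, VariantAnnotation], path: str | Path
) -> None:
    cols = [
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
        *list(_PREDICTOR_COLS.values()),
        "nucleotide_change",
        "protein_change",
    ]

    def fmt(x):
        return "NA" if x is None else (repr(x) if isinstance(x, float) else str(x))

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for vid in sorted(annotations):
            a = annotations[vid]
            chrom, pos, ref, alt = vid.split(":")
            row = [
                chrom,
                pos,
                ref,
                alt,
                a.gene,
                a.exonic_function.value,
                fmt(a.splice_offset),
                fmt(a.maf_exome_eas),
                fmt(a.maf_genome_eas),
                fmt(a.reve),
                fmt(a.cadd),
                *[
                    "NA" if a.predictor_calls.get(name) is None else a.predictor_calls[name]
                    for name in _PREDICTOR_COLS
                ],
                fmt(a.nucleotide_change),
                fmt(a.protein_change),
            ]
            fh.write("\t".join(row) + "\n")


def simulate_cohort(config: SimConfig, out_dir: str | Path):
    """Simulate and write the (VCF, annotation TSV, sample TSV) file triple."""
    cohort = simulate_cohort_data(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcf = out / "cohort.vcf"
    ann = out / "annotations.tsv"
    smp = out / "samples.tsv"
    write_vcf(cohort, vcf)
    write_annotation_table(cohort.annotations, ann)
    write_sample_table(cohort.samples, smp)
    return vcf, ann, smp


# ---------------------------------------------------------------------------
# worked-example fixtures
# ---------------------------------------------------------------------------

_ALL_DAMAGING = {name: "damaging" for name in CATEGORICAL_PREDICTORS}
_ALL_TOLERATED = {name: "tolerated" for name in CATEGORICAL_PREDICTORS}

# Recessive-model findings: (vid fields, annotation fields, genotypes)
# MAF pairs, CADD and ReVe reproduce the published candidate table; decoys
# each violate exactly one filter (`fails` key).
_TABLE1_VARIANTS = [
    # --- true candidates -------------------------------------------------
    dict(chrom="chr2", pos=238275918, ref="C", alt="T", gene="COL6A3",
         func=ExonicFunction.MISSENSE, maf=(0.0063, 0.0099), cadd=29.6, reve=0.851,
         nchange="c.4912G>A", pchange="p.A1638T",
         genotypes={"AR-146": 2, "CTRL-A01": 1}),  # het-only in controls: retained
    dict(chrom="chr2", pos=238283448, ref="G", alt="A", gene="COL6A3",
         func=ExonicFunction.MISSENSE, maf=(0.0021, 0.0012), cadd=23.3, reve=0.728,
         nchange="c.3286C>T", pchange="p.R1096C",
         genotypes={"EOPD-0488": 1, "EOPD-1304": 1}),
    dict(chrom="chr2", pos=238266491, ref="G", alt="C", gene="COL6A3",
         func=ExonicFunction.MISSENSE, maf=(0.0003, 0.0006), cadd=27.0, reve=0.766,
         nchange="c.6506C>G", pchange="p.P2169R",
         genotypes={"EOPD-0488": 1}),
    dict(chrom="chr2", pos=238249328, ref="G", alt="A", gene="COL6A3",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=27.9, reve=0.889,
         nchange="c.8231C>T", pchange="p.T2744M",
         genotypes={"EOPD-1304": 1}),
    dict(chrom="chr2", pos=238277596, ref="G", alt="A", gene="COL6A3",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=24.4, reve=0.856,
         nchange="c.4510C>T", pchange="p.R1504W",
         genotypes={"EOPD-0766": 1}),
    dict(chrom="chr2", pos=238270387, ref="G", alt="T", gene="COL6A3",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=21.8, reve=0.763,
         nchange="c.6151C>A", pchange="p.P2051T",
         genotypes={"EOPD-0766": 1}),
    dict(chrom="chr11", pos=2192961, ref="G", alt="C", gene="TH",
         func=ExonicFunction.MISSENSE, maf=(0.0001, None), cadd=26.0, reve=0.777,
         nchange="c.56C>G", pchange="p.S19C",
         genotypes={"LOPD-0390": 2}),
    # --- decoys ----------------------------------------------------------
    dict(chrom="chr2", pos=238200001, ref="A", alt="G", gene="COL6A3",
         func=ExonicFunction.MISSENSE, maf=(0.05, 0.04), cadd=25.0, reve=0.80,
         genotypes={"DEC-01": 2}, fails="maf"),
    dict(chrom="chr11", pos=2180001, ref="C", alt="T", gene="TH",
         func=ExonicFunction.MISSENSE, maf=(0.02, 0.01), cadd=24.0, reve=0.75,
         genotypes={"DEC-06": 2}, fails="maf"),
    dict(chrom="chr2", pos=238200101, ref="C", alt="T", gene="COL6A3",
         func=ExonicFunction.MISSENSE, maf=(0.001, 0.001), cadd=22.0, reve=0.30,
         genotypes={"DEC-02": 2}, fails="reve"),
    dict(chrom="chr11", pos=2180101, ref="G", alt="A", gene="TH",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=23.0, reve=0.699,
         genotypes={"DEC-07": 2}, fails="reve"),
    dict(chrom="chr2", pos=238200201, ref="G", alt="A", gene="COL6A3",
         func=ExonicFunction.SYNONYMOUS, maf=(0.001, 0.001), cadd=5.0, reve=None,
         genotypes={"DEC-03": 2}, fails="class"),
    dict(chrom="chr11", pos=2180201, ref="T", alt="C", gene="TH",
         func=ExonicFunction.SYNONYMOUS, maf=(0.0, 0.0), cadd=4.0, reve=None,
         genotypes={"DEC-08": 2}, fails="class"),
    dict(chrom="chr11", pos=2180301, ref="A", alt="T", gene="TH",
         func=ExonicFunction.MISSENSE, maf=(0.0005, 0.0005), cadd=26.0, reve=0.90,
         genotypes={"DEC-04": 1}, fails="pairing"),
    dict(chrom="chr2", pos=238200301, ref="T", alt="G", gene="COL6A3",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=25.0, reve=0.80,
         genotypes={"DEC-09": 1}, fails="pairing"),
    dict(chrom="chr11", pos=2180401, ref="C", alt="G", gene="TH",
         func=ExonicFunction.MISSENSE, maf=(0.002, 0.002), cadd=27.0, reve=0.85,
         genotypes={"DEC-05": 2, "CTRL-A02": 2}, fails="control"),
    # a compound-het pair whose two members are both carried by one control
    dict(chrom="chr2", pos=238200401, ref="A", alt="C", gene="COL6A3",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=26.0, reve=0.82,
         genotypes={"DEC-10": 1, "CTRL-A03": 1}, fails="control"),
    dict(chrom="chr2", pos=238200501, ref="G", alt="C", gene="COL6A3",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=26.5, reve=0.83,
         genotypes={"DEC-10": 1, "CTRL-A03": 1}, fails="control"),
]

_TABLE1_SAMPLES = [
    ("AR-146", Status.CASE, Subgroup.FPD_AR, 47.0, "male"),
    ("EOPD-0488", Status.CASE, Subgroup.SEOPD, 41.0, "female"),
    ("EOPD-1304", Status.CASE, Subgroup.SEOPD, 44.0, "male"),
    ("EOPD-0766", Status.CASE, Subgroup.SEOPD, 39.0, "female"),
    ("LOPD-0390", Status.CASE, Subgroup.SLOPD, 59.0, "male"),
    *[(f"DEC-{i:02d}", Status.CASE, Subgroup.SEOPD, 45.0, "male") for i in range(1, 11)],
    ("CTRL-A01", Status.CONTROL, Subgroup.CONTROL1, 44.0, "female"),
    ("CTRL-A02", Status.CONTROL, Subgroup.CONTROL1, 47.0, "male"),
    ("CTRL-A03", Status.CONTROL, Subgroup.CONTROL1, 41.0, "female"),
    ("CTRL-A04", Status.CONTROL, Subgroup.CONTROL1, 45.0, "male"),
]

# Dominant-model findings table plus decoys against the stricter MAF
# threshold, the control screen, the ReVe cutoff, the consequence class, and
# the heterozygous-state requirement.
_TABLE2_VARIANTS = [
    dict(chrom="chr11", pos=26621198, ref="G", alt="A", gene="ANO3",
         func=ExonicFunction.STOPGAIN, maf=(None, None), cadd=41.0, reve=0.740,
         nchange="c.1773G>A", pchange="p.W591X",
         genotypes={"EOPD-0001": 1}),
    dict(chrom="chr11", pos=26669285, ref="G", alt="A", gene="ANO3",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=23.7, reve=0.768,
         nchange="c.2458G>A", pchange="p.G820S",
         genotypes={"EOPD-0190": 1, "EOPD-1469": 1}),
    dict(chrom="chr3", pos=123044224, ref="C", alt="T", gene="ADCY5",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=31.0, reve=0.854,
         nchange="c.2033G>A", pchange="p.R678H",
         genotypes={"LOPD-1445": 1}),
    dict(chrom="chr1", pos=43392818, ref="C", alt="T", gene="SLC2A1",
         func=ExonicFunction.MISSENSE, maf=(0.0, None), cadd=26.3, reve=0.812,
         nchange="c.1373G>A", pchange="p.R458Q",
         genotypes={"LOPD-0694": 1}),
    # --- decoys ----------------------------------------------------------
    dict(chrom="chr11", pos=26600001, ref="A", alt="G", gene="ANO3",
         func=ExonicFunction.MISSENSE, maf=(0.0021, 0.0012), cadd=25.0, reve=0.80,
         genotypes={"DEC-11": 1}, fails="maf"),
    dict(chrom="chr11", pos=26600101, ref="C", alt="T", gene="ANO3",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=26.0, reve=0.82,
         genotypes={"DEC-12": 1, "CTRL-B01": 1}, fails="control"),
    dict(chrom="chr3", pos=123000001, ref="G", alt="A", gene="ADCY5",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=20.0, reve=0.50,
         genotypes={"DEC-13": 1}, fails="reve"),
    dict(chrom="chr1", pos=43300001, ref="T", alt="C", gene="SLC2A1",
         func=ExonicFunction.SYNONYMOUS, maf=(0.0, 0.0), cadd=3.0, reve=None,
         genotypes={"DEC-14": 1}, fails="class"),
    dict(chrom="chr1", pos=43300101, ref="G", alt="T", gene="SLC2A1",
         func=ExonicFunction.MISSENSE, maf=(0.0, 0.0), cadd=27.0, reve=0.80,
         genotypes={"DEC-15": 2}, fails="zygosity"),
]

_TABLE2_SAMPLES = [
    ("EOPD-0001", Status.CASE, Subgroup.SEOPD, 38.0, "male"),
    ("EOPD-0190", Status.CASE, Subgroup.SEOPD, 42.0, "female"),
    ("EOPD-1469", Status.CASE, Subgroup.SEOPD, 46.0, "male"),
    ("LOPD-1445", Status.CASE, Subgroup.SLOPD, 61.0, "female"),
    ("LOPD-0694", Status.CASE, Subgroup.SLOPD, 65.0, "male"),
    *[(f"DEC-{i}", Status.CASE, Subgroup.SEOPD, 45.0, "male") for i in range(11, 16)],
    ("CTRL-B01", Status.CONTROL, Subgroup.CONTROL1, 43.0, "female"),
    ("CTRL-B02", Status.CONTROL, Subgroup.CONTROL1, 45.0, "male"),
]

#: decoy variant id -> the single filter the decoy is engineered to fail
TABLE1_DECOYS = {
    f"{v['chrom']}:{v['pos']}:{v['ref']}:{v['alt']}": v["fails"]
    for v in _TABLE1_VARIANTS
    if "fails" in v
}
TABLE2_DECOYS = {
    f"{v['chrom']}:{v['pos']}:{v['ref']}:{v['alt']}": v["fails"]
    for v in _TABLE2_VARIANTS
    if "fails" in v
}

#: the homozygous tract embedded in the roh_case fixture (a consanguineous
#: proband; the recessive candidate at chr2:238275918 lies inside it)
ROH_TRACT = ("chr2", 237614085, 242978914)


def _build_fixture(variant_rows, sample_rows) -> CohortData:
    samples = [
        SampleInfo(sample_id=sid, status=st, subgroup=sub, age=age, sex=sex,
                   pcs=(0.0, 0.0, 0.0, 0.0, 0.0))
        for sid, st, sub, age, sex in sample_rows
    ]
    records, anns = [], {}
    dosages = np.zeros((len(samples), len(variant_rows)))
    sample_index = {s.sample_id: i for i, s in enumerate(samples)}
    for j, row in enumerate(variant_rows):
        rec = VariantRecord(row["chrom"], row["pos"], row["ref"], row["alt"])
        records.append(rec)
        lof_like = row["func"] in (
            ExonicFunction.STOPGAIN,
            ExonicFunction.STOPLOSS,
            ExonicFunction.FRAMESHIFT,
            ExonicFunction.SPLICING,
        )
        damaging_like = lof_like or (row.get("reve") or 0.0) >= 0.7
        calls = dict(_ALL_DAMAGING) if damaging_like else dict(_ALL_TOLERATED)
        anns[rec.id] = VariantAnnotation(
            variant_id=rec.id,
            gene=row["gene"],
            exonic_function=row["func"],
            maf_exome_eas=row["maf"][0],
            maf_genome_eas=row["maf"][1],
            reve=row.get("reve"),
            cadd=row.get("cadd"),
            predictor_calls=calls,
            nucleotide_change=row.get("nchange"),
            protein_change=row.get("pchange"),
        )
        for sid, d in row["genotypes"].items():
            dosages[sample_index[sid], j] = float(d)
    return CohortData(samples=samples, variants=records, dosages=dosages, annotations=anns)


def _build_roh_case() -> CohortData:
    chrom, start, end = ROH_TRACT
    candidate_pos = 238275918
    n_tract = 150
    tract_pos = np.linspace(start, end, n_tract).astype(np.int64)
    tract_pos[np.argmin(np.abs(tract_pos - candidate_pos))] = candidate_pos
    tract_pos = np.unique(tract_pos)
    flank_left = np.arange(start - 60 * 30_000, start, 30_000, dtype=np.int64)
    flank_right = np.arange(end + 30_000, end + 61 * 30_000, 30_000, dtype=np.int64)
    pos = np.concatenate([flank_left, tract_pos, flank_right])
    records = [VariantRecord(chrom, int(p), "A", "G") for p in pos]
    # alternating homozygous genotypes inside the tract, heterozygous flanks
    dos = np.empty(pos.size)
    in_tract = (pos >= start) & (pos <= end)
    dos[~in_tract] = 1.0
    dos[in_tract] = np.where(np.arange(in_tract.sum()) % 2 == 0, 2.0, 0.0)
    samples = [
        SampleInfo("AR-146", Status.CASE, Subgroup.FPD_AR, 47.0, "male",
                   (0.0, 0.0, 0.0, 0.0, 0.0))
    ]
    cand = VariantRecord(chrom, candidate_pos, "C", "T")
    anns = {
        cand.id: VariantAnnotation(
            variant_id=cand.id,
            gene="COL6A3",
            exonic_function=ExonicFunction.MISSENSE,
            maf_exome_eas=0.0063,
            maf_genome_eas=0.0099,
            reve=0.851,
            cadd=29.6,
            predictor_calls=dict(_ALL_DAMAGING),
        )
    }
    j = int(np.nonzero(pos == candidate_pos)[0][0])
    records[j] = cand
    dos[j] = 2.0
    return CohortData(
        samples=samples, variants=records, dosages=dos[None, :], annotations=anns
    )


def make_paper_fixture_data(which: str) -> CohortData:
    """Build a worked-example fixture cohort in memory.

    ``which`` is one of ``table1_ar`` (recessive candidates plus decoys),
    ``table2_ad`` (dominant candidates plus decoys), or ``roh_case`` (one
    consanguineous sample with an embedded 5.36 Mb homozygous tract).
    """
    if which == "table1_ar":
        return _build_fixture(_TABLE1_VARIANTS, _TABLE1_SAMPLES)
    if which == "table2_ad":
        return _build_fixture(_TABLE2_VARIANTS, _TABLE2_SAMPLES)
    if which == "roh_case":
        return _build_roh_case()
    raise ValidationError(
        f"unknown fixture {which!r}; expected table1_ar, table2_ad or roh_case"
    )


def make_paper_fixture(which: str, out_dir: str | Path):
    """Write a fixture as the (VCF, annotation TSV, sample TSV) file triple."""
    cohort = make_paper_fixture_data(which)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcf, ann, smp = out / f"{which}.vcf", out / f"{which}_annotations.tsv", out / f"{which}_samples.tsv"
    write_vcf(cohort, vcf)
    write_annotation_table(cohort.annotations, ann)
    write_sample_table(cohort.samples, smp)
    return vcf, ann, smp
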