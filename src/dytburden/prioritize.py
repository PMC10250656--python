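"""Candidate-finding identification under recessive and dominant models.

For each case sample the module emits *findings* — sample/gene events that
survive the inheritance-model filters:

* ``AR_hom``: a deleterious homozygote (dosage 2) with effective MAF < 0.01
  in a gene screened under the recessive model;
* ``AR_comphet``: an unordered pair of distinct deleterious heterozygotes
  (dosage 1 each, both MAF < 0.01) in the same recessive-model gene — a
  *putative* compound heterozygote, phase unconfirmed;
* ``AD_het``: a deleterious heterozygote with effective MAF < 0.001 in a
  gene screened under the dominant model.

Genes annotated with both inheritance patterns are evaluated under both
models independently.  Findings are then screened against healthy controls
(dominant findings drop on any control carrier; recessive findings drop only
on a biallelic control) and classified by a configurable reduced ACMG
evidence engine.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .classify import classify, effective_maf
from .exceptions import ValidationError
from .io import CohortData, VariantAnnotation
from .panel import GenePanel

logger = logging.getLogger(__name__)

__all__ = [
    "Model",
    "AcmgClass",
    "CandidateFinding",
    "AcmgConfig",
    "load_acmg_config",
    "ar_candidates",
    "ad_candidates",
    "control_screen",
    "predictor_support",
    "acmg_classify",
    "classify_findings",
    "AR_MAF_MAX",
    "AD_MAF_MAX",
]

AR_MAF_MAX = 0.01
AD_MAF_MAX = 0.001


class Model(str, enum.Enum):
    AR_HOM = "AR_hom"
    AR_COMPHET = "AR_comphet"
    AD_HET = "AD_het"


class AcmgClass(str, enum.Enum):
    P = "P"
    LP = "LP"
    US = "US"


_CLASS_RANK = {AcmgClass.P: 2, AcmgClass.LP: 1, AcmgClass.US: 0}


@dataclass
class CandidateFinding:
    """One sample-gene event under an inheritance model."""

    sample_id: str
    gene: str
    model: Model
    variant_ids: list[str]
    annotations: list[VariantAnnotation]
    zygosity: list[str]  # "Hom" / "Het" per variant
    predictor_support: list[int] = field(default_factory=list)
    acmg: AcmgClass | None = None
    acmg_per_variant: list[AcmgClass] = field(default_factory=list)
    evidence_per_variant: list[tuple[str, ...]] = field(default_factory=list)
    screened_out: bool = False
    screen_reason: str | None = None

    def __post_init__(self) -> None:
        n = len(self.variant_ids)
        if self.model is Model.AR_COMPHET:
            if n != 2 or self.variant_ids[0] == self.variant_ids[1]:
                raise ValidationError(
                    "AR_comphet finding requires exactly 2 distinct variants"
                )
        elif n != 1:
            raise ValidationError(f"{self.model.value} finding requires exactly 1 variant")
        if len(self.annotations) != n or len(self.zygosity) != n:
            raise ValidationError("per-variant fields must match variant_ids length")
        genes = {a.gene for a in self.annotations}
        if genes != {self.gene}:
            raise ValidationError(
                f"finding gene {self.gene!r} inconsistent with annotations {genes}"
            )


def _gene_variant_indices(cohort: CohortData) -> dict[str, list[int]]:
    by_gene: dict[str, list[int]] = {}
    for j in cohort.annotated_variant_indices():
        ann = cohort.annotations[cohort.variants[j].id]
        by_gene.setdefault(ann.gene, []).append(j)
    return by_gene


def _deleterious_rare(cohort: CohortData, j: int, maf_max: float) -> bool:
    ann = cohort.annotations[cohort.variants[j].id]
    vc = classify(ann)
    return vc.is_deleterious and vc.effective_maf < maf_max


def _finding(cohort, sample_i, gene, model, var_idx, zygosity) -> CandidateFinding:
    anns = [cohort.annotations[cohort.variants[j].id] for j in var_idx]
    return CandidateFinding(
        sample_id=cohort.samples[sample_i].sample_id,
        gene=gene,
        model=model,
        variant_ids=[cohort.variants[j].id for j in var_idx],
        annotations=anns,
        zygosity=zygosity,
        predictor_support=[predictor_support(a) for a in anns],
    )


def ar_candidates(cohort: CohortData, panel: GenePanel) -> list[CandidateFinding]:
    """Recessive-model findings for every case sample.

    Missing dosages are treated as non-carrier (conservative candidate
    calling).  Compound-heterozygous findings are emitted per unordered pair,
    so three qualifying heterozygotes in one gene yield three pair findings.
    """
    by_gene = _gene_variant_indices(cohort)
    out: list[CandidateFinding] = []
    case_idx = cohort.case_indices()
    for gene in (g.symbol for g in panel.recessive_genes()):
        cols = [
            j for j in by_gene.get(gene, []) if _deleterious_rare(cohort, j, AR_MAF_MAX)
        ]
        if not cols:
            continue
        sub = cohort.dosages[np.ix_(case_idx, cols)]
        sub = np.nan_to_num(sub, nan=0.0)
        for r, i in enumerate(case_idx):
            hom = [cols[c] for c in np.nonzero(sub[r] == 2.0)[0]]
            het = [cols[c] for c in np.nonzero(sub[r] == 1.0)[0]]
            for j in hom:
                out.append(_finding(cohort, i, gene, Model.AR_HOM, [j], ["Hom"]))
            for j1, j2 in itertools.combinations(het, 2):
                out.append(
                    _finding(
                        cohort, i, gene, Model.AR_COMPHET, [j1, j2], ["Het", "Het"]
                    )
                )
    out.sort(key=lambda f: (f.gene, f.sample_id, f.model.value, f.variant_ids))
    return out


def ad_candidates(cohort: CohortData, panel: GenePanel) -> list[CandidateFinding]:
    """Dominant-model findings: deleterious heterozygotes with MAF < 0.001.

    Homozygotes are not emitted under this model; genes with both inheritance
    patterns are additionally screened by :func:`ar_candidates` under its own
    criteria.
    """
    by_gene = _gene_variant_indices(cohort)
    out: list[CandidateFinding] = []
    case_idx = cohort.case_indices()
    for gene in (g.symbol for g in panel.dominant_genes()):
        cols = [
            j for j in by_gene.get(gene, []) if _deleterious_rare(cohort, j, AD_MAF_MAX)
        ]
        if not cols:
            continue
        sub = np.nan_to_num(cohort.dosages[np.ix_(case_idx, cols)], nan=0.0)
        for r, i in enumerate(case_idx):
            for c in np.nonzero(sub[r] == 1.0)[0]:
                out.append(_finding(cohort, i, gene, Model.AD_HET, [cols[c]], ["Het"]))
    out.sort(key=lambda f: (f.gene, f.sample_id, f.variant_ids))
    return out


def _control_dosages(cohort: CohortData, variant_id: str) -> np.ndarray:
    j = cohort.variant_ids.index(variant_id)
    d = cohort.dosages[cohort.control_indices(), j]
    return np.nan_to_num(d, nan=0.0)


def control_screen(
    findings: list[CandidateFinding], cohort: CohortData
) -> list[CandidateFinding]:
    """Flag findings contradicted by healthy-control genotypes.

    Dominant findings are screened out if *any* control carries the variant;
    recessive findings only if some control is biallelic — homozygous for the
    finding's variant, or (for a compound-het pair) homozygous for either
    member or carrying both members.  Screening mutates the ``screened_out``
    flag in place and returns the same list; it is monotone in the control
    genotypes.
    """
    ctrl_idx = cohort.control_indices()
    if ctrl_idx.size == 0:
        logger.warning("no controls in cohort; control screening is a no-op")
        return findings
    for f in findings:
        if f.model is Model.AD_HET:
            if (_control_dosages(cohort, f.variant_ids[0]) >= 1).any():
                f.screened_out = True
                f.screen_reason = "control carrier"
        elif f.model is Model.AR_HOM:
            if (_control_dosages(cohort, f.variant_ids[0]) == 2).any():
                f.screened_out = True
                f.screen_reason = "control biallelic"
        else:  # AR_comphet
            d1 = _control_dosages(cohort, f.variant_ids[0])
            d2 = _control_dosages(cohort, f.variant_ids[1])
            if ((d1 == 2) | (d2 == 2) | ((d1 >= 1) & (d2 >= 1))).any():
                f.screened_out = True
                f.screen_reason = "control biallelic"
    return findings


def predictor_support(ann: VariantAnnotation, cadd_damaging_min: float = 20.0) -> int:
    """Number of the seven pathogenicity predictors calling the variant damaging.

    The six categorical predictors contribute their stored calls; CADD
    contributes one count when its phred score meets ``cadd_damaging_min``.
    Missing calls contribute nothing.
    """
    n = sum(1 for call in ann.predictor_calls.values() if call == "damaging")
    if ann.cadd is not None and ann.cadd >= cadd_damaging_min:
        n += 1
    return n


# ---------------------------------------------------------------------------
# reduced ACMG evidence engine
# ---------------------------------------------------------------------------

_KNOWN_RULES = {"lof", "absent", "predictor_support"}


@dataclass
class AcmgConfig:
    """Configurable evidence codes and combining table.

    ``evidence`` maps a code name to its predicate parameters; ``combining``
    maps a class to an ordered list of requirements, each a set of codes with
    an optional inheritance-model restriction.
    """

    cadd_damaging_min: float
    evidence: dict[str, dict]
    combining: dict[AcmgClass, list[dict]]

    def validate(self) -> None:
        for code, rule in self.evidence.items():
            if rule.get("rule") not in _KNOWN_RULES:
                raise ValidationError(
                    f"evidence code {code!r} has unknown rule {rule.get('rule')!r}; "
                    f"known rules: {sorted(_KNOWN_RULES)}"
                )
        for cls, reqs in self.combining.items():
            for req in reqs:
                for code in req.get("codes", []):
                    if code not in self.evidence:
                        raise ValidationError(
                            f"combining table for {cls.value} references unknown "
                            f"evidence code {code!r}"
                        )
                for m in req.get("models", []) or []:
                    Model(m)  # raises ValueError on unknown model token


def load_acmg_config(path: str | Path | None = None) -> AcmgConfig:
    """Load an ACMG evidence configuration; ``None`` loads the shipped default."""
    if path is None:
        text = (
            resources.files("dytburden")
            .joinpath("data/acmg_default.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    try:
        combining = {
            AcmgClass(cls): list(reqs) for cls, reqs in raw["combining"].items()
        }
    except ValueError as e:
        raise ValidationError(f"unknown ACMG class in combining table: {e}") from None
    cfg = AcmgConfig(
        cadd_damaging_min=float(raw.get("cadd_damaging_min", 20.0)),
        evidence=dict(raw["evidence"]),
        combining=combining,
    )
    try:
        cfg.validate()
    except ValueError as e:
        raise ValidationError(str(e)) from None
    return cfg


def _assign_evidence(
    ann: VariantAnnotation, cohort: CohortData, cfg: AcmgConfig
) -> tuple[str, ...]:
    vc = classify(ann)
    codes = []
    for code, rule in cfg.evidence.items():
        kind = rule["rule"]
        if kind == "lof":
            allow = rule.get("gene_allowlist")
            if vc.is_lof and (allow is None or ann.gene in allow):
                codes.append(code)
        elif kind == "absent":
            if vc.effective_maf == 0.0:
                if ann.variant_id in cohort.variant_ids:
                    carried = (_control_dosages(cohort, ann.variant_id) >= 1).any()
                else:
                    carried = False
                if not carried:
                    codes.append(code)
        elif kind == "predictor_support":
            if predictor_support(ann, cfg.cadd_damaging_min) >= int(
                rule.get("min_support", 4)
            ):
                codes.append(code)
    return tuple(codes)


def _combine(codes: tuple[str, ...], model: Model, cfg: AcmgConfig) -> AcmgClass:
    have = set(codes)
    for cls in (AcmgClass.P, AcmgClass.LP):
        for req in cfg.combining.get(cls, []):
            models = req.get("models")
            if models is not None and model.value not in models:
                continue
            if set(req.get("codes", [])) <= have:
                return cls
    return AcmgClass.US


def acmg_classify(
    finding: CandidateFinding, cohort: CohortData, config: AcmgConfig | None = None
) -> AcmgClass:
    """Classify a finding with the reduced evidence engine.

    Evidence is assigned per variant and combined per the configured table;
    a multi-variant finding's class is its weakest per-variant class (both
    members of a putative compound heterozygote must support pathogenicity).
    Deterministic and independent of the order findings are processed in.
    """
    cfg = config if config is not None else load_acmg_config()
    per_variant: list[AcmgClass] = []
    evidence: list[tuple[str, ...]] = []
    for ann in finding.annotations:
        codes = _assign_evidence(ann, cohort, cfg)
        evidence.append(codes)
        per_variant.append(_combine(codes, finding.model, cfg))
    finding.acmg_per_variant = per_variant
    finding.evidence_per_variant = evidence
    finding.acmg = min(per_variant, key=lambda c: _CLASS_RANK[c])
    return finding.acmg


def classify_findings(
    findings: list[CandidateFinding],
    cohort: CohortData,
    config: AcmgConfig | None = None,
) -> list[CandidateFinding]:
    """ACMG-classify every retained (non-screened-out) finding in place."""
    cfg = config if config is not None else load_acmg_config()
    for f in findings:
        if not f.screened_out:
            acmg_classify(f, cohort, cfg)
    return findings
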