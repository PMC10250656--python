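"""Variant consequence classes, rarity flags, and burden-subgroup membership.

The classification scheme:

* **LoF** — stop gain/loss, frameshift, or a splicing change within two base
  pairs of an exon-intron junction.
* **Dmis** (damaging missense) — missense with an ensemble pathogenicity
  score (ReVe) of at least 0.7.
* **deleterious** — the union of LoF and Dmis.
* Rarity is judged on the *effective* population frequency: the maximum of
  the two East-Asian gnomAD frequencies carried by the annotation, with a
  variant absent from both sources treated as frequency 0 ("novel").
  Rarity comparisons are strict: ``MAF < 0.01`` and ``MAF < 0.001``.

The four burden variant subgroups (missense, Dmis, LoF, deleterious) crossed
with the two rarity thresholds give the eight cells a variant may enter; the
plain missense subgroup deliberately ignores the pathogenicity score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .exceptions import ValidationError
from .io import ExonicFunction, VariantAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "effective_maf",
    "is_lof",
    "is_dmis",
    "classify",
    "subgroup_membership",
    "SUBGROUP_CLASSES",
    "MAF_THRESHOLDS",
    "REVE_DAMAGING_MIN",
    "SPLICE_LOF_MAX_OFFSET",
]

REVE_DAMAGING_MIN = 0.7
SPLICE_LOF_MAX_OFFSET = 2
SUBGROUP_CLASSES = ("missense", "Dmis", "LoF", "deleterious")
MAF_THRESHOLDS = (0.01, 0.001)

_LOF_FUNCTIONS = {
    ExonicFunction.STOPGAIN,
    ExonicFunction.STOPLOSS,
    ExonicFunction.FRAMESHIFT,
}


@dataclass(frozen=True)
class VariantClass:
    is_missense: bool
    is_lof: bool
    is_dmis: bool
    is_deleterious: bool
    rare_001: bool
    rare_0001: bool
    effective_maf: float

    def __post_init__(self) -> None:
        if self.is_dmis and not self.is_missense:
            raise ValidationError("is_dmis implies is_missense")
        if self.is_deleterious != (self.is_dmis or self.is_lof):
            raise ValidationError("is_deleterious must equal is_dmis or is_lof")
        if self.rare_0001 and not self.rare_001:
            raise ValidationError("rare_0001 implies rare_001")


def effective_maf(ann: VariantAnnotation) -> float:
    """Combined East-Asian gnomAD frequency: max of the available sources, 0 if absent.

    Taking the maximum is the conservative rarity choice — a variant common
    in either frequency source is not considered rare.
    """
    freqs = [f for f in (ann.maf_exome_eas, ann.maf_genome_eas) if f is not None]
    return max(freqs) if freqs else 0.0


def is_lof(ann: VariantAnnotation) -> bool:
    """Loss-of-function: stop gain/loss, frameshift, or splicing within 2 bp."""
    if ann.exonic_function in _LOF_FUNCTIONS:
        return True
    if ann.exonic_function is ExonicFunction.SPLICING:
        if ann.splice_offset is None:
            raise ValidationError(
                f"{ann.variant_id}: splicing variant lacks splice_offset; "
                f"cannot evaluate the +/-2 bp junction rule"
            )
        return abs(ann.splice_offset) <= SPLICE_LOF_MAX_OFFSET
    return False


def is_dmis(ann: VariantAnnotation) -> bool:
    """Damaging missense: missense with ReVe >= 0.7 (inclusive threshold)."""
    if ann.exonic_function is not ExonicFunction.MISSENSE:
        return False
    if ann.reve is None:
        logger.warning(
            "%s: missense variant without ReVe score treated as non-damaging",
            ann.variant_id,
        )
        return False
    return ann.reve >= REVE_DAMAGING_MIN


def classify(ann: VariantAnnotation) -> VariantClass:
    """Populate all class and rarity flags for one annotated variant.

    Pure function of the annotation: identical annotations yield identical
    classifications.
    """
    maf = effective_maf(ann)
    missense = ann.exonic_function is ExonicFunction.MISSENSE
    lof = is_lof(ann)
    dmis = is_dmis(ann)
    return VariantClass(
        is_missense=missense,
        is_lof=lof,
        is_dmis=dmis,
        is_deleterious=dmis or lof,
        rare_001=maf < 0.01,
        rare_0001=maf < 0.001,
        effective_maf=maf,
    )


def subgroup_membership(vc: VariantClass) -> set[tuple[str, float]]:
    """The (class, MAF-threshold) burden cells the variant enters.

    A variant enters a cell iff it carries the class flag and is rare at the
    cell's threshold; cells at 0.001 are always a subset of the corresponding
    cells at 0.01.
    """
    flags = {
        "missense": vc.is_missense,
        "Dmis": vc.is_dmis,
        "LoF": vc.is_lof,
        "deleterious": vc.is_deleterious,
    }
    rare = {0.01: vc.rare_001, 0.001: vc.rare_0001}
    return {
        (cls, thr)
        for cls in SUBGROUP_CLASSES
        for thr in MAF_THRESHOLDS
        if flags[cls] and rare[thr]
    }
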