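"""Gene panel loading and validation.

A panel is an ordered list of gene symbols, each carrying the inheritance
mode under which candidate findings are sought: autosomal recessive (``AR``),
autosomal dominant (``AD``), or ``BOTH`` (the gene is screened under both
models independently).  The package ships a 47-gene dystonia panel as its
default resource; *GCH1* is deliberately absent from it because its
contribution to Parkinson's disease risk had been established separately
for the cohorts this analysis targets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from .exceptions import ValidationError

__all__ = ["Inheritance", "PanelGene", "GenePanel", "load_panel", "panel_summary"]


class Inheritance(str, enum.Enum):
    AR = "AR"
    AD = "AD"
    BOTH = "BOTH"

    @property
    def recessive(self) -> bool:
        """True if the gene is screened under the recessive (biallelic) model."""
        return self in (Inheritance.AR, Inheritance.BOTH)

    @property
    def dominant(self) -> bool:
        """True if the gene is screened under the dominant (heterozygous) model."""
        return self in (Inheritance.AD, Inheritance.BOTH)


@dataclass(frozen=True)
class PanelGene:
    """One panel member: an HGNC-style symbol plus its inheritance mode."""

    symbol: str
    inheritance: Inheritance
    chrom: str | None = None

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise ValidationError("panel gene symbol must be non-empty")
        if not isinstance(self.inheritance, Inheritance):
            raise ValidationError(
                f"inheritance for {self.symbol!r} must be an Inheritance enum"
            )


@dataclass
class GenePanel:
    """An ordered, duplicate-free collection of :class:`PanelGene`."""

    genes: list[PanelGene] = field(default_factory=list)
    name: str = "panel"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.symbol in seen:
                raise ValidationError(f"duplicate gene symbol in panel: {g.symbol!r}")
            seen.add(g.symbol)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return any(g.symbol == symbol for g in self.genes)

    def get(self, symbol: str) -> PanelGene | None:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        return None

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def recessive_genes(self) -> list[PanelGene]:
        return [g for g in self.genes if g.inheritance.recessive]

    def dominant_genes(self) -> list[PanelGene]:
        return [g for g in self.genes if g.inheritance.dominant]

    def with_genes(self, extra: Iterable[PanelGene]) -> "GenePanel":
        """Return a new panel extended with arbitrary additional genes."""
        return GenePanel(genes=list(self.genes) + list(extra), name=self.name)


def _parse_rows(rows: Iterable[tuple[str, str]], name: str) -> GenePanel:
    genes: list[PanelGene] = []
    seen: set[str] = set()
    for i, (symbol, token) in enumerate(rows, start=1):
        symbol = symbol.strip()
        token = token.strip().upper()
        if not symbol:
            raise ValidationError(f"row {i}: empty gene symbol")
        if symbol in seen:
            raise ValidationError(f"duplicate gene symbol in panel: {symbol!r}")
        seen.add(symbol)
        try:
            mode = Inheritance(token)
        except ValueError:
            raise ValidationError(
                f"row {i}: unknown inheritance token {token!r} "
                f"(expected AR, AD or BOTH)"
            ) from None
        genes.append(PanelGene(symbol=symbol, inheritance=mode))
    if not genes:
        raise ValidationError("panel definition is empty")
    return GenePanel(genes=genes, name=name)


def load_panel(
    source: Union[str, Path, Iterable[tuple[str, str]], None] = None,
) -> GenePanel:
    """Load a gene panel.

    Parameters
    ----------
    source
        Path to a two-column TSV with header ``symbol<TAB>inheritance``, or an
        iterable of ``(symbol, inheritance)`` pairs, or ``None`` for the
        shipped default dystonia panel (47 genes: 19 AR, 25 AD, 3 BOTH).

    Inheritance tokens are matched case-insensitively; symbols are trimmed but
    otherwise treated as opaque, case-sensitive join keys.
    """
    if source is None:
        ref = resources.files("dytburden").joinpath("data/dyt_panel.tsv")
        return _parse_panel_text(ref.read_text(encoding="utf-8"), name="dyt47")
    if isinstance(source, (str, Path)):
        path = Path(source)
        return _parse_panel_text(path.read_text(encoding="utf-8"), name=path.stem)
    return _parse_rows(source, name="inline")


def _parse_panel_text(text: str, name: str) -> GenePanel:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValidationError("panel file is empty")
    header = [c.strip().lower() for c in lines[0].split("\t")]
    if header[:2] != ["symbol", "inheritance"]:
        raise ValidationError(
            f"panel file must start with 'symbol\\tinheritance' header, got {lines[0]!r}"
        )
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"panel row has fewer than two columns: {ln!r}")
        rows.append((parts[0], parts[1]))
    if not rows:
        raise ValidationError("panel file contains a header but no genes")
    return _parse_rows(rows, name=name)


def panel_summary(panel: GenePanel) -> dict[str, int]:
    """Counts of panel members by inheritance mode; values sum to ``len(panel)``."""
    counts = {"AR": 0, "AD": 0, "BOTH": 0}
    for g in panel.genes:
        counts[g.inheritance.value] += 1
    return counts
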