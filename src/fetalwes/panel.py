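"""Virtual developmental-disorder gene panel.

Every filtering decision downstream is constrained by a curated gene panel
in which each gene carries an *allelic requirement* (the inheritance mode
under which variants in it cause disease) and a disease *mechanism*.  The
panel file format mirrors the tab-separated distribution style of curated
gene-to-phenotype resources (DDG2P and similar), without binding to any
particular release: one row per gene, with an optional pLI column holding
the probability that the gene is loss-of-function intolerant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional

__all__ = [
    "AllelicRequirement",
    "Mechanism",
    "PanelGene",
    "Panel",
    "PanelFormatError",
    "DuplicateGeneError",
    "read_panel",
    "write_panel",
]

#: chromosome labels treated as the X chromosome
_X_LABELS = frozenset({"X", "chrX"})

REQUIRED_COLUMNS = ("symbol", "allelic_requirement", "mechanism", "chromosome")


class AllelicRequirement(str, Enum):
    """Inheritance mode under which variants in a gene are disease-causing."""

    MONOALLELIC = "monoallelic"
    BIALLELIC = "biallelic"
    HEMIZYGOUS = "hemizygous"
    MONOALLELIC_AND_BIALLELIC = "monoallelic_and_biallelic"

    @property
    def matches_monoallelic(self) -> bool:
        return self in (
            AllelicRequirement.MONOALLELIC,
            AllelicRequirement.MONOALLELIC_AND_BIALLELIC,
        )

    @property
    def matches_biallelic(self) -> bool:
        return self in (
            AllelicRequirement.BIALLELIC,
            AllelicRequirement.MONOALLELIC_AND_BIALLELIC,
        )


class Mechanism(str, Enum):
    LOSS_OF_FUNCTION = "loss_of_function"
    ACTIVATING = "activating"
    DOMINANT_NEGATIVE = "dominant_negative"
    UNCERTAIN = "uncertain"


class PanelFormatError(ValueError):
    """Panel file is malformed (missing columns, bad enum value)."""


class DuplicateGeneError(ValueError):
    """The same gene symbol appears more than once in a panel."""


@dataclass(frozen=True)
class PanelGene:
    """One gene of the virtual panel.

    The mechanism is carried as metadata for reviewers; it does not take
    part in filtering.  ``pli`` is optional because constraint metrics are
    undefined for many genes.
    """

    symbol: str
    allelic_requirement: AllelicRequirement
    mechanism: Mechanism = Mechanism.UNCERTAIN
    chromosome: str = ""
    pli: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise ValueError("gene symbol must be non-empty")
        object.__setattr__(self, "symbol", self.symbol.strip())
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"pli must lie in [0, 1], got {self.pli!r}")
        if (
            self.allelic_requirement is AllelicRequirement.HEMIZYGOUS
            and self.chromosome not in _X_LABELS
        ):
            raise ValueError(
                f"hemizygous requirement on non-X chromosome "
                f"{self.chromosome!r} for gene {self.symbol}"
            )

    @property
    def is_x_linked(self) -> bool:
        return self.chromosome in _X_LABELS


@dataclass
class Panel:
    """A collection of :class:`PanelGene` keyed by symbol.

    Symbol lookup is case-sensitive after whitespace stripping; an absent
    symbol yields ``None``, never a default gene.
    """

    name: str = "panel"
    version: str = "0"
    _genes: dict[str, PanelGene] = field(default_factory=dict)

    def add(self, gene: PanelGene) -> None:
        if gene.symbol in self._genes:
            raise DuplicateGeneError(f"duplicate gene symbol {gene.symbol!r}")
        self._genes[gene.symbol] = gene

    def get(self, symbol: str) -> Optional[PanelGene]:
        return self._genes.get(symbol.strip())

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip() in self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[PanelGene]:
        return iter(self._genes.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return self._genes == other._genes

    @property
    def symbols(self) -> list[str]:
        return list(self._genes)


def read_panel(path: str | Path, name: str = "panel", version: str = "0") -> Panel:
    """Read a tab-separated panel file into a :class:`Panel`.

    The file must carry a header naming at least ``symbol``,
    ``allelic_requirement``, ``mechanism`` and ``chromosome``; a ``pli``
    column is optional (empty cells mean "no estimate").  Lines starting
    with ``#`` are ignored.
    """
    path = Path(path)
    panel = Panel(name=name, version=version)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = (line for line in fh if not line.startswith("#"))
        reader = csv.DictReader(rows, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise PanelFormatError(
                f"panel file {path} is missing required column(s): {missing}"
            )
        has_pli = "pli" in header
        for row in reader:
            pli_cell = (row.get("pli") or "").strip() if has_pli else ""
            try:
                gene = PanelGene(
                    symbol=row["symbol"],
                    allelic_requirement=AllelicRequirement(
                        row["allelic_requirement"].strip()
                    ),
                    mechanism=Mechanism(row["mechanism"].strip()),
                    chromosome=(row["chromosome"] or "").strip(),
                    pli=float(pli_cell) if pli_cell else None,
                )
            except KeyError as exc:  # a short row leaves cells as None
                raise PanelFormatError(f"short row in {path}: {row}") from exc
            panel.add(gene)
    return panel


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel in the same tab-separated format ``read_panel`` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("symbol\tallelic_requirement\tmechanism\tchromosome\tpli\n")
        for gene in panel:
            pli = "" if gene.pli is None else repr(gene.pli)
            fh.write(
                f"{gene.symbol}\t{gene.allelic_requirement.value}\t"
                f"{gene.mechanism.value}\t{gene.chromosome}\t{pli}\n"
            )
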