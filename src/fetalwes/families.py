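"""Pedigree and multi-sample variant ingestion.

A cohort is a set of fetus–parent families: *trios* (both parents
sequenced) or *dyads* (one parent).  Each fetus carries exactly one of the
eleven prenatal phenotype classes assigned from the ultrasound findings.
Variant records are read from a standard multi-sample VCF whose INFO field
carries the gene symbol (``GENE``), a sequence-ontology consequence term
(``CSQ_TERM``), a population allele frequency (``POP_AF``, absent when the
allele has never been observed) and, for pre-called copy-number or
uniparental-disomy events, a ``VARCLASS`` tag.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "PhenotypeClass",
    "PHENOTYPE_CLASSES",
    "FamilyUnit",
    "Genotype",
    "VariantClass",
    "AnnotatedVariant",
    "PedigreeError",
    "SampleMismatchError",
    "read_pedigree",
    "write_pedigree",
    "read_cohort_variants",
]

_X_LABELS = frozenset({"X", "chrX"})


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class PhenotypeClass(str, Enum):
    """The eleven ultrasound-based anomaly classes of the cohort."""

    ABDOMINAL = "abdominal"
    BRAIN = "brain"
    CARDIAC = "cardiac"
    THORACIC = "thoracic"
    FACIAL_CLEFT = "facial_cleft"
    HYDROPS = "hydrops"
    INCREASED_NT = "increased_NT"
    RENAL = "renal"
    SKELETAL = "skeletal"
    SPINAL = "spinal"
    MULTISYSTEM = "multisystem"


PHENOTYPE_CLASSES: tuple[PhenotypeClass, ...] = tuple(PhenotypeClass)


class PedigreeError(ValueError):
    """Structurally invalid pedigree (e.g. a fetus with no parent)."""


class SampleMismatchError(KeyError):
    """A pedigree sample is absent from the variant file."""


@dataclass(frozen=True)
class FamilyUnit:
    """One fetus plus its available sequenced parents."""

    family_id: str
    fetus_id: str
    phenotype_class: PhenotypeClass
    fetal_sex: Sex = Sex.UNKNOWN
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    mother_affected: bool = False
    father_affected: bool = False

    def __post_init__(self) -> None:
        if self.mother_id is None and self.father_id is None:
            raise PedigreeError(
                f"family {self.family_id}: fetus {self.fetus_id} has no "
                f"sequenced parent"
            )

    @property
    def is_trio(self) -> bool:
        return self.mother_id is not None and self.father_id is not None

    @property
    def members(self) -> tuple[str, ...]:
        out = [self.fetus_id]
        if self.mother_id is not None:
            out.append(self.mother_id)
        if self.father_id is not None:
            out.append(self.father_id)
        return tuple(out)


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT)


class VariantClass(str, Enum):
    SNV_INDEL = "snv_indel"
    CNV = "cnv"
    UPD = "upd"


@dataclass(frozen=True)
class AnnotatedVariant:
    """One (site, alt allele) with genotypes across one family.

    ``pop_af`` of ``None`` means the allele is unobserved in reference
    populations and is treated as frequency 0 by the filters.  Coordinates
    are 1-based; multi-allelic records are split per alt before reaching
    this type.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    genotypes: tuple[tuple[str, Genotype], ...]
    pop_af: Optional[float] = None
    variant_class: VariantClass = VariantClass.SNV_INDEL

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValueError(f"pop_af out of [0, 1]: {self.pop_af}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_x(self) -> bool:
        return self.chrom in _X_LABELS

    def genotype_of(self, sample: str) -> Genotype:
        for s, g in self.genotypes:
            if s == sample:
                return g
        return Genotype.MISSING

    @property
    def effective_af(self) -> float:
        """Population frequency used by the filters (absent -> 0)."""
        return 0.0 if self.pop_af is None else self.pop_af


# ---------------------------------------------------------------------------
# pedigree I/O
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> list[FamilyUnit]:
    """Read a 6-column PED file extended with a 7th phenotype-class column.

    Columns: family, individual, father, mother, sex (1=male, 2=female,
    0=unknown), affected status (2=affected, 1=unaffected) and, on the
    fetus row, the phenotype class label.  The fetus is the affected
    individual whose parent columns are non-zero; parental affected status
    is taken from the parents' own rows.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise PedigreeError(f"pedigree row with <6 columns: {line!r}")
            rows.append(parts)

    by_family: dict[str, list[list[str]]] = defaultdict(list)
    for parts in rows:
        by_family[parts[0]].append(parts)

    sex_map = {"1": Sex.MALE, "2": Sex.FEMALE}
    families: list[FamilyUnit] = []
    for fam_id, fam_rows in by_family.items():
        present = {r[1] for r in fam_rows}
        affected_by_id = {r[1]: r[5] == "2" for r in fam_rows}
        children = [r for r in fam_rows if r[2] != "0" or r[3] != "0"]
        if not children:
            raise PedigreeError(f"family {fam_id}: no fetus row (no parent links)")
        if len(children) > 1:
            raise PedigreeError(
                f"family {fam_id}: multiple fetus rows; model multi-fetus "
                f"pregnancies as separate families"
            )
        child = children[0]
        father_id = child[2] if child[2] != "0" and child[2] in present else None
        mother_id = child[3] if child[3] != "0" and child[3] in present else None
        if father_id is None and mother_id is None:
            raise PedigreeError(
                f"family {fam_id}: fetus {child[1]} has no sequenced parent"
            )
        if len(child) < 7:
            raise PedigreeError(
                f"family {fam_id}: fetus row lacks the phenotype_class column"
            )
        try:
            pclass = PhenotypeClass(child[6])
        except ValueError as exc:
            raise ValueError(
                f"family {fam_id}: unknown phenotype class {child[6]!r}"
            ) from exc
        families.append(
            FamilyUnit(
                family_id=fam_id,
                fetus_id=child[1],
                phenotype_class=pclass,
                fetal_sex=sex_map.get(child[4], Sex.UNKNOWN),
                mother_id=mother_id,
                father_id=father_id,
                mother_affected=affected_by_id.get(mother_id or "", False),
                father_affected=affected_by_id.get(father_id or "", False),
            )
        )
    return families


def write_pedigree(families: list[FamilyUnit], path: str | Path) -> None:
    """Write families back to the extended PED format (fetus row last)."""
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    with Path(path).open("w", encoding="utf-8") as fh:
        for fam in families:
            if fam.father_id is not None:
                aff = "2" if fam.father_affected else "1"
                fh.write(f"{fam.family_id}\t{fam.father_id}\t0\t0\t1\t{aff}\n")
            if fam.mother_id is not None:
                aff = "2" if fam.mother_affected else "1"
                fh.write(f"{fam.family_id}\t{fam.mother_id}\t0\t0\t2\t{aff}\n")
            fh.write(
                f"{fam.family_id}\t{fam.fetus_id}\t{fam.father_id or 0}\t"
                f"{fam.mother_id or 0}\t{sex_code[fam.fetal_sex]}\t2\t"
                f"{fam.phenotype_class.value}\n"
            )


# ---------------------------------------------------------------------------
# variant I/O
# ---------------------------------------------------------------------------

def _allele_counts(raw_gt: list[int], alt_index: int) -> tuple[int, int]:
    """(#alleles equal to alt_index, #called alleles) for one sample.

    cyvcf2 genotype entries end with a phasing flag; ``-1`` marks an
    uncalled allele.  Any uncalled allele makes the genotype missing.
    """
    alleles = raw_gt[:-1]
    called = [a for a in alleles if a >= 0]
    if len(called) < len(alleles):
        return (0, 0)
    return (sum(a == alt_index for a in called), len(called))


def _classify_genotype(
    n_alt: int, n_called: int, *, male_x: bool
) -> Genotype:
    if n_called == 0:
        return Genotype.MISSING
    if male_x:
        # male X outside the pseudo-autosomal regions is single-copy:
        # any alt call, diploid-coded or haploid, is hemizygous-alt
        return Genotype.HEMI_ALT if n_alt > 0 else Genotype.HOM_REF
    if n_called == 1:
        return Genotype.HOM_ALT if n_alt == 1 else Genotype.HOM_REF
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == n_called:
        return Genotype.HOM_ALT
    return Genotype.HET


def read_cohort_variants(
    path: str | Path,
    families: list[FamilyUnit],
    warning_counter: Optional[dict[str, int]] = None,
) -> dict[str, list[AnnotatedVariant]]:
    """Read a multi-sample VCF into per-family annotated variants.

    Multi-allelic records are split into one variant per alt allele.  A
    variant enters a family's list only if at least one family member
    carries the alt; sites at which every member is homozygous reference
    (or missing) are dropped for that family.  Male genotypes on the X
    are normalised to hemizygous calls.
    """
    vcf = VCF(str(path))
    sample_index = {s: i for i, s in enumerate(vcf.samples)}
    counters = warning_counter if warning_counter is not None else {}
    counters.setdefault("malformed_genotype", 0)

    male_samples: set[str] = set()
    for fam in families:
        for member in fam.members:
            if member not in sample_index:
                raise SampleMismatchError(
                    f"sample {member!r} (family {fam.family_id}) missing from "
                    f"variant file {path}"
                )
        if fam.fetal_sex is Sex.MALE:
            male_samples.add(fam.fetus_id)
        if fam.father_id is not None:
            male_samples.add(fam.father_id)

    out: dict[str, list[AnnotatedVariant]] = {f.family_id: [] for f in families}
    member_idx = [
        (fam, [(m, sample_index[m], m in male_samples) for m in fam.members])
        for fam in families
    ]

    for record in vcf:
        gene = record.INFO.get("GENE") or ""
        csq = record.INFO.get("CSQ_TERM") or ""
        pop_af = record.INFO.get("POP_AF")
        varclass = VariantClass(record.INFO.get("VARCLASS") or "snv_indel")
        raw = record.genotypes
        on_x = record.CHROM in _X_LABELS
        for alt_i, alt in enumerate(record.ALT, start=1):
            if isinstance(pop_af, (tuple, list)):
                af = pop_af[alt_i - 1]  # Number=A annotation
            else:
                af = pop_af
            for fam, members in member_idx:
                gts: list[tuple[str, Genotype]] = []
                any_alt = False
                for name, idx, is_male in members:
                    try:
                        n_alt, n_called = _allele_counts(raw[idx], alt_i)
                    except (IndexError, TypeError):
                        counters["malformed_genotype"] += 1
                        logger.warning(
                            "malformed genotype for %s at %s:%s", name,
                            record.CHROM, record.POS,
                        )
                        n_alt, n_called = 0, 0
                    g = _classify_genotype(
                        n_alt, n_called, male_x=on_x and is_male
                    )
                    gts.append((name, g))
                    any_alt = any_alt or g.carries_alt
                if not any_alt:
                    continue
                out[fam.family_id].append(
                    AnnotatedVariant(
                        chrom=record.CHROM,
                        pos=record.POS,
                        ref=record.REF,
                        alt=alt,
                        gene=gene,
                        consequence=csq,
                        genotypes=tuple(gts),
                        pop_af=float(af) if af is not None else None,
                        variant_class=varclass,
                    )
                )
    return out
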