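"""Inheritance-aware variant prioritisation.

This is the analytical core of the package: from the annotated variants of
one family, select rare, protein-altering variants whose inheritance
pattern matches the allelic requirement of the panel gene they fall in,
and assemble them into *potential diagnoses* — the unit a clinical review
panel assesses.  Trio genotypes identify de novo variants directly and
phase heterozygous pairs in recessive genes into cis (same parental
haplotype, discarded) or trans (compound heterozygous, retained).

Two deliberate asymmetries of the procedure:

* an inherited heterozygous variant in a dominant (monoallelic) gene is
  discarded when the transmitting parent is unaffected — unless it matches
  a *whitelist* of known-pathogenic or predicted-truncating variants.
  Incomplete parental phenotype information (or incomplete penetrance)
  otherwise silently removes true diagnoses such as inherited
  Noonan-spectrum variants;
* pre-called copy-number and uniparental-disomy events bypass the gene
  panel and consequence filters entirely: they are reviewed as events,
  not as sequence variants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .families import (
    AnnotatedVariant,
    FamilyUnit,
    Genotype,
    VariantClass,
)
from .panel import AllelicRequirement, Panel

__all__ = [
    "DEFAULT_PROTEIN_ALTERING_TERMS",
    "DEFAULT_TRUNCATING_TERMS",
    "FilterConfig",
    "InheritanceCall",
    "DiagnosisModel",
    "PotentialDiagnosis",
    "Whitelist",
    "read_whitelist",
    "is_protein_altering",
    "passes_frequency",
    "call_inheritance",
    "find_compound_hets",
    "whitelist_rescue",
    "prioritise_family",
    "prioritise_cohort",
]

DEFAULT_PROTEIN_ALTERING_TERMS = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "protein_altering_variant",
    }
)

DEFAULT_TRUNCATING_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "start_lost",
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds of the bioinformatic filter.

    Frequency ceilings follow standard rare-disease practice: dominant and
    X-linked candidate alleles must be essentially absent from reference
    populations (default 0.1%), while recessive carrier alleles may
    segregate at somewhat higher frequency (default 0.5%).
    """

    protein_altering_terms: frozenset[str] = DEFAULT_PROTEIN_ALTERING_TERMS
    truncating_terms: frozenset[str] = DEFAULT_TRUNCATING_TERMS
    max_af_monoallelic: float = 0.001
    max_af_biallelic: float = 0.005
    dyad_presume_denovo: bool = True

    def __post_init__(self) -> None:
        if not self.truncating_terms <= self.protein_altering_terms:
            raise ValueError("truncating_terms must be a subset of protein_altering_terms")
        if not (0.0 <= self.max_af_monoallelic <= self.max_af_biallelic <= 1.0):
            raise ValueError(
                "require 0 <= max_af_monoallelic <= max_af_biallelic <= 1"
            )


class InheritanceCall(str, Enum):
    DE_NOVO = "de_novo"
    DE_NOVO_PRESUMED = "de_novo_presumed"
    INHERITED_MATERNAL = "inherited_maternal"
    INHERITED_PATERNAL = "inherited_paternal"
    BIALLELIC_HOMOZYGOUS = "biallelic_homozygous"
    HEMIZYGOUS_MATERNAL = "hemizygous_maternal"
    MENDELIAN_INCONSISTENT = "mendelian_inconsistent"
    UNINFORMATIVE = "uninformative"

    @property
    def is_de_novo(self) -> bool:
        return self in (InheritanceCall.DE_NOVO, InheritanceCall.DE_NOVO_PRESUMED)

    @property
    def is_inherited(self) -> bool:
        return self in (
            InheritanceCall.INHERITED_MATERNAL,
            InheritanceCall.INHERITED_PATERNAL,
            InheritanceCall.BIALLELIC_HOMOZYGOUS,
            InheritanceCall.HEMIZYGOUS_MATERNAL,
        )


class DiagnosisModel(str, Enum):
    MONOALLELIC_DE_NOVO = "monoallelic_de_novo"
    MONOALLELIC_INHERITED = "monoallelic_inherited"
    BIALLELIC_HOMOZYGOUS = "biallelic_homozygous"
    BIALLELIC_COMPOUND_HET = "biallelic_compound_het"
    X_LINKED_HEMIZYGOUS = "x_linked_hemizygous"
    CNV_EVENT = "cnv_event"
    UPD_EVENT = "upd_event"


@dataclass(frozen=True)
class PotentialDiagnosis:
    """One or two variants in one gene in one fetus, as reviewed by a CRP.

    A compound-heterozygous pair is a single potential diagnosis carrying
    two variants of opposite parental origin; every other model carries
    exactly one variant.
    """

    family_id: str
    gene: str
    model: DiagnosisModel
    variants: tuple[tuple[AnnotatedVariant, InheritanceCall], ...]
    rescued_by_whitelist: bool = False

    def __post_init__(self) -> None:
        n = len(self.variants)
        if self.model is DiagnosisModel.BIALLELIC_COMPOUND_HET:
            if n != 2:
                raise ValueError("compound-het diagnosis needs exactly 2 variants")
        elif n != 1:
            raise ValueError(f"model {self.model.value} needs exactly 1 variant, got {n}")
        for _, call in self.variants:
            if call is InheritanceCall.MENDELIAN_INCONSISTENT:
                raise ValueError("mendelian-inconsistent variant in a diagnosis")

    @property
    def diagnosis_id(self) -> str:
        positions = "-".join(str(v.pos) for v, _ in self.variants)
        return f"{self.family_id}:{self.gene or 'NA'}:{self.model.value}:{positions}"

    @property
    def is_de_novo(self) -> bool:
        """De novo in the recurrence-risk sense (includes de novo CNVs)."""
        return all(call.is_de_novo for _, call in self.variants)

    @property
    def sort_key(self) -> tuple:
        v = self.variants[0][0]
        return (self.family_id, self.gene, v.chrom, v.pos, v.alt, self.model.value)


@dataclass
class Whitelist:
    """Known-pathogenic variant whitelist.

    Entries are either an exact site key (chrom, pos, ref, alt) or a
    gene-level rule ``any_truncating`` matching every truncating
    consequence in that gene.
    """

    exact: set[tuple[str, int, str, str]] = field(default_factory=set)
    truncating_genes: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.exact) + len(self.truncating_genes)


def read_whitelist(path: str | Path) -> Whitelist:
    """Read a tab-separated whitelist: ``chrom pos ref alt`` or ``gene any_truncating``."""
    wl = Whitelist()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2 and parts[1] == "any_truncating":
                wl.truncating_genes.add(parts[0])
            elif len(parts) == 4:
                wl.exact.add((parts[0], int(parts[1]), parts[2], parts[3]))
            else:
                raise ValueError(f"unrecognised whitelist row: {line!r}")
    return wl


# ---------------------------------------------------------------------------
# elementary filters
# ---------------------------------------------------------------------------

def is_protein_altering(consequence: str, cfg: FilterConfig) -> bool:
    """Whether a consequence term counts as protein-altering; unknown terms do not."""
    return consequence in cfg.protein_altering_terms


def passes_frequency(
    variant: AnnotatedVariant, model: DiagnosisModel, cfg: FilterConfig
) -> bool:
    """Population-frequency ceiling under the assembled diagnosis model.

    Monoallelic and X-linked models use the stringent (dominant) ceiling,
    biallelic models the recessive one.  Pre-called CNV/UPD events are not
    frequency-filtered.
    """
    if model in (DiagnosisModel.CNV_EVENT, DiagnosisModel.UPD_EVENT):
        return True
    if model in (
        DiagnosisModel.BIALLELIC_HOMOZYGOUS,
        DiagnosisModel.BIALLELIC_COMPOUND_HET,
    ):
        return variant.effective_af <= cfg.max_af_biallelic
    return variant.effective_af <= cfg.max_af_monoallelic


# ---------------------------------------------------------------------------
# inheritance calling
# ---------------------------------------------------------------------------

def _carries(g: Optional[Genotype]) -> bool:
    return g is not None and g.carries_alt


def _has_ref(g: Genotype) -> bool:
    return g in (Genotype.HOM_REF, Genotype.HET)


def call_inheritance(variant: AnnotatedVariant, family: FamilyUnit,
                     cfg: Optional[FilterConfig] = None) -> InheritanceCall:
    """Classify the transmission of one variant within one family.

    Trio logic is exhaustive over fetal/maternal/paternal genotypes; a
    parent with a missing genotype is handled like an absent parent.  In
    dyads, a fetal heterozygote not carried by the available parent is
    presumed de novo when ``cfg.dyad_presume_denovo`` is set, and
    uninformative otherwise (the unsequenced parent could have transmitted
    it).
    """
    cfg = cfg or FilterConfig()
    gf = variant.genotype_of(family.fetus_id)
    if gf in (Genotype.MISSING, Genotype.HOM_REF):
        return InheritanceCall.UNINFORMATIVE

    gm = variant.genotype_of(family.mother_id) if family.mother_id else None
    gp = variant.genotype_of(family.father_id) if family.father_id else None
    if gm is Genotype.MISSING:
        gm = None
    if gp is Genotype.MISSING:
        gp = None

    if gf is Genotype.HEMI_ALT:
        # male X: the maternally transmitted X is the only informative one
        if gm is None:
            return (
                InheritanceCall.DE_NOVO_PRESUMED
                if cfg.dyad_presume_denovo
                else InheritanceCall.UNINFORMATIVE
            )
        if gm is Genotype.HOM_REF:
            return InheritanceCall.DE_NOVO
        return InheritanceCall.HEMIZYGOUS_MATERNAL

    if gf is Genotype.HOM_ALT:
        if gm is Genotype.HOM_REF or gp is Genotype.HOM_REF:
            return InheritanceCall.MENDELIAN_INCONSISTENT
        if _carries(gm) and _carries(gp):
            return InheritanceCall.BIALLELIC_HOMOZYGOUS
        return InheritanceCall.UNINFORMATIVE

    # gf is HET
    if gm is not None and gp is not None:
        if gm is Genotype.HOM_ALT and gp is Genotype.HOM_ALT:
            # both parents must transmit the alt -> fetus cannot be het
            return InheritanceCall.MENDELIAN_INCONSISTENT
        maternal = _carries(gm) and _has_ref(gp)
        paternal = _carries(gp) and _has_ref(gm)
        if maternal and paternal:
            return InheritanceCall.UNINFORMATIVE  # origin ambiguous
        if maternal:
            return InheritanceCall.INHERITED_MATERNAL
        if paternal:
            return InheritanceCall.INHERITED_PATERNAL
        return InheritanceCall.DE_NOVO
    available = gm if gm is not None else gp
    if available is None:
        return InheritanceCall.UNINFORMATIVE
    if _carries(available):
        return (
            InheritanceCall.INHERITED_MATERNAL
            if available is gm
            else InheritanceCall.INHERITED_PATERNAL
        )
    return (
        InheritanceCall.DE_NOVO_PRESUMED
        if cfg.dyad_presume_denovo
        else InheritanceCall.UNINFORMATIVE
    )


def find_compound_hets(
    het_variants_in_gene: Sequence[tuple[AnnotatedVariant, InheritanceCall]],
    family: FamilyUnit,
    cfg: Optional[FilterConfig] = None,
) -> list[tuple[tuple[AnnotatedVariant, InheritanceCall], tuple[AnnotatedVariant, InheritanceCall]]]:
    """Return all trans pairs among the fetus's heterozygous calls in one gene.

    A trans pair combines one maternally and one paternally inherited
    heterozygote; cis pairs (same parental origin) are excluded.  In dyads
    with de-novo presumption enabled, one inherited-from-available-parent
    variant may pair with one presumed-de-novo variant (not carried by the
    available parent).
    """
    cfg = cfg or FilterConfig()
    maternal = [vc for vc in het_variants_in_gene if vc[1] is InheritanceCall.INHERITED_MATERNAL]
    paternal = [vc for vc in het_variants_in_gene if vc[1] is InheritanceCall.INHERITED_PATERNAL]
    pairs = [(m, p) for m in maternal for p in paternal]
    if not family.is_trio and cfg.dyad_presume_denovo:
        inherited = maternal + paternal
        presumed = [
            vc for vc in het_variants_in_gene
            if vc[1] is InheritanceCall.DE_NOVO_PRESUMED
        ]
        pairs.extend((i, d) for i in inherited for d in presumed)
    return pairs


def whitelist_rescue(
    variant: AnnotatedVariant,
    panel: Panel,
    whitelist: Optional[Whitelist],
    cfg: Optional[FilterConfig] = None,
) -> bool:
    """Whether a variant matches the known-pathogenic whitelist.

    True on an exact site match, or under a gene-level ``any_truncating``
    rule when the consequence is truncating and the gene is on the panel.
    """
    if whitelist is None:
        return False
    cfg = cfg or FilterConfig()
    if variant.key in whitelist.exact:
        return True
    return (
        variant.gene in whitelist.truncating_genes
        and variant.consequence in cfg.truncating_terms
        and variant.gene in panel
    )


# ---------------------------------------------------------------------------
# per-family prioritisation
# ---------------------------------------------------------------------------

def _transmitting_parent_affected(
    call: InheritanceCall, family: FamilyUnit
) -> bool:
    if call is InheritanceCall.INHERITED_MATERNAL:
        return family.mother_affected
    if call is InheritanceCall.INHERITED_PATERNAL:
        return family.father_affected
    return False


def prioritise_family(
    variants: Iterable[AnnotatedVariant],
    family: FamilyUnit,
    panel: Panel,
    whitelist: Optional[Whitelist] = None,
    cfg: Optional[FilterConfig] = None,
    counters: Optional[dict[str, int]] = None,
) -> list[PotentialDiagnosis]:
    """Run the full per-family filter and assemble potential diagnoses.

    Stages: panel-gene restriction (CNV/UPD events bypass), consequence
    filter, per-variant inheritance call, allelic-requirement matching
    (including compound-het trans phasing and the whitelist rescue of
    inherited variants in dominant genes), then the model-specific
    frequency filter.  ``counters``, if given, accumulates per-stage
    exclusion counts.  Output order is deterministic: by family, gene,
    chromosome, position, alt.
    """
    cfg = cfg or FilterConfig()
    c = counters if counters is not None else {}
    for key in (
        "input", "event_records", "non_panel_gene", "non_protein_altering",
        "mendelian_inconsistent", "uninformative", "unaffected_parent_dropped",
        "whitelist_rescued", "frequency_failed", "model_unmatched",
        "gene_stage_variants", "diagnoses", "variants_emitted",
    ):
        c.setdefault(key, 0)

    out: list[PotentialDiagnosis] = []
    by_gene: dict[str, list[tuple[AnnotatedVariant, InheritanceCall]]] = {}

    for v in variants:
        c["input"] += 1
        if v.variant_class is not VariantClass.SNV_INDEL:
            c["event_records"] += 1
            call = call_inheritance(v, family, cfg)
            if call is InheritanceCall.MENDELIAN_INCONSISTENT:
                c["mendelian_inconsistent"] += 1
                continue
            model = (
                DiagnosisModel.CNV_EVENT
                if v.variant_class is VariantClass.CNV
                else DiagnosisModel.UPD_EVENT
            )
            out.append(
                PotentialDiagnosis(
                    family_id=family.family_id, gene=v.gene, model=model,
                    variants=((v, call),),
                )
            )
            continue
        if v.gene not in panel:
            c["non_panel_gene"] += 1
            continue
        if not is_protein_altering(v.consequence, cfg):
            c["non_protein_altering"] += 1
            continue
        call = call_inheritance(v, family, cfg)
        if call is InheritanceCall.MENDELIAN_INCONSISTENT:
            c["mendelian_inconsistent"] += 1
            continue
        if call is InheritanceCall.UNINFORMATIVE:
            c["uninformative"] += 1
            continue
        by_gene.setdefault(v.gene, []).append((v, call))
        c["gene_stage_variants"] += 1

    for gene, calls in by_gene.items():
        pg = panel.get(gene)
        assert pg is not None
        req = pg.allelic_requirement
        compound_pool: list[tuple[AnnotatedVariant, InheritanceCall]] = []
        for v, call in calls:
            fetal_gt = v.genotype_of(family.fetus_id)
            if fetal_gt is Genotype.HEMI_ALT:
                if req is AllelicRequirement.HEMIZYGOUS:
                    d = PotentialDiagnosis(
                        family_id=family.family_id, gene=gene,
                        model=DiagnosisModel.X_LINKED_HEMIZYGOUS,
                        variants=((v, call),),
                    )
                    _emit_if_rare(d, cfg, out, c)
                elif call.is_de_novo and req.matches_monoallelic:
                    d = PotentialDiagnosis(
                        family_id=family.family_id, gene=gene,
                        model=DiagnosisModel.MONOALLELIC_DE_NOVO,
                        variants=((v, call),),
                    )
                    _emit_if_rare(d, cfg, out, c)
                else:
                    c["model_unmatched"] += 1
                continue
            if call is InheritanceCall.BIALLELIC_HOMOZYGOUS:
                if req.matches_biallelic:
                    d = PotentialDiagnosis(
                        family_id=family.family_id, gene=gene,
                        model=DiagnosisModel.BIALLELIC_HOMOZYGOUS,
                        variants=((v, call),),
                    )
                    _emit_if_rare(d, cfg, out, c)
                else:
                    c["model_unmatched"] += 1
                continue
            if call.is_de_novo:
                matched = False
                if req.matches_monoallelic:
                    d = PotentialDiagnosis(
                        family_id=family.family_id, gene=gene,
                        model=DiagnosisModel.MONOALLELIC_DE_NOVO,
                        variants=((v, call),),
                    )
                    _emit_if_rare(d, cfg, out, c)
                    matched = True
                if req.matches_biallelic and not family.is_trio:
                    # dyad presumed-de-novo hets may complete a trans pair
                    compound_pool.append((v, call))
                    matched = True
                if not matched:
                    c["model_unmatched"] += 1
                continue
            # inherited heterozygote
            matched = False
            if req.matches_monoallelic:
                rescued = whitelist_rescue(v, panel, whitelist, cfg)
                if _transmitting_parent_affected(call, family) or rescued:
                    d = PotentialDiagnosis(
                        family_id=family.family_id, gene=gene,
                        model=DiagnosisModel.MONOALLELIC_INHERITED,
                        variants=((v, call),),
                        rescued_by_whitelist=rescued
                        and not _transmitting_parent_affected(call, family),
                    )
                    if _emit_if_rare(d, cfg, out, c) and d.rescued_by_whitelist:
                        c["whitelist_rescued"] += 1
                    matched = True
                else:
                    c["unaffected_parent_dropped"] += 1
            if req.matches_biallelic:
                compound_pool.append((v, call))
                matched = True
            if not matched and not req.matches_biallelic:
                pass  # already counted as dropped above

        if compound_pool:
            # compound-het candidates must individually pass the recessive
            # frequency ceiling before trans pairing
            rare_pool = [
                vc for vc in compound_pool
                if passes_frequency(vc[0], DiagnosisModel.BIALLELIC_COMPOUND_HET, cfg)
            ]
            c["frequency_failed"] += len(compound_pool) - len(rare_pool)
            for m, p in find_compound_hets(rare_pool, family, cfg):
                first, second = sorted((m, p), key=lambda vc: (vc[0].pos, vc[0].alt))
                d = PotentialDiagnosis(
                    family_id=family.family_id, gene=gene,
                    model=DiagnosisModel.BIALLELIC_COMPOUND_HET,
                    variants=(first, second),
                )
                out.append(d)
                c["diagnoses"] += 1
                c["variants_emitted"] += 2

    out.sort(key=lambda d: d.sort_key)
    return out


def _emit_if_rare(
    d: PotentialDiagnosis,
    cfg: FilterConfig,
    out: list[PotentialDiagnosis],
    counters: dict[str, int],
) -> bool:
    v = d.variants[0][0]
    if not passes_frequency(v, d.model, cfg):
        counters["frequency_failed"] += 1
        return False
    out.append(d)
    counters["diagnoses"] += 1
    counters["variants_emitted"] += 1
    return True


def prioritise_cohort(
    variants_by_family: dict[str, list[AnnotatedVariant]],
    families: list[FamilyUnit],
    panel: Panel,
    whitelist: Optional[Whitelist] = None,
    cfg: Optional[FilterConfig] = None,
    counters: Optional[dict[str, int]] = None,
) -> list[PotentialDiagnosis]:
    """Prioritise every family; concatenated, deterministically ordered."""
    out: list[PotentialDiagnosis] = []
    for fam in sorted(families, key=lambda f: f.family_id):
        out.extend(
            prioritise_family(
                variants_by_family.get(fam.family_id, []),
                fam, panel, whitelist, cfg, counters,
            )
        )
    return out


def write_candidate_table(
    diagnoses: Sequence[PotentialDiagnosis], path: str | Path
) -> None:
    """One row per variant; compound-het pairs share a diagnosis id."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "diagnosis_id", "family_id", "gene", "model", "chrom", "pos",
                "ref", "alt", "consequence", "pop_af", "inheritance",
                "rescued_by_whitelist",
            ]
        )
        for d in diagnoses:
            for v, call in d.variants:
                w.writerow(
                    [
                        d.diagnosis_id, d.family_id, d.gene or "NA",
                        d.model.value, v.chrom, v.pos, v.ref, v.alt,
                        v.consequence,
                        "" if v.pop_af is None else repr(v.pop_af),
                        call.value, str(d.rescued_by_whitelist).lower(),
                    ]
                )
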