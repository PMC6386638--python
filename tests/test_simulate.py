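from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pytest

from fetalwes.families import (
    AnnotatedVariant,
    FamilyUnit,
    Genotype,
    PhenotypeClass,
    Sex,
    VariantClass,
    read_cohort_variants,
    read_pedigree,
)
from fetalwes.panel import read_panel
from fetalwes.prioritise import InheritanceCall, call_inheritance, prioritise_cohort
from fetalwes.simulate import (
    DEFAULT_CLASS_SIZES,
    Manifest,
    SimulationConfig,
    _PositionAllocator,
    simulate_cohort,
    spike_variant,
)

from .conftest import scaled_config


def _file_hashes(paths: dict[str, Path]) -> dict[str, str]:
    return {k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()}


def test_same_seed_gives_byte_identical_files(tmp_path):
    cfg = scaled_config(seed=42)
    h1 = _file_hashes(simulate_cohort(cfg, tmp_path / "a")[0])
    h2 = _file_hashes(simulate_cohort(scaled_config(seed=42), tmp_path / "b")[0])
    assert h1 == h2
    h3 = _file_hashes(simulate_cohort(scaled_config(seed=43), tmp_path / "c")[0])
    assert h1 != h3


def test_default_config_reproduces_cohort_structure(tmp_path):
    cfg = SimulationConfig(seed=5, spikes={}, n_background_sites=1)
    paths, manifest = simulate_cohort(cfg, tmp_path)
    assert manifest.n_families == 610
    assert manifest.n_trios == 596 and manifest.n_dyads == 14
    fams = read_pedigree(paths["pedigree"])
    by_class: dict[str, int] = {}
    for f in fams:
        by_class[f.phenotype_class.value] = by_class.get(f.phenotype_class.value, 0) + 1
    assert by_class == DEFAULT_CLASS_SIZES


def test_zero_class_sizes_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(class_sizes={"cardiac": 0})


def test_manifest_json_round_trip(small_cohort):
    paths, manifest = small_cohort
    back = Manifest.from_json(paths["manifest"])
    assert back.expected_ids() == manifest.expected_ids()
    assert back.n_families == manifest.n_families


def test_spiked_variants_present_in_reread_cohort(small_cohort):
    paths, manifest = small_cohort
    fams = read_pedigree(paths["pedigree"])
    variants = read_cohort_variants(paths["vcf"], fams)
    for spike in manifest.spikes:
        keys = {tuple(k) for k in spike.variant_keys}
        fam_keys = {(v.chrom, v.pos, v.ref, v.alt) for v in variants[spike.family_id]}
        assert keys <= fam_keys


def test_no_spikes_and_common_background_yield_nothing(tmp_path):
    cfg = scaled_config(
        seed=9, spikes={}, background_common_weight=1.0, background_common_af=0.2
    )
    paths, _ = simulate_cohort(cfg, tmp_path)
    panel = read_panel(paths["panel"])
    fams = read_pedigree(paths["pedigree"])
    variants = read_cohort_variants(paths["vcf"], fams)
    assert prioritise_cohort(variants, fams, panel) == []


def test_background_is_never_mendelian_inconsistent(small_cohort):
    paths, _ = small_cohort
    panel = read_panel(paths["panel"])
    fams = read_pedigree(paths["pedigree"])
    variants = read_cohort_variants(paths["vcf"], fams)
    counters: dict[str, int] = {}
    prioritise_cohort(variants, fams, panel, counters=counters)
    assert counters["mendelian_inconsistent"] == 0


# ---------------------------------------------------------------------------
# spike round-trip property
# ---------------------------------------------------------------------------

_GT_MAP = {"0/0": Genotype.HOM_REF, "0/1": Genotype.HET, "0": Genotype.HOM_REF}

INTENDED_CALL = {
    "monoallelic_de_novo": InheritanceCall.DE_NOVO,
    "x_linked_hemizygous": InheritanceCall.DE_NOVO,
    "biallelic_homozygous": InheritanceCall.BIALLELIC_HOMOZYGOUS,
    "monoallelic_inherited_affected": InheritanceCall.INHERITED_MATERNAL,
    "monoallelic_inherited_whitelisted": InheritanceCall.INHERITED_MATERNAL,
    "cnv_event": InheritanceCall.DE_NOVO,
    "upd_event": InheritanceCall.DE_NOVO,
}


def _site_to_variant(site, family: FamilyUnit) -> AnnotatedVariant:
    males = {family.fetus_id} if family.fetal_sex is Sex.MALE else set()
    if family.father_id:
        males.add(family.father_id)
    gts = []
    for member in family.members:
        raw = site.genotypes.get(member, "0" if site.chrom == "X" and member in males else "0/0")
        if raw in _GT_MAP:
            g = _GT_MAP[raw]
        elif raw in ("1", "1/1"):
            g = (
                Genotype.HEMI_ALT
                if site.chrom == "X" and member in males
                else Genotype.HOM_ALT
            )
        else:
            raise AssertionError(raw)
        gts.append((member, g))
    return AnnotatedVariant(
        chrom=site.chrom, pos=site.pos, ref=site.ref, alt=site.alt,
        gene=site.gene, consequence=site.consequence, genotypes=tuple(gts),
        pop_af=site.pop_af, variant_class=VariantClass(site.varclass),
    )


def test_thousand_spikes_round_trip_through_inheritance_calling():
    """Across 1000 random spikes the constructed genotypes always produce
    the intended inheritance call."""
    from fetalwes.panel import AllelicRequirement, Mechanism, PanelGene

    rng = np.random.default_rng(123)
    alloc = _PositionAllocator()
    genes = {
        "monoallelic_de_novo": PanelGene("DDM001", AllelicRequirement.MONOALLELIC,
                                         Mechanism.UNCERTAIN, "1"),
        "x_linked_hemizygous": PanelGene("DDX001", AllelicRequirement.HEMIZYGOUS,
                                         Mechanism.UNCERTAIN, "X"),
        "biallelic_homozygous": PanelGene("DDB001", AllelicRequirement.BIALLELIC,
                                          Mechanism.UNCERTAIN, "2"),
        "biallelic_compound_het": PanelGene("DDB002", AllelicRequirement.BIALLELIC,
                                            Mechanism.UNCERTAIN, "3"),
        "monoallelic_inherited_affected": PanelGene(
            "DDM002", AllelicRequirement.MONOALLELIC, Mechanism.UNCERTAIN, "4"),
        "monoallelic_inherited_whitelisted": PanelGene(
            "DDM003", AllelicRequirement.MONOALLELIC, Mechanism.UNCERTAIN, "5"),
        "cnv_event": PanelGene("DDM004", AllelicRequirement.MONOALLELIC,
                               Mechanism.UNCERTAIN, "6"),
        "upd_event": PanelGene("DDM005", AllelicRequirement.MONOALLELIC,
                               Mechanism.UNCERTAIN, "7"),
    }
    trio = FamilyUnit(
        family_id="FAM1", fetus_id="C", mother_id="M", father_id="F",
        phenotype_class=PhenotypeClass.MULTISYSTEM, fetal_sex=Sex.MALE,
    )
    spike_types = list(genes)
    for i in range(1000):
        stype = spike_types[int(rng.integers(len(spike_types)))]
        sites = spike_variant(trio, genes[stype], stype, rng, alloc)
        calls = {
            call_inheritance(_site_to_variant(s, trio), trio) for s in sites
        }
        if stype == "biallelic_compound_het":
            assert calls == {
                InheritanceCall.INHERITED_MATERNAL,
                InheritanceCall.INHERITED_PATERNAL,
            }
        else:
            assert calls == {INTENDED_CALL[stype]}


def test_incompatible_spike_raises():
    from fetalwes.panel import AllelicRequirement, Mechanism, PanelGene

    female_trio = FamilyUnit(
        family_id="FAM1", fetus_id="C", mother_id="M", father_id="F",
        phenotype_class=PhenotypeClass.RENAL, fetal_sex=Sex.FEMALE,
    )
    gene = PanelGene("DDX001", AllelicRequirement.HEMIZYGOUS, Mechanism.UNCERTAIN, "X")
    with pytest.raises(ValueError):
        spike_variant(
            female_trio, gene, "x_linked_hemizygous",
            np.random.default_rng(0), _PositionAllocator(),
        )
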