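from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

from fetalwes.families import (
    AnnotatedVariant,
    FamilyUnit,
    Genotype,
    PhenotypeClass,
    Sex,
    VariantClass,
)
from fetalwes.panel import AllelicRequirement, Mechanism, Panel, PanelGene
from fetalwes.simulate import SimulationConfig, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def trio() -> FamilyUnit:
    return FamilyUnit(
        family_id="FAM1", fetus_id="C", mother_id="M", father_id="F",
        phenotype_class=PhenotypeClass.CARDIAC, fetal_sex=Sex.FEMALE,
    )


@pytest.fixture
def male_trio() -> FamilyUnit:
    return FamilyUnit(
        family_id="FAM1", fetus_id="C", mother_id="M", father_id="F",
        phenotype_class=PhenotypeClass.INCREASED_NT, fetal_sex=Sex.MALE,
    )


@pytest.fixture
def dyad() -> FamilyUnit:
    return FamilyUnit(
        family_id="FAM2", fetus_id="C2", mother_id="M2", father_id=None,
        phenotype_class=PhenotypeClass.SKELETAL, fetal_sex=Sex.FEMALE,
    )


def make_variant(
    gts: dict[str, str],
    gene: str = "DDM001",
    consequence: str = "missense_variant",
    pop_af: float | None = None,
    chrom: str = "1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "T",
    variant_class: VariantClass = VariantClass.SNV_INDEL,
) -> AnnotatedVariant:
    """Terse AnnotatedVariant factory; gts maps sample -> genotype name."""
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, pop_af=pop_af,
        genotypes=tuple((s, Genotype(g)) for s, g in gts.items()),
        variant_class=variant_class,
    )


def make_panel(*genes: PanelGene) -> Panel:
    panel = Panel(name="test")
    defaults = [
        PanelGene("DDM001", AllelicRequirement.MONOALLELIC,
                  Mechanism.LOSS_OF_FUNCTION, "1", 0.9),
        PanelGene("DDB001", AllelicRequirement.BIALLELIC,
                  Mechanism.LOSS_OF_FUNCTION, "2", 0.1),
        PanelGene("DDX001", AllelicRequirement.HEMIZYGOUS,
                  Mechanism.LOSS_OF_FUNCTION, "X", 0.5),
        PanelGene("DDD001", AllelicRequirement.MONOALLELIC_AND_BIALLELIC,
                  Mechanism.UNCERTAIN, "3", None),
    ]
    for g in defaults:
        panel.add(g)
    for g in genes:
        panel.add(g)
    return panel


def scaled_config(seed: int = 0, factor: int = 8, **kwargs) -> SimulationConfig:
    """A cohort scaled down ~8x with a reduced spike set, for fast tests."""
    cfg = SimulationConfig(seed=seed, **kwargs)
    cfg.class_sizes = {k: max(1, v // factor) for k, v in cfg.class_sizes.items()}
    cfg.dyad_count = 2
    if "spikes" not in kwargs:
        cfg.spikes = {
            "monoallelic_de_novo": 4,
            "x_linked_hemizygous": 1,
            "cnv_event": 1,
            "upd_event": 1,
            "biallelic_homozygous": 2,
            "biallelic_compound_het": 2,
            "monoallelic_inherited_affected": 1,
            "monoallelic_inherited_whitelisted": 2,
        }
    cfg.n_background_sites = 40
    return cfg


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory) -> tuple[dict[str, Path], object]:
    outdir = tmp_path_factory.mktemp("sim_small")
    return simulate_cohort(scaled_config(seed=11), outdir)
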