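from __future__ import annotations

from itertools import combinations

import pytest
from hypothesis import given, strategies as st

from fetalwes.families import VariantClass
from fetalwes.prioritise import (
    DiagnosisModel,
    FilterConfig,
    InheritanceCall,
    Whitelist,
    find_compound_hets,
    is_protein_altering,
    passes_frequency,
    prioritise_family,
    whitelist_rescue,
)

from .conftest import make_panel, make_variant

CFG = FilterConfig()


@pytest.mark.parametrize(
    "term,expected",
    [
        ("stop_gained", True),
        ("splice_donor_variant", True),
        ("missense_variant", True),
        ("synonymous_variant", False),
        ("intron_variant", False),
        ("", False),
    ],
)
def test_protein_altering_membership(term, expected):
    assert is_protein_altering(term, CFG) is expected


@pytest.mark.parametrize(
    "af,model,expected",
    [
        (None, DiagnosisModel.MONOALLELIC_DE_NOVO, True),  # unobserved allele
        (0.02, DiagnosisModel.MONOALLELIC_DE_NOVO, False),
        (0.002, DiagnosisModel.BIALLELIC_HOMOZYGOUS, True),
        (0.002, DiagnosisModel.MONOALLELIC_INHERITED, False),
        (0.001, DiagnosisModel.X_LINKED_HEMIZYGOUS, True),
        (0.5, DiagnosisModel.CNV_EVENT, True),  # events bypass frequency
    ],
)
def test_frequency_ceilings_by_model(af, model, expected):
    v = make_variant({"C": "het"}, pop_af=af)
    assert passes_frequency(v, model, CFG) is expected


# ---------------------------------------------------------------------------
# compound hets
# ---------------------------------------------------------------------------

def _het(pos, call):
    gts = (
        {"C": "het", "M": "het", "F": "hom_ref"}
        if call is InheritanceCall.INHERITED_MATERNAL
        else {"C": "het", "M": "hom_ref", "F": "het"}
    )
    return (make_variant(gts, gene="DDB001", pos=pos), call)


def test_one_maternal_one_paternal_is_one_pair(trio):
    pairs = find_compound_hets(
        [_het(1, InheritanceCall.INHERITED_MATERNAL),
         _het(2, InheritanceCall.INHERITED_PATERNAL)],
        trio,
    )
    assert len(pairs) == 1


def test_cis_pair_is_rejected(trio):
    pairs = find_compound_hets(
        [_het(1, InheritanceCall.INHERITED_MATERNAL),
         _het(2, InheritanceCall.INHERITED_MATERNAL)],
        trio,
    )
    assert pairs == []


@pytest.mark.parametrize("n_mat,n_pat", [(0, 3), (1, 1), (2, 3), (4, 2)])
def test_pair_count_matches_brute_force(trio, n_mat, n_pat):
    """n maternal x m paternal hets yield exactly n*m trans pairs,
    verified against brute-force pairing over all 2-subsets."""
    calls = [_het(1 + i, InheritanceCall.INHERITED_MATERNAL) for i in range(n_mat)]
    calls += [
        _het(100 + i, InheritanceCall.INHERITED_PATERNAL) for i in range(n_pat)
    ]
    pairs = find_compound_hets(calls, trio)
    brute = [
        (a, b)
        for a, b in combinations(calls, 2)
        if {a[1], b[1]}
        == {InheritanceCall.INHERITED_MATERNAL, InheritanceCall.INHERITED_PATERNAL}
    ]
    assert len(pairs) == n_mat * n_pat == len(brute)


def test_dyad_pairs_need_presumption_flag(dyad):
    inherited = (
        make_variant({"C2": "het", "M2": "het"}, gene="DDB001", pos=1),
        InheritanceCall.INHERITED_MATERNAL,
    )
    presumed = (
        make_variant({"C2": "het", "M2": "hom_ref"}, gene="DDB001", pos=2),
        InheritanceCall.DE_NOVO_PRESUMED,
    )
    assert len(find_compound_hets([inherited, presumed], dyad)) == 1
    off = FilterConfig(dyad_presume_denovo=False)
    assert find_compound_hets([inherited, presumed], dyad, off) == []


# ---------------------------------------------------------------------------
# whitelist
# ---------------------------------------------------------------------------

def test_whitelist_exact_and_rule_matches():
    panel = make_panel()
    wl = Whitelist(exact={("1", 1000, "A", "T")}, truncating_genes={"DDM001"})
    exact_hit = make_variant({"C": "het"}, pos=1000)
    assert whitelist_rescue(exact_hit, panel, wl, CFG)
    rule_hit = make_variant({"C": "het"}, consequence="stop_gained", pos=2000)
    assert whitelist_rescue(rule_hit, panel, wl, CFG)
    # missense does not satisfy an any_truncating rule
    miss = make_variant({"C": "het"}, consequence="missense_variant", pos=2000)
    assert not whitelist_rescue(miss, panel, wl, CFG)
    # unlisted gene
    other = make_variant({"C": "het"}, gene="DDB001", consequence="stop_gained",
                         pos=3000)
    assert not whitelist_rescue(other, panel, wl, CFG)


# ---------------------------------------------------------------------------
# per-family assembly
# ---------------------------------------------------------------------------

def test_de_novo_in_dominant_gene_is_a_diagnosis(trio):
    v = make_variant({"C": "het", "M": "hom_ref", "F": "hom_ref"},
                     consequence="stop_gained")
    out = prioritise_family([v], trio, make_panel())
    assert len(out) == 1
    assert out[0].model is DiagnosisModel.MONOALLELIC_DE_NOVO
    assert not out[0].rescued_by_whitelist


def test_inherited_from_unaffected_parent_is_dropped(trio):
    v = make_variant({"C": "het", "M": "het", "F": "hom_ref"},
                     consequence="stop_gained")
    assert prioritise_family([v], trio, make_panel()) == []


def test_inherited_from_affected_parent_is_kept():
    from fetalwes.families import FamilyUnit, PhenotypeClass

    fam = FamilyUnit(
        family_id="FAM1", fetus_id="C", mother_id="M", father_id="F",
        phenotype_class=PhenotypeClass.ABDOMINAL, mother_affected=True,
    )
    v = make_variant({"C": "het", "M": "het", "F": "hom_ref"})
    out = prioritise_family([v], fam, make_panel())
    assert len(out) == 1
    assert out[0].model is DiagnosisModel.MONOALLELIC_INHERITED
    assert not out[0].rescued_by_whitelist


def test_whitelist_rescues_inherited_pathogenic(trio):
    v = make_variant({"C": "het", "M": "het", "F": "hom_ref"}, pos=1000)
    wl = Whitelist(exact={("1", 1000, "A", "T")})
    out = prioritise_family([v], trio, make_panel(), whitelist=wl)
    assert len(out) == 1 and out[0].rescued_by_whitelist
    assert prioritise_family([v], trio, make_panel(), whitelist=None) == []


def test_non_panel_gene_never_emits(trio):
    v = make_variant({"C": "het", "M": "hom_ref", "F": "hom_ref"}, gene="NOTPANEL")
    assert prioritise_family([v], trio, make_panel()) == []


def test_synonymous_never_emits(trio):
    v = make_variant({"C": "het", "M": "hom_ref", "F": "hom_ref"},
                     consequence="synonymous_variant")
    assert prioritise_family([v], trio, make_panel()) == []


def test_single_het_in_recessive_gene_is_not_a_diagnosis(trio):
    v = make_variant({"C": "het", "M": "hom_ref", "F": "hom_ref"}, gene="DDB001")
    assert prioritise_family([v], trio, make_panel()) == []


def test_homozygote_in_recessive_gene(trio):
    v = make_variant({"C": "hom_alt", "M": "het", "F": "het"}, gene="DDB001")
    out = prioritise_family([v], trio, make_panel())
    assert [d.model for d in out] == [DiagnosisModel.BIALLELIC_HOMOZYGOUS]


def test_compound_het_pair_is_one_diagnosis(trio):
    v1 = make_variant({"C": "het", "M": "het", "F": "hom_ref"}, gene="DDB001", pos=10)
    v2 = make_variant({"C": "het", "M": "hom_ref", "F": "het"}, gene="DDB001", pos=20)
    out = prioritise_family([v1, v2], trio, make_panel())
    assert len(out) == 1
    assert out[0].model is DiagnosisModel.BIALLELIC_COMPOUND_HET
    assert len(out[0].variants) == 2


def test_hemizygous_model_in_x_gene(male_trio):
    v = make_variant({"C": "hemi_alt", "M": "hom_ref", "F": "hom_ref"},
                     gene="DDX001", chrom="X", consequence="stop_gained")
    out = prioritise_family([v], male_trio, make_panel())
    assert [d.model for d in out] == [DiagnosisModel.X_LINKED_HEMIZYGOUS]


def test_cnv_and_upd_bypass_panel_and_consequence(trio):
    cnv = make_variant({"C": "het", "M": "hom_ref", "F": "hom_ref"},
                       gene="PKD1/TSC2", consequence="copy_number_loss",
                       variant_class=VariantClass.CNV, pos=7000)
    upd = make_variant({"C": "het", "M": "hom_ref", "F": "hom_ref"},
                       gene="", consequence="uniparental_disomy",
                       variant_class=VariantClass.UPD, chrom="15", pos=1)
    out = prioritise_family([cnv, upd], trio, make_panel())
    assert {d.model for d in out} == {DiagnosisModel.CNV_EVENT, DiagnosisModel.UPD_EVENT}


def test_common_variant_filtered_by_model_threshold(trio):
    v = make_variant({"C": "het", "M": "hom_ref", "F": "hom_ref"}, pop_af=0.01)
    assert prioritise_family([v], trio, make_panel()) == []


def test_accounting_conserves_input(trio):
    variants = [
        make_variant({"C": "het", "M": "hom_ref", "F": "hom_ref"}, pos=1),
        make_variant({"C": "het", "M": "het", "F": "hom_ref"}, pos=2),
        make_variant({"C": "het", "M": "hom_ref", "F": "hom_ref"},
                     gene="NOPE", pos=3),
        make_variant({"C": "het", "M": "hom_ref", "F": "hom_ref"},
                     consequence="synonymous_variant", pos=4),
        make_variant({"C": "hom_alt", "M": "hom_ref", "F": "het"}, pos=5),
    ]
    counters: dict[str, int] = {}
    prioritise_family(variants, trio, make_panel(), counters=counters)
    accounted = (
        counters["event_records"]
        + counters["non_panel_gene"]
        + counters["non_protein_altering"]
        + counters["mendelian_inconsistent"]
        + counters["uninformative"]
        + counters["gene_stage_variants"]
    )
    assert counters["input"] == len(variants) == accounted


# ---------------------------------------------------------------------------
# monotonicity properties
# ---------------------------------------------------------------------------

@st.composite
def family_variants(draw):
    genes = ["DDM001", "DDB001", "DDD001", "OFFPANEL"]
    csqs = ["missense_variant", "stop_gained", "synonymous_variant"]
    gts = ["hom_ref", "het", "hom_alt"]
    n = draw(st.integers(0, 8))
    out = []
    for i in range(n):
        out.append(
            make_variant(
                {"C": draw(st.sampled_from(gts)),
                 "M": draw(st.sampled_from(gts)),
                 "F": draw(st.sampled_from(gts))},
                gene=draw(st.sampled_from(genes)),
                consequence=draw(st.sampled_from(csqs)),
                pop_af=draw(st.sampled_from([None, 1e-5, 5e-4, 3e-3, 0.02])),
                pos=10 + i,
            )
        )
    return out


_TRIO = None


def _prop_trio():
    from fetalwes.families import FamilyUnit, PhenotypeClass
    return FamilyUnit(
        family_id="FAM1", fetus_id="C", mother_id="M", father_id="F",
        phenotype_class=PhenotypeClass.CARDIAC,
    )


@given(family_variants())
def test_raising_frequency_thresholds_never_removes_diagnoses(variants):
    trio = _prop_trio()
    tight = FilterConfig(max_af_monoallelic=0.0005, max_af_biallelic=0.002)
    loose = FilterConfig(max_af_monoallelic=0.005, max_af_biallelic=0.05)
    ids_tight = {d.diagnosis_id for d in prioritise_family(variants, trio, make_panel(), cfg=tight)}
    ids_loose = {d.diagnosis_id for d in prioritise_family(variants, trio, make_panel(), cfg=loose)}
    assert ids_tight <= ids_loose


@given(family_variants())
def test_shrinking_consequence_set_never_adds_diagnoses(variants):
    trio = _prop_trio()
    full = FilterConfig()
    small = FilterConfig(
        protein_altering_terms=frozenset({"stop_gained"}),
        truncating_terms=frozenset({"stop_gained"}),
    )
    ids_small = {d.diagnosis_id for d in prioritise_family(variants, trio, make_panel(), cfg=small)}
    ids_full = {d.diagnosis_id for d in prioritise_family(variants, trio, make_panel(), cfg=full)}
    assert ids_small <= ids_full


@given(family_variants())
def test_no_emitted_call_is_mendelian_inconsistent(variants):
    trio = _prop_trio()
    for d in prioritise_family(variants, trio, make_panel()):
        for _, call in d.variants:
            assert call is not InheritanceCall.MENDELIAN_INCONSISTENT
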