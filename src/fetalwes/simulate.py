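"""Synthetic prenatal exome cohorts with known ground truth.

The generator emulates the study conditions of the cohort this package
models: 610 fetus–parent families (596 trios, 14 dyads) distributed over
the eleven ultrasound phenotype classes, with a configurable set of
spiked-in causal variants — one per diagnosis model, including a
whitelist-rescue case in which a pathogenic variant is inherited from an
apparently unaffected parent — on a benign polymorphic background.

Background allele frequencies follow a two-point mixture (common ~0.1,
rare ~1e-4) rather than a fitted site-frequency spectrum: only behaviour
around the filter thresholds matters to the pipeline.  Genome coordinates
are synthetic (one pseudo-contig per autosome plus X) and ref/alt bases
are drawn from {A, C, G, T}; annotation fields, not sequence context,
drive the analysis.  Pre-exome exclusions (aneuploidy by QF-PCR, large
CNVs by microarray) are recorded in the manifest as bookkeeping counts
only.

Every file the pipeline consumes is written — panel, pedigree,
multi-sample VCF, whitelist, review-decision template, outcomes — plus a
JSON *manifest* that is the exhaustive ground truth: which diagnoses were
spiked where, and which of them are expected to survive filtering with
and without the whitelist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .classify import CRPDecision, Classification, Contribution, write_decisions
from .families import FamilyUnit, PhenotypeClass, Sex, write_pedigree
from .panel import AllelicRequirement, Mechanism, Panel, PanelGene, write_panel
from .prioritise import DiagnosisModel

__all__ = [
    "DEFAULT_CLASS_SIZES",
    "DEFAULT_SPIKES",
    "SimulationConfig",
    "SpikeRecord",
    "Manifest",
    "simulate_cohort",
]

#: family counts per phenotype class, as in the cohort being emulated
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "abdominal": 45,
    "brain": 69,
    "cardiac": 81,
    "thoracic": 23,
    "facial_cleft": 32,
    "hydrops": 33,
    "increased_NT": 93,
    "renal": 16,
    "skeletal": 65,
    "spinal": 10,
    "multisystem": 143,
}

#: spiked causal diagnoses per model; totals 52, mirroring the modelled
#: cohort's breakdown (32 de novo incl. one CNV and one X-linked case,
#: 19 inherited, 1 uniparental disomy)
DEFAULT_SPIKES: dict[str, int] = {
    "monoallelic_de_novo": 30,
    "x_linked_hemizygous": 1,
    "cnv_event": 1,
    "upd_event": 1,
    "biallelic_homozygous": 10,
    "biallelic_compound_het": 4,
    "monoallelic_inherited_affected": 2,
    "monoallelic_inherited_whitelisted": 3,
}

_SPIKE_MODEL: dict[str, DiagnosisModel] = {
    "monoallelic_de_novo": DiagnosisModel.MONOALLELIC_DE_NOVO,
    "x_linked_hemizygous": DiagnosisModel.X_LINKED_HEMIZYGOUS,
    "cnv_event": DiagnosisModel.CNV_EVENT,
    "upd_event": DiagnosisModel.UPD_EVENT,
    "biallelic_homozygous": DiagnosisModel.BIALLELIC_HOMOZYGOUS,
    "biallelic_compound_het": DiagnosisModel.BIALLELIC_COMPOUND_HET,
    "monoallelic_inherited_affected": DiagnosisModel.MONOALLELIC_INHERITED,
    "monoallelic_inherited_whitelisted": DiagnosisModel.MONOALLELIC_INHERITED,
}

_BASES = ("A", "C", "G", "T")


@dataclass
class SimulationConfig:
    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    dyad_count: int = 14
    spikes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SPIKES))
    n_background_sites: int = 150
    background_common_af: float = 0.10
    background_rare_af: float = 1e-4
    background_common_weight: float = 0.6
    noise_rate: float = 0.0
    phenotype_cap: float = 0.20
    pre_exclusion_qf_pcr: int = 97
    pre_exclusion_microarray: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.class_sizes.values()):
            raise ValueError("class sizes must be >= 0")
        if sum(self.class_sizes.values()) == 0:
            raise ValueError("class sizes sum to 0")
        for key in self.spikes:
            if key not in _SPIKE_MODEL:
                raise ValueError(f"unknown spike model {key!r}")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must lie in [0, 1]")

    @property
    def n_families(self) -> int:
        return sum(self.class_sizes.values())


@dataclass
class SpikeRecord:
    """Ground truth for one spiked diagnosis."""

    family_id: str
    gene: str
    spike_type: str
    model: str
    variant_keys: list[list]  # [chrom, pos, ref, alt] per variant
    expected_diagnosis_id: str
    requires_whitelist: bool = False


@dataclass
class Manifest:
    seed: int
    n_families: int
    n_trios: int
    n_dyads: int
    class_sizes: dict[str, int]
    spikes: list[SpikeRecord]
    n_background_sites: int
    pre_exclusion: dict[str, int]

    def expected_ids(self, with_whitelist: bool = True) -> set[str]:
        """Diagnosis ids the pipeline is expected to emit."""
        return {
            s.expected_diagnosis_id
            for s in self.spikes
            if with_whitelist or not s.requires_whitelist
        }

    def spiked_genes(self) -> set[str]:
        return {s.gene for s in self.spikes if s.gene}

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["spikes"] = [asdict(s) for s in self.spikes]
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Manifest":
        with Path(path).open(encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["spikes"] = [SpikeRecord(**s) for s in payload["spikes"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# synthetic panel
# ---------------------------------------------------------------------------

def _build_panel(rng: np.random.Generator) -> tuple[Panel, dict[str, list[str]]]:
    """A schema-compatible synthetic stand-in for the real gene panel.

    Symbols, coordinates and pLI values are synthetic; only the allelic
    requirement structure matters to the pipeline.
    """
    panel = Panel(name="synthetic-dd-panel", version="sim")
    pools: dict[str, list[str]] = {
        "monoallelic": [], "biallelic": [], "hemizygous": [], "dual": [],
    }
    layout = (
        ("DDM", 18, AllelicRequirement.MONOALLELIC, "monoallelic"),
        ("DDB", 12, AllelicRequirement.BIALLELIC, "biallelic"),
        ("DDX", 3, AllelicRequirement.HEMIZYGOUS, "hemizygous"),
        ("DDD", 4, AllelicRequirement.MONOALLELIC_AND_BIALLELIC, "dual"),
    )
    mechanisms = list(Mechanism)
    chrom_cycle = 0
    for prefix, count, req, pool in layout:
        for i in range(1, count + 1):
            symbol = f"{prefix}{i:03d}"
            if req is AllelicRequirement.HEMIZYGOUS:
                chrom = "X"
            else:
                chrom = str((chrom_cycle % 22) + 1)
                chrom_cycle += 1
            panel.add(
                PanelGene(
                    symbol=symbol,
                    allelic_requirement=req,
                    mechanism=mechanisms[int(rng.integers(len(mechanisms)))],
                    chromosome=chrom,
                    pli=round(float(rng.uniform()), 3),
                )
            )
            pools[pool].append(symbol)
    return panel, pools


#: genes deliberately left off the panel, used for background variants
_NON_PANEL_GENES = [f"BKG{i:03d}" for i in range(1, 11)]


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

def _build_families(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[FamilyUnit]:
    families: list[FamilyUnit] = []
    i = 0
    class_order = list(cfg.class_sizes)
    for label in class_order:
        for _ in range(cfg.class_sizes[label]):
            i += 1
            fid = f"FAM{i:04d}"
            families.append(
                FamilyUnit(
                    family_id=fid,
                    fetus_id=f"{fid}_C",
                    phenotype_class=PhenotypeClass(label),
                    fetal_sex=Sex.MALE if rng.uniform() < 353 / 610 else Sex.FEMALE,
                    mother_id=f"{fid}_M",
                    father_id=f"{fid}_F",
                )
            )
    n_dyads = min(cfg.dyad_count, len(families))
    dyad_idx = rng.choice(len(families), size=n_dyads, replace=False)
    for j in sorted(int(x) for x in dyad_idx):
        f = families[j]
        # dyads keep the mother; the father was not sequenced
        families[j] = FamilyUnit(
            family_id=f.family_id,
            fetus_id=f.fetus_id,
            phenotype_class=f.phenotype_class,
            fetal_sex=f.fetal_sex,
            mother_id=f.mother_id,
            father_id=None,
        )
    return families


def _set_parent_affected(fam: FamilyUnit, parent: str) -> FamilyUnit:
    return FamilyUnit(
        family_id=fam.family_id,
        fetus_id=fam.fetus_id,
        phenotype_class=fam.phenotype_class,
        fetal_sex=fam.fetal_sex,
        mother_id=fam.mother_id,
        father_id=fam.father_id,
        mother_affected=fam.mother_affected or parent == "mother",
        father_affected=fam.father_affected or parent == "father",
    )


# ---------------------------------------------------------------------------
# VCF assembly
# ---------------------------------------------------------------------------

@dataclass
class _Site:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    pop_af: Optional[float]
    varclass: str
    genotypes: dict[str, str]  # sample -> GT string; absent -> 0/0 (or 0 on X for males)

    def sort_key(self) -> tuple:
        c = self.chrom
        order = 23 if c == "X" else int(c)
        return (order, self.pos, self.alt)


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(len(_BASES), size=2, replace=False)
    return _BASES[int(ref)], _BASES[int(alt)]


class _PositionAllocator:
    """Unique, deterministic positions per gene / chromosome."""

    def __init__(self) -> None:
        self._next: dict[str, int] = {}

    def take(self, key: str, base: int) -> int:
        pos = self._next.get(key, base)
        self._next[key] = pos + 137
        return pos


def _gene_base(gene: str) -> int:
    # stable per-gene offset keeps spike positions unique and reproducible
    return 1_000_000 + (hash_stable(gene) % 9000) * 10_000


def hash_stable(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31)
    return h


# ---------------------------------------------------------------------------
# spiking
# ---------------------------------------------------------------------------

_SPIKE_CONSEQUENCES = (
    "missense_variant", "stop_gained", "frameshift_variant",
    "splice_donor_variant", "splice_acceptor_variant", "inframe_insertion",
)


def _spike_af(rng: np.random.Generator) -> Optional[float]:
    # causal alleles are essentially unobserved in reference populations
    if rng.uniform() < 0.5:
        return None
    return round(float(rng.uniform(0.0, 5e-5)), 8)


def spike_variant(
    family: FamilyUnit,
    gene: PanelGene,
    spike_type: str,
    rng: np.random.Generator,
    alloc: _PositionAllocator,
    force_consequence: Optional[str] = None,
) -> list[_Site]:
    """Construct the site(s) realising one spiked diagnosis in one family.

    Genotypes are Mendelian-consistent by construction and satisfy the
    target model's definition; population frequencies are drawn below the
    relevant filter ceiling.
    """
    fid = family.family_id
    chrom = gene.chromosome
    consequence = force_consequence or str(
        _SPIKE_CONSEQUENCES[int(rng.integers(len(_SPIKE_CONSEQUENCES)))]
    )

    def new_site(gt: dict[str, str], varclass: str = "snv_indel",
                 csq: Optional[str] = None) -> _Site:
        ref, alt = _draw_alleles(rng)
        return _Site(
            chrom=chrom,
            pos=alloc.take(gene.symbol, _gene_base(gene.symbol)),
            ref=ref, alt=alt, gene=gene.symbol,
            consequence=csq or consequence,
            pop_af=_spike_af(rng), varclass=varclass, genotypes=gt,
        )

    mother, father, fetus = family.mother_id, family.father_id, family.fetus_id

    if spike_type == "monoallelic_de_novo":
        gt = {fetus: "0/1"}
        if mother:
            gt[mother] = "0/0"
        if father:
            gt[father] = "0/0"
        return [new_site(gt)]

    if spike_type == "x_linked_hemizygous":
        if family.fetal_sex is not Sex.MALE or not gene.is_x_linked:
            raise ValueError("hemizygous spike needs a male fetus and an X gene")
        gt = {fetus: "1"}
        if mother:
            gt[mother] = "0/0"  # de novo on the maternally transmitted X
        if father:
            gt[father] = "0"
        return [new_site(gt)]

    if spike_type == "biallelic_homozygous":
        if not family.is_trio:
            raise ValueError("homozygous spike needs both parents")
        return [new_site({fetus: "1/1", mother: "0/1", father: "0/1"})]

    if spike_type == "biallelic_compound_het":
        if not family.is_trio:
            raise ValueError("compound-het spike needs both parents")
        s1 = new_site({fetus: "0/1", mother: "0/1", father: "0/0"})
        s2 = new_site({fetus: "0/1", mother: "0/0", father: "0/1"})
        return [s1, s2]

    if spike_type in (
        "monoallelic_inherited_affected", "monoallelic_inherited_whitelisted"
    ):
        # transmitted by the mother (always sequenced, trios and dyads alike)
        gt = {fetus: "0/1", mother: "0/1"}
        if father:
            gt[father] = "0/0"
        return [new_site(gt)]

    if spike_type == "cnv_event":
        gt = {fetus: "0/1"}
        if mother:
            gt[mother] = "0/0"
        if father:
            gt[father] = "0/0"
        return [new_site(gt, varclass="cnv", csq="copy_number_loss")]

    if spike_type == "upd_event":
        gt = {fetus: "0/1"}
        if mother:
            gt[mother] = "0/0"
        if father:
            gt[father] = "0/0"
        return [new_site(gt, varclass="upd", csq="uniparental_disomy")]

    raise ValueError(f"unknown spike type {spike_type!r}")


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def _background_sites(
    cfg: SimulationConfig,
    families: list[FamilyUnit],
    panel_symbols: list[str],
    rng: np.random.Generator,
    alloc: _PositionAllocator,
) -> list[_Site]:
    """Benign polymorphic background.

    Four strata, all expected to be removed by the filters: common and
    rare synonymous variants anywhere; common protein-altering variants
    in panel genes (removed by frequency); rare protein-altering variants
    in non-panel genes (removed by the panel restriction).
    """
    sites: list[_Site] = []
    for _ in range(cfg.n_background_sites):
        common = rng.uniform() < cfg.background_common_weight
        af = (
            float(rng.normal(cfg.background_common_af, 0.02))
            if common
            else cfg.background_rare_af
        )
        af = min(max(af, 1e-6), 0.5)
        stratum = rng.uniform()
        if stratum < 0.4:
            gene = panel_symbols[int(rng.integers(len(panel_symbols)))]
            csq = "synonymous_variant"
        elif stratum < 0.7:
            gene = panel_symbols[int(rng.integers(len(panel_symbols)))]
            csq = "missense_variant"
            # protein-altering background in panel genes must be common,
            # otherwise it would constitute an unintended diagnosis
            af = max(af, 0.02)
        else:
            gene = _NON_PANEL_GENES[int(rng.integers(len(_NON_PANEL_GENES)))]
            csq = "missense_variant" if rng.uniform() < 0.5 else "synonymous_variant"
        chrom = str((hash_stable(gene) % 22) + 1)
        ref, alt = _draw_alleles(rng)
        # parental genotypes are Hardy-Weinberg draws; the fetus receives
        # one allele from each parent (an unsequenced dyad parent is still
        # simulated for transmission)
        n = len(families)
        pm = rng.uniform(size=(n, 2)) < af
        pf = rng.uniform(size=(n, 2)) < af
        rows = np.arange(n)
        cm = pm[rows, rng.integers(2, size=n)]
        cp = pf[rows, rng.integers(2, size=n)]
        child_n = cm.astype(int) + cp.astype(int)
        mother_n = pm.sum(axis=1)
        father_n = pf.sum(axis=1)
        gts: dict[str, str] = {}
        for i, fam in enumerate(families):
            if child_n[i]:
                gts[fam.fetus_id] = _gt_string(int(child_n[i]))
            if fam.mother_id and mother_n[i]:
                gts[fam.mother_id] = _gt_string(int(mother_n[i]))
            if fam.father_id and father_n[i]:
                gts[fam.father_id] = _gt_string(int(father_n[i]))
        sites.append(
            _Site(
                chrom=chrom, pos=alloc.take(gene, _gene_base(gene)),
                ref=ref, alt=alt, gene=gene, consequence=csq,
                pop_af=round(af, 6), varclass="snv_indel", genotypes=gts,
            )
        )
    return sites


def _gt_string(n_alt: int) -> str:
    return ("0/0", "0/1", "1/1")[n_alt]


_GT_VALUES = ("0/0", "0/1", "1/1")


def _apply_noise(
    sites: list[_Site], samples: list[str], rate: float, rng: np.random.Generator
) -> None:
    """Optional genotype-flip noise: each (site, sample) genotype is
    replaced by a random diploid genotype with probability ``rate``."""
    if rate <= 0:
        return
    for site in sites:
        flips = rng.uniform(size=len(samples)) < rate
        for flip, sample in zip(flips, samples):
            if flip:
                site.genotypes[sample] = _GT_VALUES[int(rng.integers(3))]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _write_vcf(
    sites: list[_Site], samples: list[str], families: list[FamilyUnit],
    path: Path,
) -> None:
    male_on_x: set[str] = set()
    for fam in families:
        if fam.fetal_sex is Sex.MALE:
            male_on_x.add(fam.fetus_id)
        if fam.father_id:
            male_on_x.add(fam.father_id)
    contigs = sorted({s.chrom for s in sites}, key=lambda c: 23 if c == "X" else int(c))
    with path.open("w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ_TERM,Number=1,Type=String,Description="Consequence term">\n')
        fh.write('##INFO=<ID=POP_AF,Number=A,Type=Float,Description="Population allele frequency">\n')
        fh.write('##INFO=<ID=VARCLASS,Number=1,Type=String,Description="snv_indel|cnv|upd">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for site in sorted(sites, key=_Site.sort_key):
            info = [f"GENE={site.gene}", f"CSQ_TERM={site.consequence}"]
            if site.pop_af is not None:
                info.append(f"POP_AF={site.pop_af:.6g}")
            info.append(f"VARCLASS={site.varclass}")
            default_male_x = "0" if site.chrom == "X" else "0/0"
            cols = [
                site.genotypes.get(
                    s, default_male_x if s in male_on_x and site.chrom == "X" else "0/0"
                )
                for s in samples
            ]
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t"
                + ";".join(info) + "\tGT\t" + "\t".join(cols) + "\n"
            )


def simulate_cohort(
    cfg: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], Manifest]:
    """Generate a full synthetic cohort under ``outdir``.

    Returns the written file paths and the ground-truth manifest.  The
    same seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    panel, pools = _build_panel(rng)
    families = _build_families(cfg, rng)
    alloc = _PositionAllocator()

    # -- spike assignment: distinct eligible family per spike ---------------
    spike_order = [
        (stype, k) for stype, count in sorted(cfg.spikes.items())
        for k in range(count)
    ]
    available = list(range(len(families)))
    rng.shuffle(available)
    used: set[int] = set()

    def claim(predicate) -> int:
        for idx in available:
            if idx in used:
                continue
            if predicate(families[idx]):
                used.add(idx)
                return idx
        raise ValueError("no eligible family left for spike")

    gene_cursor = {k: 0 for k in pools}

    def next_gene(pool: str) -> PanelGene:
        symbols = pools[pool]
        sym = symbols[gene_cursor[pool] % len(symbols)]
        gene_cursor[pool] += 1
        g = panel.get(sym)
        assert g is not None
        return g

    spikes: list[SpikeRecord] = []
    sites: list[_Site] = []
    whitelist_rows: list[str] = []
    first_whitelist_rule_used = False

    for stype, _k in spike_order:
        if stype == "x_linked_hemizygous":
            idx = claim(lambda f: f.is_trio and f.fetal_sex is Sex.MALE)
            gene = next_gene("hemizygous")
        elif stype in ("biallelic_homozygous", "biallelic_compound_het",
                       "cnv_event", "upd_event"):
            idx = claim(lambda f: f.is_trio)
            gene = next_gene("biallelic" if stype.startswith("biallelic") else "monoallelic")
        elif stype == "monoallelic_de_novo":
            idx = claim(lambda f: f.is_trio)
            # dual-requirement genes also accept the monoallelic model
            gene = next_gene("dual" if _k % 5 == 4 else "monoallelic")
        else:  # inherited monoallelic types
            idx = claim(lambda f: f.is_trio)
            gene = next_gene("monoallelic")
        fam = families[idx]

        force_csq = None
        if stype == "monoallelic_inherited_whitelisted" and not first_whitelist_rule_used:
            # exercise the gene-level any_truncating whitelist rule once;
            # the remaining rescues use exact site keys
            force_csq = "stop_gained"
        new_sites = spike_variant(fam, gene, stype, rng, alloc, force_csq)
        sites.extend(new_sites)

        if stype == "monoallelic_inherited_affected":
            families[idx] = _set_parent_affected(fam, "mother")
            fam = families[idx]
        if stype == "monoallelic_inherited_whitelisted":
            if not first_whitelist_rule_used:
                whitelist_rows.append(f"{gene.symbol}\tany_truncating")
                first_whitelist_rule_used = True
            else:
                s = new_sites[0]
                whitelist_rows.append(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}")

        model = _SPIKE_MODEL[stype]
        ordered = sorted(new_sites, key=lambda s: (s.pos, s.alt))
        positions = "-".join(str(s.pos) for s in ordered)
        spikes.append(
            SpikeRecord(
                family_id=fam.family_id,
                gene=gene.symbol,
                spike_type=stype,
                model=model.value,
                variant_keys=[[s.chrom, s.pos, s.ref, s.alt] for s in ordered],
                expected_diagnosis_id=(
                    f"{fam.family_id}:{gene.symbol}:{model.value}:{positions}"
                ),
                requires_whitelist=stype == "monoallelic_inherited_whitelisted",
            )
        )

    sites.extend(_background_sites(cfg, families, panel.symbols, rng, alloc))

    samples: list[str] = []
    for fam in families:
        if fam.father_id:
            samples.append(fam.father_id)
        if fam.mother_id:
            samples.append(fam.mother_id)
        samples.append(fam.fetus_id)
    _apply_noise(sites, samples, cfg.noise_rate, rng)

    # -- outcomes: study-like proportions -----------------------------------
    outcome_rows: list[str] = []
    outcome_labels = np.array(
        ["termination", "miscarriage", "stillbirth", "neonatal_death", "livebirth"]
    )
    outcome_p = np.array([142, 14, 22, 14, 282], dtype=float)
    outcome_p /= outcome_p.sum()
    for fam in families:
        if rng.uniform() < 474 / 610:
            label = str(outcome_labels[int(rng.choice(5, p=outcome_p))])
        else:
            label = "unknown"
        outcome_rows.append(f"{fam.family_id}\t{label}")

    # -- write everything ----------------------------------------------------
    paths = {
        "panel": outdir / "panel.tsv",
        "pedigree": outdir / "cohort.ped",
        "vcf": outdir / "cohort.vcf",
        "whitelist": outdir / "whitelist.tsv",
        "decisions": outdir / "decisions.tsv",
        "outcomes": outdir / "outcomes.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_panel(panel, paths["panel"])
    write_pedigree(families, paths["pedigree"])
    _write_vcf(sites, samples, families, paths["vcf"])
    with paths["whitelist"].open("w", encoding="utf-8") as fh:
        for row in whitelist_rows:
            fh.write(row + "\n")
    decisions = [
        CRPDecision(
            diagnosis_id=s.expected_diagnosis_id,
            classification=Classification.PATHOGENIC,
            contribution=Contribution.FULL,
        )
        for s in sorted(spikes, key=lambda s: s.expected_diagnosis_id)
    ]
    write_decisions(decisions, paths["decisions"])
    with paths["outcomes"].open("w", encoding="utf-8") as fh:
        fh.write("family_id\toutcome\n")
        for row in outcome_rows:
            fh.write(row + "\n")

    manifest = Manifest(
        seed=cfg.seed,
        n_families=len(families),
        n_trios=sum(1 for f in families if f.is_trio),
        n_dyads=sum(1 for f in families if not f.is_trio),
        class_sizes=dict(cfg.class_sizes),
        spikes=spikes,
        n_background_sites=cfg.n_background_sites,
        pre_exclusion={
            "qf_pcr": cfg.pre_exclusion_qf_pcr,
            "microarray": cfg.pre_exclusion_microarray,
        },
    )
    manifest.to_json(paths["manifest"])
    return paths, manifest
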