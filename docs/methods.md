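# Methods

## The analysis in one paragraph

The package models the post-sequencing analysis of a prenatal exome
cohort: fetuses with structural anomalies, sequenced with both parents
(trios) or one parent (dyads), screened against a virtual panel of
developmental-disorder genes. Variants are prioritised when they are
rare, protein-altering, and transmitted in a way that matches the panel
gene's allelic requirement; the surviving *potential diagnoses* are
classified by a human review panel, and the cohort-level statistics —
diagnostic yield with exact confidence intervals, phenotype-class
enrichment, recurrence risks, outcome association — are computed from
the classified set.

## Inheritance calling

For an autosomal variant in a trio, every fetal/maternal/paternal
genotype combination is resolved by transmission logic:

* fetus heterozygous, both parents homozygous reference → **de novo**;
* fetus heterozygous and exactly one parent able to have transmitted the
  alternate allele → **inherited** (maternal or paternal); when both
  parents carry it and either could be the origin, the call is
  **uninformative** (the variant cannot be phased and is not used for
  compound-het pairing);
* fetus homozygous-alternate with both parents carriers → **biallelic
  homozygous**; with any homozygous-reference parent → **Mendelian
  inconsistent** (never emitted as a diagnosis);
* a male fetal genotype on the X outside the pseudo-autosomal regions is
  normalised to hemizygous; with a carrier mother the call is
  **hemizygous maternal**, with a homozygous-reference mother **de
  novo**. Pseudo-autosomal subtlety is out of scope and PARs are treated
  as autosomal.

In dyads (and at sites where one parent's genotype is missing), a fetal
variant not carried by the available parent is **presumed de novo** when
`dyad_presume_denovo` is enabled (the default), and uninformative
otherwise; a variant carried by the available parent is called inherited
from that parent by parsimony. The trio logic is validated in the test
suite against an independent brute-force enumeration of parental allele
transmissions over all 27 genotype combinations.

Compound heterozygotes are all pairs of one maternally and one
paternally inherited heterozygote in the same biallelic-requirement
gene; same-origin (cis) pairs are excluded. In dyads a pair of one
inherited plus one presumed-de-novo heterozygote is accepted only under
the presumption flag.

## Filter parameters

| parameter | default | rationale |
| --- | --- | --- |
| `max_af_monoallelic` | 0.001 | dominant and X-linked candidate alleles must be essentially absent from reference populations |
| `max_af_biallelic` | 0.005 | recessive carrier alleles segregate at higher frequency |
| `protein_altering_terms` | 10 sequence-ontology terms (missense, stop gained/lost, start lost, frameshift, in-frame indel, splice donor/acceptor, protein-altering) | covers the consequence vocabulary of the reference cohort's findings |
| `truncating_terms` | stop gained, frameshift, splice donor/acceptor, start lost | the subset eligible for gene-level whitelist rules |
| `dyad_presume_denovo` | on | dyads cannot prove de novo status; presumption mirrors clinical practice and is flagged in the output |

The source study does not publish its exact thresholds or consequence
list; these defaults are explicit, configurable stand-ins chosen from
standard rare-disease practice. A population frequency that is absent is
treated as 0 (an allele never observed in references is rare by
construction). Gene mechanism (loss-of-function, activating,
dominant-negative) is carried as reviewer metadata and does not filter —
no mechanism-based exclusion is part of the procedure. Dual-mode
(`monoallelic_and_biallelic`) panel genes match under either inheritance
model.

An inherited heterozygote in a monoallelic gene is retained only when
the transmitting parent is affected, or when the variant matches the
whitelist (exact chrom/pos/ref/alt key, or a gene-level
`any_truncating` rule restricted to truncating consequences in panel
genes). The rescue overrides only the unaffected-parent exclusion; it
does not bypass the consequence class or the frequency ceiling.
Pre-called CNV and UPD records bypass the panel, consequence and
frequency filters entirely and are carried as events.

## Classification and derived quantities

Review decisions are inputs, never computed: the five-tier
classification and the causal-contribution judgement encode human expert
consensus under ACMG-style guidelines, and automating them would invent
evidence the package does not have. A record is *diagnostic* iff
classification ∈ {pathogenic, likely pathogenic} and contribution ∈
{partial, full}; reportability coincides with diagnostic status under
the modelled study's ethics framework. Candidates without a decision
default to (VUS, uncertain) so pipeline accounting is conserved.
Recurrence risk is *low* for de novo findings (including presumed de
novo and de novo CNVs) and uniparental disomy, *high* for anything
inherited.

## Statistics

* **Yield intervals** are Clopper–Pearson: the exact binomial interval
  obtained by inverting the two tail probabilities, computed through the
  beta-quantile identity. This choice reproduces the reference cohort's
  printed interval (6.4–11.0% for 52/610), which mid-p or Wilson
  intervals do not. Tests verify the endpoints against direct
  root-finding on the binomial tails to 1e-9, and ≥95% empirical
  coverage at the cohort's operating point.
* **Fisher's exact test** is two-sided under the probability-mass rule
  (sum of all same-margin tables no more probable than the observed
  one), the convention of the mainstream statistical environments; it is
  verified against full hypergeometric enumeration for all tables with
  margins ≤ 12.
* **Class enrichment** tests each of the eleven phenotype classes
  one-vs-rest and applies Bonferroni with k = 11 (`min(1, 11p)`). The
  published multisystem p-value (0.01893) is reproduced under exactly
  this grouping convention, which the source reports only as "Fisher +
  Bonferroni".
* **Mann–Whitney** uses midranks for ties; for combined samples up to 20
  the two-sided p is exact by enumerating all group assignments of the
  pooled values (p = proportion of assignments with |U − n₁n₂/2| at
  least the observed deviation), otherwise a tie-corrected normal
  approximation with 0.5 continuity correction. The published pLI
  medians (0.81 vs 0.24, p = 0.0276) are **not** reproducible without
  the study's per-variant gene list and a real constraint-metric
  release; the machinery is instead validated by oracle agreement and a
  power property (a 0.5 location shift at n = 50 per group is detected
  at p < 0.01 in ≥95% of replicates).

Yields count fetuses, not variants; a fetus with several diagnostic
findings contributes once, categorised with precedence UPD > de novo >
inherited, and carries a high recurrence risk if any of its findings is
inherited.

## The simulator

`simulate_cohort` emulates the modelled study's conditions: 610 families
(596 trios, 14 dyads) across the eleven phenotype classes at the
published class sizes, with 52 spiked causal diagnoses by default — 30
autosomal de novo, 1 X-linked de novo hemizygous, 1 de novo CNV event,
1 UPD event, 10 inherited homozygous, 4 compound heterozygous, 2
dominant inherited from an affected parent, and 3 pathogenic variants
inherited from unaffected parents that survive only via the whitelist
(one through a gene-level truncating rule, two through exact keys).
This mix reproduces the study's breakdown (32 de novo / 19 inherited /
1 UPD; 33 low / 19 high recurrence).

Background variation is deliberately minimal: allele frequencies follow
a two-point mixture (common ≈ 0.1, rare ≈ 1e-4) because only behaviour
around the filter thresholds matters; parental genotypes are
Hardy-Weinberg draws and fetal genotypes are Mendelian transmissions
(the unsequenced parent of a dyad is simulated but not written).
Background strata are all designed to be excluded — synonymous
consequences, common protein-altering alleles in panel genes, rare
protein-altering alleles only in off-panel genes — so that noiseless
recovery is exact: sensitivity 1.0 and zero false positives are
invariants, not tolerances. Coordinates are synthetic (one pseudo-contig
per autosome plus X), ref/alt are random bases, and pre-exome exclusions
(QF-PCR aneuploidy, microarray CNVs) appear only as manifest counts.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: sequencing and genotyping error (beyond an
optional genotype-flip noise switch, off by default), linkage and
haplotype structure, a realistic site-frequency spectrum, mosaicism,
annotation errors, and pseudo-autosomal inheritance. Identical seeds
produce byte-identical files.

## Numerical and design notes

* Output ordering is deterministic everywhere (family, gene, chromosome,
  position, alt); diagnosis ids are derived from those keys, so reruns
  and shuffled inputs are reproducible.
* Multi-allelic VCF records are split per alternate allele before any
  genotype logic; partially called genotypes count as missing.
* An empty margin in a 2×2 table yields p = 1 by convention; an
  undefined interval bound at k = 0 or k = n is pinned to 0 or 1.
* How multiple variants in one gene collapse into potential diagnoses is
  under-determined in the source (e.g. a fetus carrying three rare
  missense variants in one recessive gene); this package groups per
  (gene, model, variant-set), so such a case yields one diagnosis per
  trans pair.
* The packaged reference decisions record all 52 findings at
  (pathogenic, full): the published table does not print the
  pathogenic/likely-pathogenic tier or the partial/full split per row,
  and the derived statistics depend only on the diagnostic flag.

## Problem sizes

Default test and acceptance runs use the full 610-family cohort for
recovery checks (a few seconds end to end) and an ~8× scaled-down cohort
for the remaining pipeline tests; oracle enumerations run at the sizes
stated above (27 trio genotype combinations, all 2×2 margins ≤ 12,
combined rank-sum samples ≤ 12).
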