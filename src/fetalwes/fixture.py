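"""Packaged reference cohort: the published diagnostic findings table.

The package ships a transcription of the 52 diagnostic findings of the
610-fetus prenatal exome cohort it models (one row per diagnosed fetus,
with phenotype class, gene, consequence, inheritance and zygosity as
printed) together with the printed cohort constants: the eleven phenotype
class sizes, the count of clinically relevant variants of uncertain
significance, and the pregnancy-outcome breakdown.  *Fixture mode* skips
variant-level filtering — the per-variant data are not public — and
recomputes every cohort statistic directly from these classified records.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .classify import read_decisions
from .prioritise import DiagnosisModel
from .stats import (
    CohortSummary,
    EnrichmentResult,
    YieldResult,
    class_enrichment,
    fisher_exact_2x2,
    yield_with_ci,
)

__all__ = [
    "FixtureRecord",
    "load_table1",
    "load_constants",
    "load_table1_decisions",
    "fixture_summary",
]


_DE_NOVO_LABELS = ("De novo", "De novo (presumed)", "De novo (copy number variation)")


@dataclass(frozen=True)
class FixtureRecord:
    """One diagnosed fetus of the reference table."""

    diagnosis_id: str
    phenotype_class: str
    gene: str
    consequence: str
    inheritance: str
    zygosity: str

    @property
    def model(self) -> DiagnosisModel:
        inh, zyg = self.inheritance, self.zygosity
        if inh == "Uniparental disomy":
            return DiagnosisModel.UPD_EVENT
        if inh == "De novo (copy number variation)":
            return DiagnosisModel.CNV_EVENT
        if zyg == "Homozygous":
            return DiagnosisModel.BIALLELIC_HOMOZYGOUS
        if zyg == "Compound heterozygous":
            return DiagnosisModel.BIALLELIC_COMPOUND_HET
        if zyg == "Hemizygous":
            return DiagnosisModel.X_LINKED_HEMIZYGOUS
        if inh in ("De novo", "De novo (presumed)"):
            return DiagnosisModel.MONOALLELIC_DE_NOVO
        return DiagnosisModel.MONOALLELIC_INHERITED

    @property
    def is_de_novo(self) -> bool:
        return self.inheritance in _DE_NOVO_LABELS

    @property
    def recurrence_low(self) -> bool:
        """De novo events and uniparental disomy carry a low recurrence risk."""
        return self.is_de_novo or self.model is DiagnosisModel.UPD_EVENT


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("fetalwes.fixtures") / name))


def load_table1(path: Optional[str | Path] = None) -> list[FixtureRecord]:
    p = Path(path) if path is not None else _fixture_path("table1_fixture.tsv")
    out: list[FixtureRecord] = []
    with p.open(encoding="utf-8") as fh:
        reader = csv.DictReader((l for l in fh if not l.startswith("#")), delimiter="\t")
        for row in reader:
            out.append(
                FixtureRecord(
                    diagnosis_id=row["diagnosis_id"],
                    phenotype_class=row["phenotype_class"],
                    gene=row["gene"],
                    consequence=row["consequence"],
                    inheritance=row["inheritance"],
                    zygosity=row["zygosity"],
                )
            )
    return out


def load_constants(path: Optional[str | Path] = None) -> dict:
    p = Path(path) if path is not None else _fixture_path("cohort_constants.json")
    with p.open(encoding="utf-8") as fh:
        return json.load(fh)


def load_table1_decisions(path: Optional[str | Path] = None):
    p = Path(path) if path is not None else _fixture_path("table1_decisions.tsv")
    return read_decisions(p)


def fixture_summary(level: float = 0.95) -> CohortSummary:
    """Recompute the cohort statistics from the packaged reference table.

    Yields, confidence intervals, the phenotype-class enrichment and the
    outcome association are all computed here from counts — nothing is
    read back from stored results.
    """
    records = load_table1()
    const = load_constants()
    n = const["n_fetuses"]
    class_sizes: dict[str, int] = const["class_sizes"]

    n_diag = len(records)
    overall = yield_with_ci(n_diag, n, level)
    relevant = yield_with_ci(
        n_diag + const["n_clinically_relevant_vus"], n, level
    )

    class_diag = {label: 0 for label in class_sizes}
    for r in records:
        class_diag[r.phenotype_class] += 1
    per_class = {
        label: yield_with_ci(class_diag[label], size, level)
        for label, size in class_sizes.items()
    }
    enrichment = class_enrichment(
        {label: (class_diag[label], size) for label, size in class_sizes.items()}
    )

    n_de_novo = sum(1 for r in records if r.is_de_novo)
    n_upd = sum(1 for r in records if r.model is DiagnosisModel.UPD_EVENT)
    n_inherited = n_diag - n_de_novo - n_upd
    rec_low = sum(1 for r in records if r.recurrence_low)

    oc = const["outcomes"]
    not_survived = oc["known"] - oc["livebirth"]
    a = oc["diagnostic_not_survived"]
    b = not_survived - a
    c = oc["diagnostic_liveborn"]
    d = oc["livebirth"] - c
    outcome_p = fisher_exact_2x2(a, b, c, d)

    return CohortSummary(
        n_families=n,
        n_trios=const["n_trios"],
        n_dyads=const["n_dyads"],
        n_potential_diagnoses=const["n_potential_diagnoses"],
        mean_potential_per_fetus=const["n_potential_diagnoses"] / n,
        overall_yield=overall,
        clinically_relevant_yield=relevant,
        per_class_yield=per_class,
        enrichment=enrichment,
        n_diagnosed_fetuses=n_diag,
        n_de_novo=n_de_novo,
        n_inherited=n_inherited,
        n_upd=n_upd,
        n_recurrence_low=rec_low,
        n_recurrence_high=n_diag - rec_low,
        outcome_table=(a, b, c, d),
        outcome_p=outcome_p,
    )
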