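"""Clinical-review decisions and derived diagnostic status.

Classification of each potential diagnosis (the five-tier pathogenic …
benign scale) and its causal contribution to the fetal phenotype (none,
uncertain, partial, full) are *inputs*: they encode the consensus of a
multidisciplinary clinical review panel applying ACMG-style guidelines,
which this package deliberately does not automate.  From those two axes
the package derives:

* ``diagnostic`` — pathogenic or likely pathogenic AND causative
  (partial or full contribution);
* ``reportable`` — identical to diagnostic under the study's ethics
  framework (non-causative findings are not returned to parents);
* ``recurrence`` — low for de novo events and uniparental disomy, high
  for inherited variants, defined only for diagnostic records.

A variant of uncertain significance may additionally be flagged as
*clinically relevant*, forming the non-diagnostic-but-useful stratum of
the yield statistics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

from .prioritise import DiagnosisModel, PotentialDiagnosis

__all__ = [
    "Classification",
    "Contribution",
    "Recurrence",
    "CRPDecision",
    "ClassifiedDiagnosis",
    "DuplicateDecisionError",
    "UnknownDiagnosisError",
    "read_decisions",
    "write_decisions",
    "apply_decisions",
    "recurrence_risk",
]


class Classification(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


class Contribution(str, Enum):
    NONE = "none"
    UNCERTAIN = "uncertain"
    PARTIAL = "partial"
    FULL = "full"


class Recurrence(str, Enum):
    LOW = "low"
    HIGH = "high"


class DuplicateDecisionError(ValueError):
    """Two conflicting decisions for the same diagnosis id."""


class UnknownDiagnosisError(KeyError):
    """A decision references a diagnosis id that was never emitted."""


@dataclass(frozen=True)
class CRPDecision:
    diagnosis_id: str
    classification: Classification
    contribution: Contribution
    clinically_relevant_vus: bool = False

    def __post_init__(self) -> None:
        if self.clinically_relevant_vus and self.classification is not Classification.VUS:
            raise ValueError(
                "clinically_relevant_vus applies only to VUS classifications"
            )


#: default applied to candidates the review panel has not (yet) decided
UNDECIDED = (Classification.VUS, Contribution.UNCERTAIN)


@dataclass(frozen=True)
class ClassifiedDiagnosis:
    diagnosis: PotentialDiagnosis
    decision: CRPDecision

    @property
    def diagnostic(self) -> bool:
        return (
            self.decision.classification
            in (Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC)
            and self.decision.contribution
            in (Contribution.PARTIAL, Contribution.FULL)
        )

    @property
    def reportable(self) -> bool:
        return self.diagnostic

    @property
    def clinically_relevant_vus(self) -> bool:
        return self.decision.clinically_relevant_vus

    @property
    def recurrence(self) -> Recurrence:
        return recurrence_risk(self)


def recurrence_risk(classified: ClassifiedDiagnosis) -> Recurrence:
    """Recurrence-risk category of a diagnostic finding.

    De novo events — point mutations, presumed de novo calls, de novo
    CNVs — and uniparental disomy carry a low recurrence risk (gonadal
    mosaicism aside); anything inherited carries a high one.
    """
    if not classified.diagnostic:
        raise ValueError("recurrence risk is defined only for diagnostic records")
    d = classified.diagnosis
    if d.model is DiagnosisModel.UPD_EVENT:
        return Recurrence.LOW
    if all(call.is_de_novo for _, call in d.variants):
        return Recurrence.LOW
    return Recurrence.HIGH


def read_decisions(path: str | Path) -> list[CRPDecision]:
    """Read a tab-separated decisions table.

    Columns: ``diagnosis_id  classification  contribution
    clinically_relevant_vus`` (the last one ``true``/``false``).
    """
    out: list[CRPDecision] = []
    with Path(path).open(encoding="utf-8") as fh:
        reader = csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t"
        )
        required = {"diagnosis_id", "classification", "contribution"}
        if reader.fieldnames is None:
            return out
        if not required <= set(reader.fieldnames):
            raise ValueError(
                f"decisions file {path} must name columns {sorted(required)}"
            )
        for row in reader:
            out.append(
                CRPDecision(
                    diagnosis_id=row["diagnosis_id"].strip(),
                    classification=Classification(row["classification"].strip()),
                    contribution=Contribution(row["contribution"].strip()),
                    clinically_relevant_vus=(
                        (row.get("clinically_relevant_vus") or "false").strip().lower()
                        == "true"
                    ),
                )
            )
    return out


def write_decisions(decisions: Sequence[CRPDecision], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["diagnosis_id", "classification", "contribution", "clinically_relevant_vus"]
        )
        for d in decisions:
            w.writerow(
                [
                    d.diagnosis_id, d.classification.value, d.contribution.value,
                    str(d.clinically_relevant_vus).lower(),
                ]
            )


def apply_decisions(
    diagnoses: Sequence[PotentialDiagnosis],
    decisions: Sequence[CRPDecision],
    strict: bool = True,
) -> list[ClassifiedDiagnosis]:
    """Join review decisions onto potential diagnoses.

    Candidates without a decision default to (VUS, uncertain) so that
    pipeline accounting is conserved: the review panel saw every
    candidate, and a missing row is an operator gap, not evidence of
    benignity.  With ``strict`` (default), a decision whose id matches no
    candidate raises :class:`UnknownDiagnosisError`; conflicting duplicate
    decisions always raise.
    """
    by_id: dict[str, CRPDecision] = {}
    for dec in decisions:
        prev = by_id.get(dec.diagnosis_id)
        if prev is not None and prev != dec:
            raise DuplicateDecisionError(
                f"conflicting decisions for {dec.diagnosis_id!r}"
            )
        by_id[dec.diagnosis_id] = dec

    known = {d.diagnosis_id for d in diagnoses}
    if strict:
        unknown = set(by_id) - known
        if unknown:
            raise UnknownDiagnosisError(
                f"decisions reference unknown diagnosis ids: {sorted(unknown)[:5]}"
            )

    out: list[ClassifiedDiagnosis] = []
    for diag in diagnoses:
        dec = by_id.get(diag.diagnosis_id)
        if dec is None:
            dec = CRPDecision(diag.diagnosis_id, *UNDECIDED)
        out.append(ClassifiedDiagnosis(diagnosis=diag, decision=dec))
    return out
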