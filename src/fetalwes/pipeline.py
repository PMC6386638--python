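"""End-to-end orchestration: read, prioritise, classify, summarise.

``run_pipeline`` ties the stages together and writes the candidate table,
the classified table, a JSON cohort summary, and a per-stage accounting
log whose counters conserve (every input variant is either kept or
excluded for exactly one reason).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .classify import ClassifiedDiagnosis, apply_decisions, read_decisions
from .families import read_cohort_variants, read_pedigree
from .panel import read_panel
from .prioritise import (
    FilterConfig,
    PotentialDiagnosis,
    prioritise_cohort,
    read_whitelist,
    write_candidate_table,
)
from .stats import CohortSummary, read_outcomes, summarise_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    panel: Path
    pedigree: Path
    vcf: Path
    outdir: Path
    whitelist: Optional[Path] = None
    decisions: Optional[Path] = None
    outcomes: Optional[Path] = None
    filter_config: FilterConfig = FilterConfig()

    def __post_init__(self) -> None:
        for name in ("panel", "pedigree", "vcf", "whitelist", "decisions", "outcomes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def _write_classified_table(
    classified: list[ClassifiedDiagnosis], path: Path
) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "diagnosis_id", "family_id", "gene", "model", "classification",
                "contribution", "diagnostic", "reportable",
                "clinically_relevant_vus", "recurrence",
            ]
        )
        for c in classified:
            w.writerow(
                [
                    c.diagnosis.diagnosis_id, c.diagnosis.family_id,
                    c.diagnosis.gene or "NA", c.diagnosis.model.value,
                    c.decision.classification.value, c.decision.contribution.value,
                    str(c.diagnostic).lower(), str(c.reportable).lower(),
                    str(c.clinically_relevant_vus).lower(),
                    c.recurrence.value if c.diagnostic else "",
                ]
            )


def run_pipeline(config: RunConfig) -> CohortSummary:
    """Run every stage and write outputs under ``config.outdir``.

    Stage failures are re-raised as :class:`PipelineError` with the stage
    name so the command line can exit non-zero with a useful message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    panel = stage("read_panel", read_panel, config.panel)
    families = stage("read_pedigree", read_pedigree, config.pedigree)
    counters: dict[str, int] = {}
    variants = stage(
        "read_cohort_variants", read_cohort_variants, config.vcf, families,
        warning_counter=counters,
    )
    whitelist = (
        stage("read_whitelist", read_whitelist, config.whitelist)
        if config.whitelist
        else None
    )
    diagnoses: list[PotentialDiagnosis] = stage(
        "prioritise", prioritise_cohort,
        variants, families, panel, whitelist, config.filter_config, counters,
    )
    decisions = (
        stage("read_decisions", read_decisions, config.decisions)
        if config.decisions
        else []
    )
    classified = stage("apply_decisions", apply_decisions, diagnoses, decisions)
    outcomes = (
        stage("read_outcomes", read_outcomes, config.outcomes)
        if config.outcomes
        else None
    )
    summary = stage("summarise", summarise_cohort, classified, families, outcomes)

    write_candidate_table(diagnoses, outdir / "candidates.tsv")
    _write_classified_table(classified, outdir / "classified.tsv")
    with (outdir / "summary.json").open("w", encoding="utf-8") as fh:
        json.dump(summary.as_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with (outdir / "counters.json").open("w", encoding="utf-8") as fh:
        json.dump(counters, fh, indent=1, sort_keys=True)
        fh.write("\n")
    for key in sorted(counters):
        logger.info("counter %s=%d", key, counters[key])
    return summary
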