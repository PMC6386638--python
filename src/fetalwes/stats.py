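"""Cohort-level diagnostic-yield statistics.

Diagnostic yield is reported as an exact binomial proportion with a
Clopper–Pearson 95% confidence interval (the interval obtained by
inverting binomial tail probabilities, computed here through the beta
quantile identity).  Phenotype-class enrichment uses a two-sided Fisher's
exact test per class against all remaining classes, with Bonferroni
correction across the eleven classes; the two-sided p-value follows the
probability-mass convention (sum of all tables no more probable than the
observed one), as in the mainstream statistical environments.
Loss-of-function-intolerance (pLI) comparisons between diagnostic and
non-diagnostic genes use the Mann–Whitney rank-sum test with midranks for
ties: exact by enumeration for small samples, a tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .classify import ClassifiedDiagnosis, Recurrence
from .families import FamilyUnit, PhenotypeClass
from .prioritise import DiagnosisModel

__all__ = [
    "YieldResult",
    "EnrichmentResult",
    "Outcome",
    "CohortSummary",
    "yield_with_ci",
    "fisher_exact_2x2",
    "class_enrichment",
    "mann_whitney_pli",
    "read_outcomes",
    "summarise_cohort",
]


@dataclass(frozen=True)
class YieldResult:
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def as_dict(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "proportion": self.proportion,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
        }

    @property
    def percent(self) -> float:
        """Proportion as a percentage rounded to one decimal, for display."""
        return round(100.0 * self.proportion, 1)


def yield_with_ci(k: int, n: int, level: float = 0.95) -> YieldResult:
    """Exact (Clopper–Pearson) binomial proportion with confidence interval.

    The lower bound solves ``P(X >= k | p) = alpha/2`` and the upper bound
    ``P(X <= k | p) = alpha/2``; both are beta distribution quantiles.
    Boundary cases: ``ci_low = 0`` when ``k = 0`` and ``ci_high = 1`` when
    ``k = n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return YieldResult(k, n, k / n, lo, hi, level)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Two-sidedness follows the probability-mass rule: the p-value sums the
    hypergeometric probabilities of every table with the same margins
    whose probability does not exceed that of the observed table.  An
    empty margin gives p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-class Fisher enrichment with Bonferroni adjustment."""

    classes: tuple[str, ...]
    diagnostic: tuple[int, ...]
    sizes: tuple[int, ...]
    raw_p: tuple[float, ...]
    adjusted_p: tuple[float, ...]
    correction: str = "bonferroni"

    @property
    def k(self) -> int:
        return len(self.classes)

    def for_class(self, name: str) -> dict:
        i = self.classes.index(name)
        return {
            "class": name,
            "diagnostic": self.diagnostic[i],
            "size": self.sizes[i],
            "raw_p": self.raw_p[i],
            "adjusted_p": self.adjusted_p[i],
        }

    def as_dict(self) -> dict:
        return {
            "correction": self.correction,
            "k": self.k,
            "classes": [self.for_class(c) for c in self.classes],
        }


def class_enrichment(per_class: dict[str, tuple[int, int]]) -> EnrichmentResult:
    """One-vs-rest Fisher's exact test per phenotype class.

    ``per_class`` maps class label to (diagnostic count, class size).  For
    each class the 2x2 table is (class diagnostic, class non-diagnostic)
    vs (rest diagnostic, rest non-diagnostic); Bonferroni adjustment
    multiplies by the number of classes and caps at 1.
    """
    labels = list(per_class)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate class labels")
    total_k = sum(v[0] for v in per_class.values())
    total_n = sum(v[1] for v in per_class.values())
    raws: list[float] = []
    for label in labels:
        k_c, n_c = per_class[label]
        if k_c > n_c:
            raise ValueError(f"class {label}: diagnostic count exceeds class size")
        raws.append(
            fisher_exact_2x2(
                k_c, n_c - k_c, total_k - k_c, (total_n - n_c) - (total_k - k_c)
            )
        )
    k = len(labels)
    adj = [min(1.0, p * k) for p in raws]
    return EnrichmentResult(
        classes=tuple(labels),
        diagnostic=tuple(per_class[l][0] for l in labels),
        sizes=tuple(per_class[l][1] for l in labels),
        raw_p=tuple(raws),
        adjusted_p=tuple(adj),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney with midranks
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 20  # combined sample size up to which the exact p is enumerated


def _rank_sum_u(ranks_a: np.ndarray, n1: int) -> float:
    return float(ranks_a.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_pli(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """(median_a, median_b, two-sided p) for a rank-sum comparison.

    Ties receive midranks.  For combined sample sizes up to 20 the p-value
    is exact: every assignment of the pooled observations to the two
    groups is enumerated and the two-sided p is the proportion of
    assignments whose U statistic lies at least as far from its null mean
    as the observed one.  Larger samples use the normal approximation with
    tie-corrected variance and a 0.5 continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = _rank_sum_u(ranks[:n1], n1)
    mu = n1 * n2 / 2.0

    if n <= _EXACT_LIMIT:
        dev_obs = abs(u_obs - mu) - 1e-12
        hits = 0
        total = 0
        for idx in combinations(range(n), n1):
            u = _rank_sum_u(ranks[list(idx)], n1)
            if abs(u - mu) >= dev_obs:
                hits += 1
            total += 1
        p = hits / total
    else:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
            z = max(z, 0.0)
            p = float(2.0 * sps.norm.sf(z))
    return float(np.median(a)), float(np.median(b)), min(p, 1.0)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------


class Outcome(str, Enum):
    TERMINATION = "termination"
    MISCARRIAGE = "miscarriage"
    STILLBIRTH = "stillbirth"
    NEONATAL_DEATH = "neonatal_death"
    LIVEBIRTH = "livebirth"
    UNKNOWN = "unknown"

    @property
    def known(self) -> bool:
        return self is not Outcome.UNKNOWN

    @property
    def survived(self) -> bool:
        """True for livebirths; meaningful only when the outcome is known."""
        return self is Outcome.LIVEBIRTH


def read_outcomes(path: str | Path) -> dict[str, Outcome]:
    """Tab-separated ``family_id outcome`` table (header optional)."""
    out: dict[str, Outcome] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("family_id"):
                continue
            fam, outcome = line.split("\t")
            out[fam] = Outcome(outcome)
    return out


@dataclass
class CohortSummary:
    """Every cohort-level quantity derived from the classified diagnoses."""

    n_families: int
    n_trios: int
    n_dyads: int
    n_potential_diagnoses: int
    mean_potential_per_fetus: float
    overall_yield: YieldResult
    clinically_relevant_yield: YieldResult
    per_class_yield: dict[str, YieldResult]
    enrichment: EnrichmentResult
    n_diagnosed_fetuses: int
    n_de_novo: int
    n_inherited: int
    n_upd: int
    n_recurrence_low: int
    n_recurrence_high: int
    outcome_table: Optional[tuple[int, int, int, int]] = None
    outcome_p: Optional[float] = None
    pli_comparison: Optional[tuple[float, float, float]] = None

    def as_dict(self) -> dict:
        return {
            "n_families": self.n_families,
            "n_trios": self.n_trios,
            "n_dyads": self.n_dyads,
            "n_potential_diagnoses": self.n_potential_diagnoses,
            "mean_potential_per_fetus": self.mean_potential_per_fetus,
            "overall_yield": self.overall_yield.as_dict(),
            "clinically_relevant_yield": self.clinically_relevant_yield.as_dict(),
            "per_class_yield": {
                k: v.as_dict() for k, v in self.per_class_yield.items()
            },
            "enrichment": self.enrichment.as_dict(),
            "n_diagnosed_fetuses": self.n_diagnosed_fetuses,
            "breakdown": {
                "de_novo": self.n_de_novo,
                "inherited": self.n_inherited,
                "upd": self.n_upd,
            },
            "recurrence": {
                "low": self.n_recurrence_low,
                "high": self.n_recurrence_high,
            },
            "outcome_table": self.outcome_table,
            "outcome_p": self.outcome_p,
            "pli_comparison": self.pli_comparison,
        }


def _fetus_category(diagnostics: list[ClassifiedDiagnosis]) -> str:
    """Categorise a diagnosed fetus as de_novo / inherited / upd.

    A fetus with several diagnostic findings (rare) is categorised by
    precedence UPD > de novo > inherited, mirroring how event-level
    findings are reported.
    """
    if any(c.diagnosis.model is DiagnosisModel.UPD_EVENT for c in diagnostics):
        return "upd"
    if any(c.diagnosis.is_de_novo for c in diagnostics):
        return "de_novo"
    return "inherited"


def summarise_cohort(
    classified: Sequence[ClassifiedDiagnosis],
    families: Sequence[FamilyUnit],
    outcomes: Optional[dict[str, Outcome]] = None,
    pli_groups: Optional[tuple[Sequence[float], Sequence[float]]] = None,
    level: float = 0.95,
) -> CohortSummary:
    """Aggregate classified diagnoses into the cohort summary.

    Yields count *fetuses*, not variants: a fetus with several diagnostic
    findings contributes once.  The outcome association is the 2x2 table
    (diagnostic vs not) x (did not survive beyond birth vs liveborn)
    restricted to families with a known outcome.
    """
    fam_by_id = {f.family_id: f for f in families}
    for c in classified:
        if c.diagnosis.family_id not in fam_by_id:
            raise KeyError(
                f"diagnosis references unknown family {c.diagnosis.family_id!r}"
            )
    n = len(families)
    n_trios = sum(1 for f in families if f.is_trio)

    per_fetus: dict[str, list[ClassifiedDiagnosis]] = {}
    for c in classified:
        per_fetus.setdefault(c.diagnosis.family_id, []).append(c)

    diagnosed: dict[str, list[ClassifiedDiagnosis]] = {
        fid: [c for c in cs if c.diagnostic]
        for fid, cs in per_fetus.items()
    }
    diagnosed = {fid: cs for fid, cs in diagnosed.items() if cs}
    crv_fetuses = {
        fid
        for fid, cs in per_fetus.items()
        if fid not in diagnosed and any(c.clinically_relevant_vus for c in cs)
    }

    n_diag = len(diagnosed)
    overall = yield_with_ci(n_diag, n, level)
    relevant = yield_with_ci(n_diag + len(crv_fetuses), n, level)

    class_sizes: dict[str, int] = {c.value: 0 for c in PhenotypeClass}
    for f in families:
        class_sizes[f.phenotype_class.value] += 1
    class_diag: dict[str, int] = {c.value: 0 for c in PhenotypeClass}
    for fid in diagnosed:
        class_diag[fam_by_id[fid].phenotype_class.value] += 1
    per_class_yield = {
        label: yield_with_ci(class_diag[label], size, level)
        for label, size in class_sizes.items()
        if size > 0
    }
    enrichment = class_enrichment(
        {label: (class_diag[label], size) for label, size in class_sizes.items() if size > 0}
    )

    cats = {fid: _fetus_category(cs) for fid, cs in diagnosed.items()}
    n_de_novo = sum(1 for v in cats.values() if v == "de_novo")
    n_inherited = sum(1 for v in cats.values() if v == "inherited")
    n_upd = sum(1 for v in cats.values() if v == "upd")

    rec_low = rec_high = 0
    for fid, cs in diagnosed.items():
        risks = {c.recurrence for c in cs}
        # a fetus with any inherited diagnostic finding has a high
        # recurrence risk overall
        if Recurrence.HIGH in risks:
            rec_high += 1
        else:
            rec_low += 1

    outcome_table = None
    outcome_p = None
    if outcomes is not None:
        a = b = c_ = d = 0
        for f in families:
            o = outcomes.get(f.family_id, Outcome.UNKNOWN)
            if not o.known:
                continue
            is_diag = f.family_id in diagnosed
            if not o.survived:
                if is_diag:
                    a += 1
                else:
                    b += 1
            else:
                if is_diag:
                    c_ += 1
                else:
                    d += 1
        outcome_table = (a, b, c_, d)
        outcome_p = fisher_exact_2x2(a, b, c_, d)

    pli_cmp = None
    if pli_groups is not None:
        pli_cmp = mann_whitney_pli(*pli_groups)

    return CohortSummary(
        n_families=n,
        n_trios=n_trios,
        n_dyads=n - n_trios,
        n_potential_diagnoses=len(classified),
        mean_potential_per_fetus=len(classified) / n if n else 0.0,
        overall_yield=overall,
        clinically_relevant_yield=relevant,
        per_class_yield=per_class_yield,
        enrichment=enrichment,
        n_diagnosed_fetuses=n_diag,
        n_de_novo=n_de_novo,
        n_inherited=n_inherited,
        n_upd=n_upd,
        n_recurrence_low=rec_low,
        n_recurrence_high=rec_high,
        outcome_table=outcome_table,
        outcome_p=outcome_p,
        pli_comparison=pli_cmp,
    )
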