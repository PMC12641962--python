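"""Stepwise High / Moderate / Low triage of germline BRCA2 variants.

The rubric integrates four evidence channels into an ordered priority level
(Low < Moderate < High) intended to rank variants for follow-up, not to
assert pathogenicity:

1. truncating rule — frameshift and stop-gained variants are High outright;
2. domain escalation — a missense change inside a functionally critical
   domain (BRC repeats, DNA-binding domain, terminal DBD) gains one level;
3. predictor escalation — concordant adverse calls from SIFT (<= 0.05) and
   PolyPhen-2 (>= 0.85) gain one level; a single adverse call also gains
   one level but caps the result at Moderate;
4. ClinVar escalation — any Pathogenic / Likely pathogenic assertion in the
   aggregate (including labels inside "conflicting" aggregates) gains one
   level, with High as the ceiling.

Every decision is recorded in a six-entry ledger from which the level can
be recomputed, so each assignment is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Optional, Sequence

from .domains import DomainAssignment, DomainCategory
from .predictions import PredictionProfile
from .variants import Consequence, VariantRecord, VariantTable

__all__ = [
    "PriorityLevel",
    "ClinvarEvidence",
    "LedgerEntry",
    "PriorityResult",
    "RubricInputError",
    "RULES",
    "assign_priority",
    "level_from_ledger",
    "prioritize_table",
]

RULES = (
    "truncating_rule",
    "domain_escalation",
    "predictor_escalation",
    "single_predictor_cap",
    "clinvar_escalation",
    "high_cap",
)

_PATH_LABELS = {"pathogenic", "likely pathogenic", "probably pathogenic"}


class RubricInputError(ValueError):
    """Raised when an evidence channel is missing for a variant."""


class PriorityLevel(IntEnum):
    LOW = 0
    MODERATE = 1
    HIGH = 2

    def __str__(self) -> str:
        return self.name.capitalize()


@dataclass(frozen=True)
class ClinvarEvidence:
    """The set of ClinVar assertion labels attached to a variant."""

    labels: frozenset[str]

    @property
    def has_path_or_likely(self) -> bool:
        return any(l.strip().lower() in _PATH_LABELS for l in self.labels)

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "ClinvarEvidence":
        return cls(frozenset(labels))

    @classmethod
    def from_variant(cls, record: VariantRecord) -> "ClinvarEvidence":
        return cls(frozenset(record.clinvar_aggregate))


@dataclass(frozen=True)
class LedgerEntry:
    rule: str
    applied: bool
    note: str


@dataclass(frozen=True)
class PriorityResult:
    level: PriorityLevel
    ledger: tuple[LedgerEntry, ...]

    def __post_init__(self) -> None:
        assert tuple(e.rule for e in self.ledger) == RULES


def assign_priority(
    variant: VariantRecord,
    assignment: DomainAssignment,
    profile: PredictionProfile,
    clinvar: ClinvarEvidence,
) -> PriorityResult:
    """Apply the stepwise rubric to one variant.

    All four evidence channels are mandatory, even when their content is
    "unknown"; pass :data:`varprio.predictions.UNKNOWN_PROFILE` for variants
    without predictor scores.
    """
    if assignment is None or profile is None or clinvar is None:
        raise RubricInputError(f"{variant.key}: rubric requires all evidence channels")
    ledger: list[LedgerEntry] = []
    consequence = variant.protein_change.consequence
    truncating = consequence in (Consequence.FRAMESHIFT, Consequence.STOP_GAINED)
    ledger.append(
        LedgerEntry(
            "truncating_rule",
            truncating,
            f"consequence={consequence.value}"
            + ("; classified High outright" if truncating else ""),
        )
    )
    if truncating:
        # Remaining channels are recorded as not applied for auditability.
        for rule in RULES[1:]:
            ledger.append(LedgerEntry(rule, False, "not reached (truncating)"))
        return PriorityResult(PriorityLevel.HIGH, tuple(ledger))

    rank = 0
    domain_hit = assignment.in_critical_domain
    if domain_hit:
        rank += 1
        note = f"inside critical domain {assignment.domain.name!r} (+1)"
    elif assignment.category is DomainCategory.INSIDE:
        note = f"inside non-critical domain {assignment.domain.name!r}"
    else:
        note = f"category={assignment.category.value}"
    ledger.append(LedgerEntry("domain_escalation", domain_hit, note))

    concordant = profile.concordant
    single = profile.single_evidence
    if concordant:
        rank += 1
        pred_note = "SIFT deleterious and PolyPhen damaging (+1)"
    else:
        pred_note = (
            f"sift_call={profile.sift_call.value}, "
            f"polyphen_call={profile.polyphen_call.value}"
        )
    ledger.append(LedgerEntry("predictor_escalation", concordant, pred_note))
    if single:
        rank += 1
        cap_note = "exactly one adverse predictor (+1, capped at Moderate)"
    else:
        cap_note = "no single-predictor cap"
    ledger.append(LedgerEntry("single_predictor_cap", single, cap_note))

    clinvar_hit = clinvar.has_path_or_likely
    ledger.append(
        LedgerEntry(
            "clinvar_escalation",
            clinvar_hit,
            "ClinVar pathogenic/likely pathogenic assertion (+1)"
            if clinvar_hit
            else "no pathogenic/likely pathogenic ClinVar assertion",
        )
    )
    if clinvar_hit:
        rank += 1

    if single:
        rank = min(rank, PriorityLevel.MODERATE)
    clamped = rank > PriorityLevel.HIGH
    ledger.append(
        LedgerEntry(
            "high_cap",
            clamped,
            "clamped to High" if clamped else "within range",
        )
    )
    level = PriorityLevel(min(rank, PriorityLevel.HIGH))
    return PriorityResult(level, tuple(ledger))


def level_from_ledger(ledger: Sequence[LedgerEntry]) -> PriorityLevel:
    """Recompute the priority level from the rule trace alone."""
    applied = {e.rule: e.applied for e in ledger}
    if applied["truncating_rule"]:
        return PriorityLevel.HIGH
    rank = sum(
        applied[rule]
        for rule in (
            "domain_escalation",
            "predictor_escalation",
            "single_predictor_cap",
            "clinvar_escalation",
        )
    )
    if applied["single_predictor_cap"]:
        rank = min(rank, PriorityLevel.MODERATE)
    return PriorityLevel(min(rank, PriorityLevel.HIGH))


@dataclass(frozen=True)
class PriorityRow:
    variant: VariantRecord
    assignment: DomainAssignment
    profile: PredictionProfile
    clinvar: ClinvarEvidence
    result: PriorityResult


@dataclass(frozen=True)
class PriorityReport:
    rows: tuple[PriorityRow, ...]

    @property
    def counts_by_level(self) -> dict[PriorityLevel, int]:
        counts = {lvl: 0 for lvl in PriorityLevel}
        for row in self.rows:
            counts[row.result.level] += 1
        return counts

    def levels(self) -> dict[str, PriorityLevel]:
        return {row.variant.key: row.result.level for row in self.rows}


def prioritize_table(
    table: VariantTable,
    assignments: Mapping[str, DomainAssignment],
    profiles: Mapping[str, PredictionProfile],
    clinvar: Optional[Mapping[str, ClinvarEvidence]] = None,
) -> PriorityReport:
    """Apply the rubric to every catalogued variant.

    ``clinvar`` defaults to evidence derived from each record's own
    aggregate label set.  Rows are ordered High -> Low, then by protein
    position (a stable, reproducible sort).
    """
    if clinvar is None:
        clinvar = {rec.key: ClinvarEvidence.from_variant(rec) for rec in table}
    missing: list[str] = []
    for rec in table:
        if rec.key not in assignments or rec.key not in profiles or rec.key not in clinvar:
            missing.append(rec.key)
    if missing:
        raise RubricInputError(f"missing evidence for variant keys: {missing}")
    rows = [
        PriorityRow(
            rec,
            assignments[rec.key],
            profiles[rec.key],
            clinvar[rec.key],
            assign_priority(rec, assignments[rec.key], profiles[rec.key], clinvar[rec.key]),
        )
        for rec in table
    ]
    rows.sort(key=lambda r: (-int(r.result.level), r.variant.protein_change.position))
    return PriorityReport(tuple(rows))
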