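"""The stepwise High/Moderate/Low triage rubric."""

import numpy as np
import pytest

import varprio as vp
from varprio.domains import DomainAnnotation, DomainAssignment, DomainCategory
from varprio.predictions import RawScores, classify, UNKNOWN_PROFILE
from varprio.rubric import (
    ClinvarEvidence,
    PriorityLevel,
    RubricInputError,
    assign_priority,
    level_from_ledger,
    prioritize_table,
)
from varprio.variants import AminoAcid, Consequence, ProteinChange, VariantRecord, VariantTable

CRITICAL = DomainAnnotation("crit", 10, 20, critical=True)
NONCRITICAL = DomainAnnotation("tail", 30, 40, critical=False)

INSIDE_CRITICAL = DomainAssignment(CRITICAL, DomainCategory.INSIDE, 0)
INSIDE_NONCRITICAL = DomainAssignment(NONCRITICAL, DomainCategory.INSIDE, 0)
BOUNDARY = DomainAssignment(CRITICAL, DomainCategory.BOUNDARY, 2)
OUTSIDE = DomainAssignment(None, DomainCategory.OUTSIDE, 99)

VUS = ClinvarEvidence.from_labels(["Uncertain significance"])
PLP = ClinvarEvidence.from_labels(["Pathogenic"])
CONFLICTING_PLP = ClinvarEvidence.from_labels(["Uncertain significance", "Likely pathogenic"])


def missense(position=15):
    return VariantRecord(
        "c.1A>G", ProteinChange(AminoAcid("Leu"), position, AminoAcid("Arg"),
                                Consequence.MISSENSE),
        None, 1, 0, "VUS",
    )


def frameshift():
    return VariantRecord(
        "c.1dup", ProteinChange(AminoAcid("Gln"), 15, None, Consequence.FRAMESHIFT),
        None, 1, 0, "Pathogenic",
    )


CONCORDANT = classify(RawScores(0.0, 0.95))
SINGLE_SIFT = classify(RawScores(0.02, 0.3))
BENIGN = classify(RawScores(0.4, 0.1))


class TestAssignPriority:
    def test_truncating_is_high_regardless(self):
        res = assign_priority(frameshift(), OUTSIDE, UNKNOWN_PROFILE, VUS)
        assert res.level is PriorityLevel.HIGH
        assert res.ledger[0].applied

    @pytest.mark.parametrize(
        "assignment, profile, clinvar, expected",
        [
            # critical domain + concordant predictors + ClinVar LP -> High
            (INSIDE_CRITICAL, CONCORDANT, CONFLICTING_PLP, PriorityLevel.HIGH),
            # critical domain + one predictor -> capped at Moderate
            (INSIDE_CRITICAL, SINGLE_SIFT, VUS, PriorityLevel.MODERATE),
            # outside + one predictor -> Moderate (the +1 precedes the cap)
            (OUTSIDE, SINGLE_SIFT, VUS, PriorityLevel.MODERATE),
            # no evidence at all -> Low
            (OUTSIDE, UNKNOWN_PROFILE, VUS, PriorityLevel.LOW),
            # boundary localization never escalates
            (BOUNDARY, BENIGN, VUS, PriorityLevel.LOW),
            # non-critical domain never escalates
            (INSIDE_NONCRITICAL, UNKNOWN_PROFILE, VUS, PriorityLevel.LOW),
            # ClinVar alone lifts Low to Moderate
            (OUTSIDE, UNKNOWN_PROFILE, PLP, PriorityLevel.MODERATE),
            # critical domain + concordant predictors -> High even without ClinVar
            (INSIDE_CRITICAL, CONCORDANT, VUS, PriorityLevel.HIGH),
        ],
    )
    def test_missense_paths(self, assignment, profile, clinvar, expected):
        assert assign_priority(missense(), assignment, profile, clinvar).level is expected

    def test_ledger_lists_all_six_rules(self):
        res = assign_priority(missense(), INSIDE_CRITICAL, SINGLE_SIFT, VUS)
        assert [e.rule for e in res.ledger] == list(vp.rubric.RULES)

    def test_missing_channel_is_an_error(self):
        with pytest.raises(RubricInputError):
            assign_priority(missense(), None, UNKNOWN_PROFILE, VUS)

    def test_conflicting_aggregate_counts_as_plp(self):
        assert CONFLICTING_PLP.has_path_or_likely
        assert not VUS.has_path_or_likely
        assert not ClinvarEvidence.from_labels(["Likely benign", "Benign"]).has_path_or_likely


class TestStudyCatalogue:
    EXPECTED = {
        "rs80359380": PriorityLevel.HIGH,
        "rs80359479": PriorityLevel.HIGH,
        "rs878853569": PriorityLevel.HIGH,
        "rs398122715": PriorityLevel.HIGH,
        "rs397507422": PriorityLevel.HIGH,
        "rs11571658": PriorityLevel.HIGH,
        "rs587782313": PriorityLevel.HIGH,
        "rs80359219": PriorityLevel.MODERATE,
        "rs1064795067": PriorityLevel.MODERATE,
        "rs587780646": PriorityLevel.MODERATE,
        "rs775030825": PriorityLevel.MODERATE,
        "rs1329182873": PriorityLevel.LOW,
        "c.9812T>C": PriorityLevel.LOW,
    }

    def test_published_levels_reproduced_rowwise(self, priority_report):
        assert priority_report.levels() == self.EXPECTED

    def test_level_counts(self, priority_report):
        counts = priority_report.counts_by_level
        assert counts[PriorityLevel.HIGH] == 7
        assert counts[PriorityLevel.MODERATE] == 4
        assert counts[PriorityLevel.LOW] == 2

    def test_report_sorted_high_to_low_then_position(self, priority_report):
        keys = [
            (-int(r.result.level), r.variant.protein_change.position)
            for r in priority_report.rows
        ]
        assert keys == sorted(keys)

    def test_withholding_predictions_never_raises_levels(
        self, study_table, study_assignments, priority_report
    ):
        blank = {k: UNKNOWN_PROFILE for k in study_table.keys}
        degraded = prioritize_table(study_table, study_assignments, blank)
        for key, level in degraded.levels().items():
            assert level <= priority_report.levels()[key]
            rec = study_table.get(key)
            if (
                rec.protein_change.consequence is Consequence.MISSENSE
                and not vp.ClinvarEvidence.from_variant(rec).has_path_or_likely
            ):
                # domain evidence alone cannot exceed Moderate
                assert level <= PriorityLevel.MODERATE

    def test_key_mismatch_lists_missing(self, study_table, study_assignments):
        with pytest.raises(RubricInputError, match="rs80359380"):
            prioritize_table(study_table, study_assignments, {})

    def test_empty_table(self):
        report = prioritize_table(VariantTable([]), {}, {})
        assert report.rows == ()


def _random_inputs(rng):
    consequence = list(Consequence)[rng.integers(3)]
    change = (
        ProteinChange(AminoAcid("Leu"), int(rng.integers(1, 3419)), AminoAcid("Arg"),
                      Consequence.MISSENSE)
        if consequence == Consequence.MISSENSE
        else ProteinChange(
            AminoAcid("Leu"), int(rng.integers(1, 3419)),
            AminoAcid("Ter") if consequence == Consequence.STOP_GAINED else None,
            Consequence(consequence),
        )
    )
    variant = VariantRecord("c.1A>G", change, None, 1, 0, "VUS")
    assignment = [INSIDE_CRITICAL, INSIDE_NONCRITICAL, BOUNDARY, OUTSIDE][rng.integers(4)]
    sift = None if rng.random() < 0.3 else float(rng.random())
    poly = None if rng.random() < 0.3 else float(rng.random())
    profile = classify(RawScores(sift, poly))
    clinvar = [VUS, PLP, CONFLICTING_PLP, ClinvarEvidence.from_labels([])][rng.integers(4)]
    return variant, assignment, profile, clinvar


class TestProperties:
    def test_monotonicity_caps_and_ledger_audit_over_random_variants(self):
        """Over 1,000 seeded random evidence combinations: adding adverse
        evidence never lowers the level, the single-predictor cap holds,
        truncating variants are always High, and the level is recomputable
        from the ledger alone."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            variant, assignment, profile, clinvar = _random_inputs(rng)
            res = assign_priority(variant, assignment, profile, clinvar)
            # ledger audit
            assert level_from_ledger(res.ledger) is res.level
            truncating = variant.protein_change.consequence is not Consequence.MISSENSE
            if truncating:
                assert res.level is PriorityLevel.HIGH
                continue
            # cap soundness
            if profile.single_evidence:
                assert res.level <= PriorityLevel.MODERATE
            # monotone in ClinVar: removing P/LP never raises
            without_clinvar = assign_priority(
                variant, assignment, profile, ClinvarEvidence.from_labels([])
            )
            assert without_clinvar.level <= res.level
            # monotone in predictors: adding a concordant adverse pair never lowers
            boosted = assign_priority(variant, assignment, CONCORDANT, clinvar)
            if not profile.single_evidence:
                assert boosted.level >= res.level
            # monotone in domain: critical localization never lowers
            in_domain = assign_priority(variant, INSIDE_CRITICAL, profile, clinvar)
            assert in_domain.level >= assign_priority(variant, OUTSIDE, profile, clinvar).level
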