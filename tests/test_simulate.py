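"""Synthetic cohort and panel generation: determinism, closure, recovery."""

import numpy as np
import pandas as pd
import pytest

import varprio as vp
from varprio.simulate import (
    CohortSpec,
    PanelSpec,
    SpecError,
    default_cohort_spec,
    default_panel_spec,
    generate_cohort,
    generate_panel,
    write_cohort,
    write_panel,
)


class TestCohortGeneration:
    def test_default_cohort_shape(self):
        df = generate_cohort(default_cohort_spec(seed=1))
        assert len(df) == 140
        assert df.group.value_counts().to_dict() == {"BC": 116, "OC": 19, "BC+OC": 5}
        assert (df.age >= 18).all()

    def test_expected_carrier_count_across_seeds(self):
        counts = [
            int(generate_cohort(default_cohort_spec(seed=s)).carrier.sum())
            for s in range(200)
        ]
        se = np.sqrt(116 * (14 / 116) * (102 / 116) + 19 * (4 / 19) * (15 / 19))
        assert abs(np.mean(counts) - 18) <= 3 * se / np.sqrt(200)

    def test_byte_identical_reproducibility(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_cohort(generate_cohort(default_cohort_spec(seed=9)), a)
        write_cohort(generate_cohort(default_cohort_spec(seed=9)), b)
        assert a.read_bytes() == b.read_bytes()

    def test_zero_sizes_give_empty_table(self):
        spec = default_cohort_spec()
        spec.sizes = {"BC": 0, "OC": 0, "BC+OC": 0}
        assert generate_cohort(spec).empty

    def test_degenerate_prevalence_one(self):
        spec = default_cohort_spec(seed=3)
        spec.carrier_prevalence = {g: 1.0 for g in spec.carrier_prevalence}
        assert generate_cohort(spec).carrier.all()

    def test_impossible_probability_rejected(self):
        spec = default_cohort_spec()
        spec.carrier_prevalence["BC"] = 1.5
        with pytest.raises(SpecError):
            generate_cohort(spec)

    def test_bernoulli_mode_varies_margins(self):
        spec = default_cohort_spec(seed=4)
        spec.allocation = "bernoulli"
        df = generate_cohort(spec)
        assert len(df) == 140  # same shape, sampled margins

    def test_parameter_recovery_at_scale(self):
        """Prevalence, group age means and the carrier-associated covariate
        odds ratios estimated from a 50,000-patient cohort are within 2%
        relative error of the configured values."""
        spec = default_cohort_spec(seed=0).with_total(50_000)
        df = generate_cohort(spec)
        assert len(df) == 50_000
        prev = df.carrier.mean()
        assert abs(prev / (18 / 140) - 1) < 0.02
        for group, mean in (("BC", 46.9), ("OC", 56.6)):
            assert abs(df[df.group == group].age.mean() / mean - 1) < 0.02
        def odds_ratio(sub, var, level):
            c, n = sub[sub.carrier], sub[~sub.carrier]
            pc, pn = (c[var] == level).mean(), (n[var] == level).mean()
            return (pc / (1 - pc)) / (pn / (1 - pn))
        bc = df[df.group == "BC"]
        target = ((4 / 14) / (10 / 14)) / ((6 / 102) / (96 / 102))
        assert abs(odds_ratio(bc, "bmi_class", "overweight") / target - 1) < 0.02
        target = ((5 / 14) / (9 / 14)) / ((70 / 102) / (32 / 102))
        assert abs(odds_ratio(bc, "chemo_response", "complete") / target - 1) < 0.02
        oc = df[df.group == "OC"]
        target = ((3 / 4) / (1 / 4)) / ((2 / 15) / (13 / 15))
        assert abs(odds_ratio(oc, "laterality", "bilateral") / target - 1) < 0.02


class TestPanelGeneration:
    def test_all_records_roundtrip_through_parser(self):
        table, scores, clinvar = generate_panel(default_panel_spec(seed=7, n_variants=1000))
        assert len(table) == 1000
        for rec in table:
            assert vp.parse_protein_hgvs(rec.protein_change.format()) == rec.protein_change
            vp.parse_cdna_hgvs(rec.hgvs_cdna)
            assert rec.key in scores and rec.key in clinvar

    def test_truncating_variants_carry_no_scores(self):
        table, scores, _ = generate_panel(default_panel_spec(seed=11, n_variants=300))
        for rec in table:
            if rec.protein_change.consequence is not vp.Consequence.MISSENSE:
                assert scores[rec.key].sift_score is None
                assert scores[rec.key].polyphen_score is None

    def test_all_frameshift_mix_prioritizes_everything_high(self, default_domains):
        spec = PanelSpec(
            n_variants=40,
            consequence_mix={"missense": 0.0, "frameshift": 1.0, "stop_gained": 0.0},
            seed=3,
        )
        table, scores, clinvar = generate_panel(spec)
        domains, window = default_domains
        report = vp.prioritize_table(
            table,
            vp.assign_all(table, domains, window),
            {k: vp.classify(scores[k]) for k in table.keys},
            clinvar,
        )
        assert all(r.result.level is vp.PriorityLevel.HIGH for r in report.rows)

    def test_zero_adverse_weight_gives_no_concordant_calls(self):
        spec = PanelSpec(n_variants=200, score_adverse_weight=0.0, seed=5)
        table, scores, _ = generate_panel(spec)
        profiles = [vp.classify(scores[k]) for k in table.keys]
        assert not any(p.concordant for p in profiles)

    def test_reproducible_and_weights_validated(self, tmp_path):
        t1, s1, c1 = generate_panel(default_panel_spec(seed=2, n_variants=25))
        write_panel(t1, s1, c1, tmp_path / "a")
        t2, s2, c2 = generate_panel(default_panel_spec(seed=2, n_variants=25))
        write_panel(t2, s2, c2, tmp_path / "b")
        for name in ("variants.tsv", "predictions.tsv", "clinvar.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        with pytest.raises(SpecError):
            PanelSpec(consequence_mix={"missense": 0.5}).validate()


class TestPipelineClosure:
    def test_generated_outputs_feed_every_stage(self, tmp_path, default_domains):
        """Synthetic cohort + panel run through parsing, domain mapping,
        classification, triage and cohort statistics without schema
        adaptation."""
        cohort = generate_cohort(default_cohort_spec(seed=6))
        table, scores, clinvar = generate_panel(default_panel_spec(seed=6, n_variants=30))
        paths = write_panel(table, scores, clinvar, tmp_path)
        write_cohort(cohort, tmp_path / "patients.tsv")

        reread = vp.read_variant_table(paths["variants"])
        assert len(reread) == 30
        raw = vp.read_predictions(paths["predictions"])
        domains, window = default_domains
        report = vp.prioritize_table(
            reread,
            vp.assign_all(reread, domains, window),
            {k: vp.classify(raw[k]) for k in reread.keys},
        )
        assert len(report.rows) == 30
        patients = pd.read_csv(tmp_path / "patients.tsv", sep="\t")
        cmp = vp.compare_by_carrier(patients, "bmi_class", level="overweight", group="BC")
        assert 0 < cmp.p_two_sided <= 1
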