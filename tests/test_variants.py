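"""HGVS parsing, variant records and catalogue loading."""

import pytest

import varprio as vp
from varprio.variants import (
    AminoAcid,
    CdnaEditKind,
    Consequence,
    HgvsParseError,
    VariantTableError,
    parse_cdna_hgvs,
    parse_protein_hgvs,
)


class TestProteinHgvs:
    @pytest.mark.parametrize(
        "text, ref, position, alt, consequence",
        [
            ("p.Gln1089fs", "Gln", 1089, None, Consequence.FRAMESHIFT),
            ("p.Glu2947Ter", "Glu", 2947, "Ter", Consequence.STOP_GAINED),
            ("p.Ala3122Pro", "Ala", 3122, "Pro", Consequence.MISSENSE),
            ("p.Val3079fs", "Val", 3079, None, Consequence.FRAMESHIFT),
            # the inserted residue before "fs" is normalised away
            ("p.Val3079Phefs", "Val", 3079, None, Consequence.FRAMESHIFT),
            ("(p.Gln1063Arg)", "Gln", 1063, "Arg", Consequence.MISSENSE),
        ],
    )
    def test_parses_suffix_forms(self, text, ref, position, alt, consequence):
        change = parse_protein_hgvs(text)
        assert change.ref.code3 == ref
        assert change.position == position
        assert (change.alt.code3 if change.alt else None) == alt
        assert change.consequence is consequence

    def test_fs_spellings_normalise_to_same_change(self):
        assert parse_protein_hgvs("p.Val3079fs") == parse_protein_hgvs("p.Val3079Phefs")

    @pytest.mark.parametrize(
        "text",
        ["p.Xaa12Gly", "q.Gln1089fs", "p.Gln0Arg", "p.Gln1089", "p.TerAla", "p.Gln1089Zzz"],
    )
    def test_rejects_malformed_strings(self, text):
        with pytest.raises(HgvsParseError):
            parse_protein_hgvs(text)

    def test_roundtrip_on_study_catalogue(self, study_table):
        for rec in study_table:
            formatted = rec.protein_change.format()
            assert parse_protein_hgvs(formatted) == rec.protein_change

    def test_amino_acid_bijection(self):
        codes3 = set()
        for code3 in ("Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly",
                      "His", "Ile", "Leu", "Lys", "Met", "Phe", "Pro", "Ser",
                      "Thr", "Trp", "Tyr", "Val", "Ter"):
            aa = AminoAcid(code3)
            assert AminoAcid.from_code1(aa.code1) == aa
            codes3.add(aa.code1)
        assert len(codes3) == 21
        assert AminoAcid("Ter").code1 == "*"


class TestCdnaHgvs:
    @pytest.mark.parametrize(
        "text, positions, kind",
        [
            ("c.3188A>G", (3188,), CdnaEditKind.SUB),
            ("c.6415_6416delinsAT", (6415, 6416), CdnaEditKind.DELINS),
            ("c.1_1del", (1, 1), CdnaEditKind.DEL),
            ("c.3264dup", (3264,), CdnaEditKind.DUP),
            ("c.6275_6276del", (6275, 6276), CdnaEditKind.DEL),
            ("c.9235delG", (9235,), CdnaEditKind.DEL),
            ("NM_000059.4(BRCA2):c.3264dup", (3264,), CdnaEditKind.DUP),
        ],
    )
    def test_parses_edit_kinds(self, text, positions, kind):
        edit = parse_cdna_hgvs(text)
        assert edit.positions == positions
        assert edit.edit_kind is kind

    @pytest.mark.parametrize("text", ["c.12inv", "g.100A>G", "c.5_2del", "c.0A>G", "c.12"])
    def test_rejects_unsupported_edits(self, text):
        with pytest.raises(HgvsParseError):
            parse_cdna_hgvs(text)


class TestVariantTable:
    def test_study_catalogue_shape(self, study_table):
        assert len(study_table) == 13
        assert sum(r.carriers_total for r in study_table) == 18
        assert study_table.cohort_sizes.total == 140

    def test_consequence_classes(self, study_table):
        expected = {
            "rs775030825": Consequence.MISSENSE,
            "rs80359380": Consequence.FRAMESHIFT,
            "rs80359479": Consequence.FRAMESHIFT,
            "rs11571658": Consequence.FRAMESHIFT,
            # the delins is classified by its protein-level consequence
            "rs1064795067": Consequence.MISSENSE,
            "rs397507422": Consequence.FRAMESHIFT,
            "rs587782313": Consequence.MISSENSE,
            "rs80359219": Consequence.MISSENSE,
            "rs1329182873": Consequence.MISSENSE,
            "c.9812T>C": Consequence.MISSENSE,
            "rs587780646": Consequence.MISSENSE,
            "rs878853569": Consequence.FRAMESHIFT,
            "rs398122715": Consequence.STOP_GAINED,
        }
        assert {r.key: r.protein_change.consequence for r in study_table} == expected

    def test_shared_bc_oc_carrier(self, study_table):
        rec = study_table.get("rs80359479")
        assert (rec.carriers_bc, rec.carriers_oc) == (1, 1)

    def test_key_prefers_rsid_then_cdna(self, study_table):
        assert study_table.get("c.9812T>C").rsid is None
        assert study_table.get("rs398122715").hgvs_cdna == "c.8839G>T"

    def test_empty_data_section(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(
            "hgvs_cdna\thgvs_protein\trsid\tcarriers_bc\tcarriers_oc\t"
            "clinical_classification\tclinvar_aggregate\tclinvar_review\n"
        )
        assert len(vp.read_variant_table(path)) == 0

    def test_missing_column_and_duplicate_key_errors(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("hgvs_cdna\thgvs_protein\n")
        with pytest.raises(VariantTableError, match="missing mandatory"):
            vp.read_variant_table(bad)
        dup = tmp_path / "dup.tsv"
        row = "c.3188A>G\tp.Gln1063Arg\trs1\t1\t0\tVUS\t\t\n"
        dup.write_text(
            "hgvs_cdna\thgvs_protein\trsid\tcarriers_bc\tcarriers_oc\t"
            "clinical_classification\tclinvar_aggregate\tclinvar_review\n" + row + row
        )
        with pytest.raises(VariantTableError, match="duplicate"):
            vp.read_variant_table(dup)

    def test_unparseable_row_reports_line_number(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "hgvs_cdna\thgvs_protein\trsid\tcarriers_bc\tcarriers_oc\t"
            "clinical_classification\tclinvar_aggregate\tclinvar_review\n"
            "c.3188A>G\tp.Xaa12Gly\trs1\t1\t0\tVUS\t\t\n"
        )
        with pytest.raises(VariantTableError, match="row 2"):
            vp.read_variant_table(bad)
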