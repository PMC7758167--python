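"""CDM table assembly: TERM_MODIFIERS, NOTE_NLP, measurements, relationships."""

import pytest

from pathcdm.cdm import (
    CdmRecordSet,
    IhcResult,
    MolecularTest,
    SpecimenRecord,
    SurgicalCase,
    TermModifierError,
    build_fact_relationships,
    build_note_nlp,
    build_specimens,
    derive_condition,
    derive_measurements,
    serialize_term_modifiers,
    write_cdm_tables,
)
from pathcdm.normalize import NormalizedResult, aggregate_molecular
from pathcdm.parser import ExtractedEntity, SurgicalEntity


class TestSerializeTermModifiers:
    def test_full_ihc_modifier_string(self):
        s = serialize_term_modifiers(
            {
                "Negated": False,
                "value_as_concept_id": 9191,
                "value_as_narrative": "1+/3",
                "sub_id": "S 120034567",
                "section_source_value": "Immunochemistry test report",
            }
        )
        assert s == (
            "Negated=FALSE; value_as_concept_id=9191; value_as_narrative=1+/3; "
            "sub_id=S 120034567; section_source_value=Immunochemistry test report"
        )

    def test_surgical_modifiers_omit_value_keys(self):
        s = serialize_term_modifiers(
            {
                "Negated": False,
                "sub_id": "S 110023456",
                "section_source_value": "Pathology reports of surgical specimen",
            }
        )
        assert s == (
            "Negated=FALSE; sub_id=S 110023456; "
            "section_source_value=Pathology reports of surgical specimen"
        )

    def test_empty_map_serializes_to_empty_string(self):
        assert serialize_term_modifiers({}) == ""

    def test_fixed_order_regardless_of_input_order(self):
        s = serialize_term_modifiers(
            {"section_source_value": "x", "Negated": True, "value_as_concept_id": 1}
        )
        assert s == "Negated=TRUE; value_as_concept_id=1; section_source_value=x"

    def test_unknown_key_is_a_schema_error(self):
        with pytest.raises(TermModifierError):
            serialize_term_modifiers({"Negated": False, "novel_key": 1})


def _entity(**kw):
    defaults = dict(
        section_source_value="ihc",
        lexical_variant="EGFR (GI)",
        raw_value="1+/3",
        snippet="EGFR (GI) | 1+/3",
        offset_start=170,
        offset_end=186,
        sub_id="S 120034567",
    )
    defaults.update(kw)
    return ExtractedEntity(**defaults)


class TestBuildNoteNlp:
    def test_snippet_and_offsets_copied_verbatim(self):
        row = build_note_nlp(
            _entity(),
            note_nlp_id=1,
            note_id="n2",
            section_concept_id=40758358,
            section_label="Immunochemistry test report",
            note_nlp_concept_id=3016231,
            lexical_variant="EGFR",
            normalized=NormalizedResult("positive", False, "1+/3"),
            value_concept_id=9191,
        )
        assert row.snippet == "EGFR (GI) | 1+/3"
        assert row.offset == "170,186"
        assert row.lexical_variant == "EGFR"
        assert row.note_nlp_concept_id == 3016231
        assert "value_as_concept_id=9191" in row.term_modifiers
        assert "value_as_narrative=1+/3" in row.term_modifiers

    def test_entity_without_result_gets_no_value_modifiers(self):
        row = build_note_nlp(
            _entity(raw_value="", snippet="tubular adenoma, nos"),
            note_nlp_id=1,
            note_id="n1",
            section_concept_id=3025891,
            section_label="Pathology reports of surgical specimen",
            note_nlp_source_concept_id=44498791,
        )
        assert "value_as" not in row.term_modifiers
        assert row.term_modifiers.startswith("Negated=FALSE; ")


def _positive():
    return NormalizedResult("positive", False, "Positive")


def _ihc(n, person="P1", sub="S 110000001"):
    return [
        IhcResult(person, sub, "2020-01-01", f"M{i}", _positive()) for i in range(n)
    ]


def _msi_test(person="P1", sub="S 110000001"):
    attrs = [("BAT26", _positive()), ("BAT25", _positive())] + [
        (m, NormalizedResult("negative", False, "Negative"))
        for m in ("D5S346", "D17S250", "D2S123")
    ]
    return MolecularTest(person, sub, "2020-01-01", aggregate_molecular("MSI", attrs))


class TestDeriveMeasurements:
    def test_msi_panel_collapses_to_one_record(self, dictionary):
        records = derive_measurements([], [_msi_test()], dictionary)
        assert len(records) == 1
        assert records[0].measurement_concept_id == 3047348
        assert records[0].value_as_concept_id == dictionary.value_map["msi_high"]

    def test_one_record_per_ihc_biomarker(self, dictionary):
        assert len(derive_measurements(_ihc(3), [], dictionary)) == 3

    def test_empty_input_gives_no_records(self, dictionary):
        assert derive_measurements([], [], dictionary) == []

    def test_ids_dense_from_one(self, dictionary):
        records = derive_measurements(_ihc(2), [_msi_test()], dictionary)
        assert [r.measurement_id for r in records] == [1, 2, 3]


def _case(person="P1", sub="S 110000001", site="sigmoid colon", diag="adenocarcinoma, nos"):
    entity = ExtractedEntity(
        section_source_value="surgical",
        lexical_variant=diag,
        raw_value="",
        snippet=diag,
        offset_start=40,
        offset_end=40 + len(diag),
        sub_id=sub,
    )
    return SurgicalCase(person, sub, "2020-01-01", SurgicalEntity(site, diag, entity))


class TestDeriveCondition:
    def test_one_record_per_surgical_report(self, dictionary):
        records = derive_condition([_case(), _case(person="P2", sub="S 110000002")], dictionary)
        assert len(records) == 2
        assert all(r.condition_source_value == "adenocarcinoma, nos" for r in records)

    def test_unmapped_diagnosis_carried_with_concept_zero(self, dictionary):
        [r] = derive_condition([_case(diag="zz-not-a-diagnosis")], dictionary)
        assert r.condition_source_concept_id == 0
        assert r.condition_source_value == "zz-not-a-diagnosis"


class TestFactRelationships:
    def test_combinatorial_row_count(self, dictionary):
        """1 specimen + 1 condition + 2 measurements -> 3 links x 2 directions."""
        cases = [_case()]
        specimens = build_specimens(cases)
        conditions = derive_condition(cases, dictionary)
        measurements = derive_measurements(_ihc(2), [], dictionary)
        rows = build_fact_relationships(specimens, conditions, measurements, dictionary)
        assert len(rows) == 6

    def test_no_specimens_no_rows(self, dictionary):
        measurements = derive_measurements(_ihc(1), [], dictionary)
        assert build_fact_relationships([], [], measurements, dictionary) == []

    def test_linkage_requires_person_agreement(self, dictionary, caplog):
        specimens = build_specimens([_case(person="P1")])
        stray = derive_measurements(_ihc(1, person="P2"), [], dictionary)
        with caplog.at_level("WARNING"):
            rows = build_fact_relationships(specimens, [], stray, dictionary)
        assert rows == []
        assert any("no matching specimen" in m for m in caplog.messages)

    def test_every_row_has_its_inverse(self, dictionary):
        cases = [_case(), _case(person="P2", sub="S 110000002")]
        specimens = build_specimens(cases)
        conditions = derive_condition(cases, dictionary)
        measurements = derive_measurements(_ihc(3), [_msi_test()], dictionary)
        rows = build_fact_relationships(specimens, conditions, measurements, dictionary)
        inverse_of = {
            r.concept_id: r.inverse_concept_id
            for r in dictionary.relationship_concepts.values()
        }
        row_set = {
            (r.domain_concept_id_1, r.fact_id_1, r.domain_concept_id_2, r.fact_id_2,
             r.relationship_concept_id)
            for r in rows
        }
        for d1, f1, d2, f2, rel in row_set:
            assert (d2, f2, d1, f1, inverse_of[rel]) in row_set

    def test_duplicate_specimens_deduplicated(self, dictionary, caplog):
        with caplog.at_level("WARNING"):
            specimens = build_specimens([_case(), _case()])
        assert len(specimens) == 1
        assert any("duplicate specimen" in m for m in caplog.messages)


class TestWriteCdmTables:
    def test_empty_record_set_writes_headers_only(self, tmp_path):
        counts = write_cdm_tables(CdmRecordSet(), tmp_path)
        assert set(counts.values()) == {0}
        for name in (
            "note_nlp",
            "measurement",
            "condition_occurrence",
            "specimen",
            "fact_relationship",
        ):
            lines = (tmp_path / f"{name}.csv").read_text().splitlines()
            assert len(lines) == 1
            assert "_id" in lines[0] or name == "fact_relationship"

    def test_rerun_is_byte_identical(self, dictionary, tmp_path):
        cases = [_case()]
        rs = CdmRecordSet(
            specimen=build_specimens(cases),
            condition_occurrence=derive_condition(cases, dictionary),
            measurement=derive_measurements(_ihc(2), [], dictionary),
        )
        rs.fact_relationship = build_fact_relationships(
            rs.specimen, rs.condition_occurrence, rs.measurement, dictionary
        )
        out1, out2 = tmp_path / "a", tmp_path / "b"
        write_cdm_tables(rs, out1)
        write_cdm_tables(rs, out2)
        for f in out1.iterdir():
            assert f.read_bytes() == (out2 / f.name).read_bytes()
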