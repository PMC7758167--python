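"""Report-type detection, section segmentation and raw entity extraction."""

import pytest

from conftest import make_ihc_text, make_molecular_text, make_surgical_text
from pathcdm.config import PipelineConfig
from pathcdm.parser import (
    InputError,
    RawReport,
    detect_report_type,
    extract_biomarker_blocks,
    extract_sections,
    extract_surgical_entities,
    find_sub_id,
    parse_biomarker_block,
)


def _report(text, note_id="n1"):
    return RawReport(note_id=note_id, person_id="p1", text=text)


class TestDetectReportType:
    @pytest.mark.parametrize(
        "text, expected",
        [
            (make_surgical_text(), "surgical"),
            (make_ihc_text(), "ihc"),
            (make_molecular_text(), "molecular"),
            ("free text with no markers at all", "unknown"),
        ],
    )
    def test_signature_detection(self, text, expected):
        assert detect_report_type(_report(text)) == expected

    def test_empty_signature_config_yields_unknown(self):
        config = PipelineConfig(signatures={})
        assert detect_report_type(_report("SAMPLE NAME: colon"), config) == "unknown"

    def test_ambiguous_signatures_yield_unknown(self):
        config = PipelineConfig(
            signatures={"surgical": ["REPORT"], "ihc": ["REPORT"]}
        )
        assert detect_report_type(_report("REPORT"), config) == "unknown"

    def test_empty_text_is_an_input_error(self):
        with pytest.raises(InputError):
            detect_report_type(_report(""))

    def test_case_insensitive_flag(self):
        config = PipelineConfig(case_sensitive=False)
        text = make_surgical_text().lower()
        assert detect_report_type(_report(text), config) == "surgical"


class TestExtractSections:
    def test_summary_between_delimiters(self):
        text = "header\nSUMMARY: all markers negative EXAMINER: xxx"
        sections = extract_sections(_report(text), "ihc")
        assert sections["summary"].text == "all markers negative"
        span = sections["summary"]
        assert text[span.offset_start : span.offset_end] == span.text

    def test_missing_summary_marker_gives_no_summary_key(self):
        sections = extract_sections(_report("no markers here"), "ihc")
        assert "summary" not in sections

    def test_adjacent_delimiters_give_empty_summary(self):
        sections = extract_sections(_report("SUMMARY: EXAMINER:"), "ihc")
        assert sections["summary"].text == ""

    def test_unterminated_summary_runs_to_end_of_text(self, caplog):
        with caplog.at_level("WARNING"):
            sections = extract_sections(_report("SUMMARY: trailing words"), "ihc")
        assert sections["summary"].text == "trailing words"
        assert any("summary runs to end" in m for m in caplog.messages)

    def test_unknown_type_rejected(self):
        with pytest.raises(InputError):
            extract_sections(_report("x"), "unknown")


class TestExtractSurgicalEntities:
    def test_sample_and_diagnosis_pair(self):
        text = "SAMPLE NAME: colon\nDIAGNOSIS: adenocarcinoma, nos"
        [res] = extract_surgical_entities(_report(text))
        assert (res.specimen_name, res.diagnosis) == ("colon", "adenocarcinoma, nos")

    def test_exactly_one_pair_per_report(self, small_corpus):
        reports, _ = small_corpus
        for r in reports:
            if r.report_type == "surgical":
                assert len(extract_surgical_entities(r)) == 1

    def test_missing_diagnosis_skips_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = extract_surgical_entities(_report("SAMPLE NAME: colon"))
        assert out == []
        assert any("missing" in m for m in caplog.messages)

    def test_multivalued_diagnosis_returned_verbatim(self):
        diagnosis = "ductal adenocarcinoma, moderately differentiated > poorly differentiated"
        text = make_surgical_text(diagnosis=diagnosis)
        [res] = extract_surgical_entities(_report(text))
        assert res.diagnosis == diagnosis
        e = res.entity
        assert text[e.offset_start : e.offset_end] == diagnosis

    def test_sub_id_recovered_from_text(self):
        [res] = extract_surgical_entities(_report(make_surgical_text()))
        assert res.entity.sub_id == "S 110023456"


class TestParseBiomarkerBlock:
    def test_name_value_split_on_bar(self):
        [e] = parse_biomarker_block("EGFR (GI) | 1+/3")
        assert e.lexical_variant == "EGFR (GI)"
        assert e.raw_value == "1+/3"
        assert e.snippet == "EGFR (GI) | 1+/3"

    def test_molecular_attribute_row(self):
        [e] = parse_biomarker_block("Codon 12 (exon 2) | Positive")
        assert (e.lexical_variant, e.raw_value) == ("Codon 12 (exon 2)", "Positive")

    def test_empty_block_yields_no_entities(self):
        assert parse_biomarker_block("") == []

    def test_row_without_bar_skipped_never_aborts(self, caplog):
        block = "EGFR | 1+/3\nbroken row no bar\nKi-67 | Negative"
        with caplog.at_level("WARNING"):
            entities = parse_biomarker_block(block)
        assert [e.lexical_variant for e in entities] == ["EGFR", "Ki-67"]
        assert any("skipped" in m for m in caplog.messages)

    def test_splits_at_first_bar_only(self):
        [e] = parse_biomarker_block("CD3 | 1+/3 | focal")
        assert e.lexical_variant == "CD3"
        assert e.raw_value == "1+/3 | focal"

    def test_offsets_absolute_via_base_offset(self):
        text = make_ihc_text(rows=("EGFR (GI) | 1+/3", "Ki-67 | Negative"))
        report = _report(text)
        [block] = extract_biomarker_blocks(report)
        entities = parse_biomarker_block(block.text, block.base_offset)
        assert len(entities) == 2
        for e in entities:
            assert text[e.offset_start : e.offset_end] == e.snippet


class TestBiomarkerBlocks:
    def test_header_is_preceding_line(self):
        text = make_molecular_text(test="KRAS mutation")
        [block] = extract_biomarker_blocks(_report(text))
        assert block.header == "KRAS mutation"

    def test_multiple_blocks_in_document_order(self):
        text = (
            "MOLECULAR STUDY REPORT\nNRAS mutation\n---\na | b\n---\n"
            "MSI\n---\nBAT26 | Negative\n---\n"
        )
        blocks = extract_biomarker_blocks(_report(text))
        assert [b.header for b in blocks] == ["NRAS mutation", "MSI"]

    def test_short_hyphen_runs_do_not_fence(self):
        text = "x\n--\na | b\n--\n"
        assert extract_biomarker_blocks(_report(text)) == []

    def test_unmatched_fence_runs_to_end_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            [block] = extract_biomarker_blocks(_report("hdr\n----\na | b\n"))
        assert "a | b" in block.text
        assert any("unmatched" in m for m in caplog.messages)


class TestOffsetFidelityAndDeterminism:
    def test_every_gold_snippet_reproduced_by_slicing(self, small_corpus):
        reports, golds = small_corpus
        by_id = {r.note_id: r for r in reports}
        checked = 0
        for g in golds:
            text = by_id[g.note_id].text
            for e in g.entities:
                assert text[e.offset_start : e.offset_end] == e.snippet
                checked += 1
        assert checked > 0

    def test_parsing_is_deterministic_and_order_preserving(self, small_corpus):
        reports, _ = small_corpus
        for r in reports:
            if r.report_type == "surgical":
                continue
            runs = []
            for _ in range(2):
                entities = []
                for block in extract_biomarker_blocks(r):
                    entities.extend(parse_biomarker_block(block.text, block.base_offset))
                runs.append(entities)
            assert runs[0] == runs[1]
            starts = [e.offset_start for e in runs[0]]
            assert starts == sorted(starts)


def test_find_sub_id_first_match():
    assert find_sub_id("a S 123456789 then S 987654321") == "S 123456789"
    assert find_sub_id("no surgical number") == ""
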