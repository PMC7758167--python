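"""Pipeline orchestration: extract → normalize → map → build CDM tables.

`run_pipeline` drives one corpus through the full conversion and returns
the assembled CDM record set, a run report (per-stage counts, skip
reasons, unmapped-term tallies) and the per-entity predictions used by the
evaluation harness.  Nothing is silently dropped: reports that fail
extraction and rows that fail parsing are counted with their reason.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from pathcdm import cdm
from pathcdm.cdm import (
    CdmRecordSet,
    IhcResult,
    MolecularTest,
    SurgicalCase,
    build_note_nlp,
)
from pathcdm.config import PipelineConfig
from pathcdm.evaluate import EntityKey
from pathcdm.normalize import (
    MOLECULAR_TESTS,
    aggregate_molecular,
    canonicalize_name,
    normalize_ihc_value,
    normalize_molecular_value,
)
from pathcdm.parser import (
    REPORT_TYPES,
    RawReport,
    count_block_rows,
    detect_report_type,
    extract_biomarker_blocks,
    extract_surgical_entities,
    find_sub_id,
    parse_biomarker_block,
)
from pathcdm.vocab import (
    ConceptDictionary,
    load_dictionary,
    lookup_condition,
    lookup_measurement,
    lookup_section,
    lookup_section_label,
    lookup_value,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-tagged fatal pipeline error."""


@dataclass
class PipelineResult:
    """Everything one run produces."""

    records: CdmRecordSet
    run_report: dict
    predictions: list[EntityKey] = field(default_factory=list)


def run_pipeline(
    reports: Sequence[RawReport],
    dictionary: Optional[ConceptDictionary] = None,
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Convert a corpus of raw reports into the five CDM tables.

    Stages run strictly in order per report: type detection (when the
    corpus carries no type), section/entity extraction, result
    normalization, concept mapping, table assembly.  When ``out_dir`` is
    given the tables and a ``run_report.json`` are written there.
    """
    d = dictionary or load_dictionary()
    config = config or PipelineConfig()

    note_nlp_rows = []
    predictions: list[EntityKey] = []
    ihc_results: list[IhcResult] = []
    molecular_tests: list[MolecularTest] = []
    surgical_cases: list[SurgicalCase] = []
    counts = {t: 0 for t in REPORT_TYPES}
    skipped_reports: list[dict] = []
    skipped_rows = 0
    unmapped_terms: dict[str, int] = {}
    unmapped_diagnoses: dict[str, int] = {}
    next_note_nlp_id = config.key_offset + 1

    for report in reports:
        try:
            rtype = (
                report.report_type
                if report.report_type in REPORT_TYPES
                else detect_report_type(report, config)
            )
        except ValueError as exc:
            raise PipelineError(f"parse: report {report.note_id}: {exc}") from exc
        if rtype not in REPORT_TYPES:
            skipped_reports.append({"note_id": report.note_id, "reason": "unknown report type"})
            continue
        counts[rtype] += 1
        sub_id = report.sub_id or find_sub_id(report.text, config)
        date = report.note_date or config.run_date

        if rtype == "surgical":
            extracted = extract_surgical_entities(report, config)
            if not extracted:
                skipped_reports.append(
                    {"note_id": report.note_id, "reason": "surgical extraction failure"}
                )
                continue
            surgical = extracted[0]
            surgical.entity.sub_id = surgical.entity.sub_id or sub_id
            source_id, _standard_id = lookup_condition(
                surgical.diagnosis, surgical.specimen_name, d
            )
            if source_id == 0:
                unmapped_diagnoses[surgical.diagnosis.lower()] = (
                    unmapped_diagnoses.get(surgical.diagnosis.lower(), 0) + 1
                )
            note_nlp_rows.append(
                build_note_nlp(
                    surgical.entity,
                    note_nlp_id=next_note_nlp_id,
                    note_id=report.note_id,
                    section_concept_id=lookup_section("surgical", d),
                    section_label=lookup_section_label("surgical", d),
                    note_nlp_concept_id=0,
                    note_nlp_source_concept_id=source_id,
                )
            )
            next_note_nlp_id += 1
            predictions.append(
                (
                    report.note_id,
                    surgical.entity.offset_start,
                    surgical.entity.offset_end,
                    surgical.entity.lexical_variant,
                    "",
                )
            )
            surgical_cases.append(
                SurgicalCase(
                    person_id=report.person_id, sub_id=sub_id, date=date, surgical=surgical
                )
            )
            continue

        blocks = extract_biomarker_blocks(report, config)
        for block in blocks:
            entities = parse_biomarker_block(
                block.text,
                block.base_offset,
                config,
                section_source_value=rtype,
                sub_id=sub_id,
            )
            skipped_rows += count_block_rows(block.text) - len(entities)

            if rtype == "ihc":
                for entity in entities:
                    canonical = canonicalize_name(entity.lexical_variant, d.aliases)
                    normalized = normalize_ihc_value(entity.raw_value, config)
                    concept_id, _, _ = lookup_measurement(canonical, d)
                    if concept_id == 0:
                        unmapped_terms[canonical] = unmapped_terms.get(canonical, 0) + 1
                    note_nlp_rows.append(
                        build_note_nlp(
                            entity,
                            note_nlp_id=next_note_nlp_id,
                            note_id=report.note_id,
                            section_concept_id=lookup_section("ihc", d),
                            section_label=lookup_section_label("ihc", d),
                            note_nlp_concept_id=concept_id,
                            lexical_variant=canonical,
                            normalized=normalized,
                            value_concept_id=lookup_value(normalized.category, d),
                        )
                    )
                    next_note_nlp_id += 1
                    predictions.append(
                        (
                            report.note_id,
                            entity.offset_start,
                            entity.offset_end,
                            canonical,
                            normalized.category,
                        )
                    )
                    ihc_results.append(
                        IhcResult(
                            person_id=report.person_id,
                            sub_id=sub_id,
                            date=date,
                            canonical_name=canonical,
                            result=normalized,
                        )
                    )
            else:  # molecular
                test_name = canonicalize_name(block.header, d.aliases)
                known_test = test_name in MOLECULAR_TESTS
                if not known_test and entities:
                    logger.warning(
                        "report %s: unknown molecular test header %r",
                        report.note_id,
                        block.header,
                    )
                    unmapped_terms[test_name] = unmapped_terms.get(test_name, 0) + 1
                attributes = []
                for entity in entities:
                    canonical = canonicalize_name(entity.lexical_variant, d.aliases)
                    normalized = normalize_molecular_value(
                        entity.raw_value,
                        d.lexicons.get(
                            "molecular_negative", ("negative", "not detected")
                        ),
                    )
                    note_nlp_rows.append(
                        build_note_nlp(
                            entity,
                            note_nlp_id=next_note_nlp_id,
                            note_id=report.note_id,
                            section_concept_id=lookup_section(test_name, d),
                            section_label=lookup_section_label(test_name, d),
                            note_nlp_concept_id=lookup_measurement(canonical, d)[0],
                            lexical_variant=entity.lexical_variant,
                            normalized=normalized,
                            value_concept_id=lookup_value(normalized.category, d),
                        )
                    )
                    next_note_nlp_id += 1
                    predictions.append(
                        (
                            report.note_id,
                            entity.offset_start,
                            entity.offset_end,
                            canonical,
                            normalized.category,
                        )
                    )
                    attributes.append((entity.lexical_variant, normalized))
                if known_test and attributes:
                    summary = aggregate_molecular(test_name, attributes, config)
                    molecular_tests.append(
                        MolecularTest(
                            person_id=report.person_id,
                            sub_id=sub_id,
                            date=date,
                            summary=summary,
                        )
                    )

    records = CdmRecordSet(note_nlp=note_nlp_rows)
    records.measurement = cdm.derive_measurements(
        ihc_results, molecular_tests, d, config.key_offset
    )
    records.condition_occurrence = cdm.derive_condition(surgical_cases, d, config.key_offset)
    records.specimen = cdm.build_specimens(surgical_cases, config.key_offset)
    records.fact_relationship = cdm.build_fact_relationships(
        records.specimen, records.condition_occurrence, records.measurement, d
    )

    run_report = {
        "reports_in": len(reports),
        "reports_by_type": counts,
        "reports_skipped": len(skipped_reports),
        "skipped_reports": skipped_reports,
        "rows_skipped": skipped_rows,
        "entities_extracted": len(note_nlp_rows),
        "ihc_results": len(ihc_results),
        "molecular_tests": len(molecular_tests),
        "unmapped_terms": dict(sorted(unmapped_terms.items())),
        "unmapped_diagnoses": dict(sorted(unmapped_diagnoses.items())),
        "table_counts": records.counts(),
    }
    if out_dir is not None:
        try:
            cdm.write_cdm_tables(records, out_dir)
            Path(out_dir, "run_report.json").write_text(
                json.dumps(run_report, indent=1), encoding="utf-8"
            )
        except OSError as exc:
            raise PipelineError(f"emit: cannot write to {out_dir}: {exc}") from exc
    return PipelineResult(records=records, run_report=run_report, predictions=predictions)


# ---------------------------------------------------------------------------
# Corpus file IO

CORPUS_FIELDS = ("note_id", "person_id", "report_type", "sub_id", "note_date", "text")


def write_corpus(reports: Sequence[RawReport], path: str | Path) -> None:
    """Write a corpus to a delimited file, one report per row (text quoted)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CORPUS_FIELDS)
        for r in reports:
            writer.writerow(
                [r.note_id, r.person_id, r.report_type, r.sub_id, r.note_date, r.text]
            )


def read_corpus(path: str | Path, config: Optional[PipelineConfig] = None) -> list[RawReport]:
    """Read a delimited corpus file; column names are fixed in config."""
    config = config or PipelineConfig()
    cols = config.corpus_columns
    reports = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            reports.append(
                RawReport(
                    note_id=row.get(cols["note_id"], ""),
                    person_id=row.get(cols["person_id"], ""),
                    report_type=row.get(cols["report_type"], "") or "unknown",
                    sub_id=row.get(cols["sub_id"], "") or "",
                    note_date=row.get(cols["note_date"], "") or "",
                    text=row.get(cols["text"], ""),
                )
            )
    return reports


def read_report_dir(path: str | Path) -> list[RawReport]:
    """Read UTF-8 plain-text report files (one report per ``*.txt`` file)."""
    reports = []
    for file in sorted(Path(path).glob("*.txt")):
        reports.append(
            RawReport(note_id=file.stem, person_id=file.stem, text=file.read_text("utf-8"))
        )
    return reports
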