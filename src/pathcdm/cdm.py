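"""Assembly of the five OMOP CDM output tables.

NOTE_NLP rows carry every extracted span verbatim with its offsets and a
serialized TERM_MODIFIERS string (negation flag, normalized value concept,
raw narrative, specimen linkage id, section label).  Summary facts fan out
to MEASUREMENT (one row per IHC biomarker, one per molecular test
aggregate), CONDITION_OCCURRENCE (one cancer diagnosis per surgical
report) and SPECIMEN (one per surgical report, keyed by the surgical
pathology number).  FACT_RELATIONSHIP links each specimen to its
condition (specimen-source-identity) and to its derived measurements
(has-specimen), emitting both directions of every link.

Surrogate keys are run-local dense integers starting at 1 (+ an optional
configured offset); output is deterministic for identical input.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

from pathcdm.normalize import MolecularSummary, NormalizedResult
from pathcdm.parser import ExtractedEntity, SurgicalEntity
from pathcdm.vocab import (
    ConceptDictionary,
    lookup_condition,
    lookup_measurement,
    lookup_value,
)

logger = logging.getLogger(__name__)

#: Fixed TERM_MODIFIERS key vocabulary, in serialization order.
TERM_MODIFIER_KEYS = (
    "Negated",
    "value_as_concept_id",
    "value_as_narrative",
    "sub_id",
    "section_source_value",
)


class TermModifierError(ValueError):
    """Raised for a TERM_MODIFIERS key outside the fixed vocabulary."""


@dataclass
class NoteNlpRecord:
    note_nlp_id: int
    note_id: str
    section_concept_id: int
    snippet: str
    offset: str  # "start,end", 0-based half-open
    lexical_variant: str
    note_nlp_concept_id: int
    note_nlp_source_concept_id: int
    term_modifiers: str


@dataclass
class MeasurementRecord:
    measurement_id: int
    person_id: str
    measurement_concept_id: int
    measurement_date: str
    value_as_concept_id: int
    measurement_source_value: str
    specimen_source_id: str  # sub_id linking back to the specimen


@dataclass
class ConditionOccurrenceRecord:
    condition_occurrence_id: int
    person_id: str
    condition_concept_id: int
    condition_source_concept_id: int
    condition_source_value: str
    condition_start_date: str
    specimen_source_id: str


@dataclass
class SpecimenRecord:
    specimen_id: int
    person_id: str
    specimen_source_id: str
    specimen_date: str
    anatomic_site_source_value: str


@dataclass
class FactRelationshipRecord:
    domain_concept_id_1: int
    fact_id_1: int
    domain_concept_id_2: int
    fact_id_2: int
    relationship_concept_id: int


@dataclass
class CdmRecordSet:
    """Rows for the five CDM tables produced by one pipeline run."""

    note_nlp: list[NoteNlpRecord] = field(default_factory=list)
    measurement: list[MeasurementRecord] = field(default_factory=list)
    condition_occurrence: list[ConditionOccurrenceRecord] = field(default_factory=list)
    specimen: list[SpecimenRecord] = field(default_factory=list)
    fact_relationship: list[FactRelationshipRecord] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "note_nlp": len(self.note_nlp),
            "measurement": len(self.measurement),
            "condition_occurrence": len(self.condition_occurrence),
            "specimen": len(self.specimen),
            "fact_relationship": len(self.fact_relationship),
        }


# Carriers for report-level facts between normalization and table assembly.


@dataclass
class IhcResult:
    """One normalized IHC biomarker result within one report."""

    person_id: str
    sub_id: str
    date: str
    canonical_name: str
    result: NormalizedResult


@dataclass
class MolecularTest:
    """One aggregated molecular test within one report."""

    person_id: str
    sub_id: str
    date: str
    summary: MolecularSummary


@dataclass
class SurgicalCase:
    """One surgical report's specimen/diagnosis facts."""

    person_id: str
    sub_id: str
    date: str
    surgical: SurgicalEntity


def serialize_term_modifiers(pairs: dict[str, object]) -> str:
    """Serialize modifier pairs as ``key=value`` joined by ``"; "``.

    Keys must come from the fixed vocabulary and are emitted in its fixed
    order regardless of input order; absent keys are omitted; booleans
    render as TRUE/FALSE.  An unknown key raises (schema-drift guard).
    """
    unknown = set(pairs) - set(TERM_MODIFIER_KEYS)
    if unknown:
        raise TermModifierError(f"unknown TERM_MODIFIERS keys: {sorted(unknown)}")
    parts = []
    for key in TERM_MODIFIER_KEYS:
        if key not in pairs:
            continue
        value = pairs[key]
        if isinstance(value, bool):
            value = "TRUE" if value else "FALSE"
        parts.append(f"{key}={value}")
    return "; ".join(parts)


def build_note_nlp(
    entity: ExtractedEntity,
    *,
    note_nlp_id: int,
    note_id: str,
    section_concept_id: int,
    section_label: str,
    note_nlp_concept_id: int = 0,
    note_nlp_source_concept_id: int = 0,
    lexical_variant: Optional[str] = None,
    normalized: Optional[NormalizedResult] = None,
    value_concept_id: int = 0,
) -> NoteNlpRecord:
    """Assemble one NOTE_NLP row from an extracted entity.

    The snippet is copied verbatim; ``lexical_variant`` defaults to the
    entity's raw name but is normally the canonicalized name.  Value
    modifiers (concept + narrative) are serialized only for entities that
    carry a normalized result (IHC/molecular); surgical diagnosis rows
    carry only negation, linkage and section modifiers.
    """
    modifiers: dict[str, object] = {
        "Negated": bool(normalized.negated) if normalized else False
    }
    if normalized is not None:
        modifiers["value_as_concept_id"] = value_concept_id
        modifiers["value_as_narrative"] = normalized.narrative
    if entity.sub_id:
        modifiers["sub_id"] = entity.sub_id
    modifiers["section_source_value"] = section_label
    return NoteNlpRecord(
        note_nlp_id=note_nlp_id,
        note_id=note_id,
        section_concept_id=section_concept_id,
        snippet=entity.snippet,
        offset=f"{entity.offset_start},{entity.offset_end}",
        lexical_variant=lexical_variant if lexical_variant is not None else entity.lexical_variant,
        note_nlp_concept_id=note_nlp_concept_id,
        note_nlp_source_concept_id=note_nlp_source_concept_id,
        term_modifiers=serialize_term_modifiers(modifiers),
    )


def derive_measurements(
    ihc_results: Sequence[IhcResult],
    molecular_tests: Sequence[MolecularTest],
    d: ConceptDictionary,
    key_offset: int = 0,
) -> list[MeasurementRecord]:
    """MEASUREMENT rows: one per IHC biomarker result and exactly one per
    molecular test aggregate (never per-codon)."""
    records: list[MeasurementRecord] = []
    next_id = key_offset + 1
    for r in ihc_results:
        concept_id, _, _ = lookup_measurement(r.canonical_name, d)
        records.append(
            MeasurementRecord(
                measurement_id=next_id,
                person_id=r.person_id,
                measurement_concept_id=concept_id,
                measurement_date=r.date,
                value_as_concept_id=lookup_value(r.result.category, d),
                measurement_source_value=r.canonical_name,
                specimen_source_id=r.sub_id,
            )
        )
        next_id += 1
    for t in molecular_tests:
        concept_id, _, _ = lookup_measurement(t.summary.test_name, d)
        records.append(
            MeasurementRecord(
                measurement_id=next_id,
                person_id=t.person_id,
                measurement_concept_id=concept_id,
                measurement_date=t.date,
                value_as_concept_id=lookup_value(t.summary.summary_category, d),
                measurement_source_value=t.summary.test_name,
                specimen_source_id=t.sub_id,
            )
        )
        next_id += 1
    return records


def derive_condition(
    cases: Sequence[SurgicalCase], d: ConceptDictionary, key_offset: int = 0
) -> list[ConditionOccurrenceRecord]:
    """CONDITION_OCCURRENCE rows: one per parsed surgical report; unmapped
    diagnoses are carried with concept 0, source text preserved."""
    records: list[ConditionOccurrenceRecord] = []
    for i, case in enumerate(cases, start=key_offset + 1):
        source_id, standard_id = lookup_condition(
            case.surgical.diagnosis, case.surgical.specimen_name, d
        )
        records.append(
            ConditionOccurrenceRecord(
                condition_occurrence_id=i,
                person_id=case.person_id,
                condition_concept_id=standard_id,
                condition_source_concept_id=source_id,
                condition_source_value=case.surgical.diagnosis,
                condition_start_date=case.date,
                specimen_source_id=case.sub_id,
            )
        )
    return records


def build_specimens(
    cases: Sequence[SurgicalCase], key_offset: int = 0
) -> list[SpecimenRecord]:
    """SPECIMEN rows: one per surgical report, keyed by the surgical
    pathology number; duplicate numbers within a person are dropped with a
    warning (specimen_source_id is unique per person)."""
    records: list[SpecimenRecord] = []
    seen: set[tuple[str, str]] = set()
    next_id = key_offset + 1
    for case in cases:
        key = (case.person_id, case.sub_id)
        if case.sub_id and key in seen:
            logger.warning(
                "duplicate specimen %r for person %r dropped", case.sub_id, case.person_id
            )
            continue
        seen.add(key)
        records.append(
            SpecimenRecord(
                specimen_id=next_id,
                person_id=case.person_id,
                specimen_source_id=case.sub_id,
                specimen_date=case.date,
                anatomic_site_source_value=case.surgical.specimen_name,
            )
        )
        next_id += 1
    return records


def build_fact_relationships(
    specimens: Sequence[SpecimenRecord],
    conditions: Sequence[ConditionOccurrenceRecord],
    measurements: Sequence[MeasurementRecord],
    d: ConceptDictionary,
) -> list[FactRelationshipRecord]:
    """FACT_RELATIONSHIP rows linking each specimen to its condition
    (specimen-source-identity) and measurements (has-specimen).

    Linkage requires agreement on BOTH person_id and the surgical
    pathology number.  Every link is emitted in both directions with the
    inverse relationship concept; facts with no matching specimen produce
    no rows (logged); identical duplicate rows are deduplicated with a
    warning.
    """
    by_key = {(s.person_id, s.specimen_source_id): s for s in specimens if s.specimen_source_id}
    dom_specimen = d.domain_concepts.get("Specimen", 0)
    dom_condition = d.domain_concepts.get("Condition", 0)
    dom_measurement = d.domain_concepts.get("Measurement", 0)
    rel_identity = d.relationship_concepts.get("specimen_source_identity")
    rel_has_specimen = d.relationship_concepts.get("has_specimen")

    rows: list[FactRelationshipRecord] = []

    def _link(domain_2: int, fact_2: int, person_id: str, sub_id: str, rel, what: str) -> None:
        specimen = by_key.get((person_id, sub_id))
        if specimen is None or rel is None:
            logger.warning(
                "%s %s of person %r has no matching specimen %r; not linked",
                what,
                fact_2,
                person_id,
                sub_id,
            )
            return
        rows.append(
            FactRelationshipRecord(
                dom_specimen, specimen.specimen_id, domain_2, fact_2, rel.concept_id
            )
        )
        rows.append(
            FactRelationshipRecord(
                domain_2, fact_2, dom_specimen, specimen.specimen_id, rel.inverse_concept_id
            )
        )

    for c in conditions:
        _link(
            dom_condition,
            c.condition_occurrence_id,
            c.person_id,
            c.specimen_source_id,
            rel_identity,
            "condition",
        )
    for m in measurements:
        _link(
            dom_measurement,
            m.measurement_id,
            m.person_id,
            m.specimen_source_id,
            rel_has_specimen,
            "measurement",
        )

    unique: list[FactRelationshipRecord] = []
    seen_rows: set[tuple[int, int, int, int, int]] = set()
    for row in rows:
        key = (
            row.domain_concept_id_1,
            row.fact_id_1,
            row.domain_concept_id_2,
            row.fact_id_2,
            row.relationship_concept_id,
        )
        if key in seen_rows:
            logger.warning("duplicate FACT_RELATIONSHIP row deduplicated: %s", key)
            continue
        seen_rows.add(key)
        unique.append(row)
    return unique


_TABLE_FILES = {
    "note_nlp": ("note_nlp.csv", NoteNlpRecord, "note_nlp_id"),
    "measurement": ("measurement.csv", MeasurementRecord, "measurement_id"),
    "condition_occurrence": (
        "condition_occurrence.csv",
        ConditionOccurrenceRecord,
        "condition_occurrence_id",
    ),
    "specimen": ("specimen.csv", SpecimenRecord, "specimen_id"),
    "fact_relationship": ("fact_relationship.csv", FactRelationshipRecord, None),
}


def write_cdm_tables(record_set: CdmRecordSet, out_dir: str | Path) -> dict[str, int]:
    """Write one CSV per CDM table with CDM column headers.

    Row order is deterministic (by surrogate key; FACT_RELATIONSHIP by full
    row) so re-running on identical input yields byte-identical files.
    Returns row counts per table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    for table, (filename, record_cls, key) in _TABLE_FILES.items():
        rows: Iterable = getattr(record_set, table)
        columns = [f.name for f in dc_fields(record_cls)]
        if key is not None:
            rows = sorted(rows, key=lambda r: getattr(r, key))
        else:
            rows = sorted(rows, key=lambda r: tuple(getattr(r, c) for c in columns))
        with open(out / filename, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(columns)
            n = 0
            for row in rows:
                writer.writerow([getattr(row, c) for c in columns])
                n += 1
        counts[table] = n
    return counts
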