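"""Report-type detection, section segmentation and raw entity extraction.

Pathology reports arrive as semi-structured free text in three dialects:

* **surgical specimen** — ``SAMPLE NAME:`` and ``DIAGNOSIS:`` lines carrying
  the operated site and the diagnosis phrase;
* **immunohistochemistry (IHC)** — a biomarker table delimited by runs of
  hyphens, one ``name | value`` row per stain;
* **molecular study** — one hyphen-delimited table per test (RAS/RAF codon
  assays, the five-marker MSI panel), each preceded by its test-name line.

All dialects may carry a ``SUMMARY: ... EXAMINER:`` section and an
"S"-prefixed surgical pathology number that links IHC and molecular reports
back to the surgical specimen.

Every extracted span records absolute character offsets into the original
report text; slicing the text with them reproduces the span verbatim
(0-based, half-open).  Extraction is deterministic and order-preserving.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from pathcdm.config import PipelineConfig

logger = logging.getLogger(__name__)

REPORT_TYPES = ("surgical", "ihc", "molecular")


class InputError(ValueError):
    """Raised for input that violates an operation's preconditions."""


@dataclass
class RawReport:
    """One free-text pathology document.

    ``sub_id`` is the surgical pathology number (e.g. ``"S 110023456"``);
    when absent it is recovered from the text by :func:`find_sub_id`.
    """

    note_id: str
    person_id: str
    text: str
    report_type: str = "unknown"
    sub_id: str = ""
    note_date: str = ""


@dataclass
class ExtractedEntity:
    """A recognized span: entity name, raw value and provenance offsets."""

    section_source_value: str
    lexical_variant: str
    raw_value: str
    snippet: str
    offset_start: int
    offset_end: int
    sub_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.offset_start < self.offset_end:
            raise InputError(
                f"invalid offsets {self.offset_start},{self.offset_end} "
                f"for snippet {self.snippet!r}"
            )


@dataclass
class SectionSpan:
    """A named section of a report with its absolute character span."""

    text: str
    offset_start: int
    offset_end: int


@dataclass
class SurgicalEntity:
    """The (specimen site, diagnosis) pair of one surgical report."""

    specimen_name: str
    diagnosis: str
    entity: ExtractedEntity


@dataclass
class BiomarkerBlock:
    """One hyphen-delimited table: its header line, body text and base offset."""

    header: str
    text: str
    base_offset: int


def detect_report_type(report: RawReport, config: Optional[PipelineConfig] = None) -> str:
    """Classify a report by its signature markers.

    Returns the unique type whose signature markers ALL occur in the text;
    ``"unknown"`` when no type matches or more than one does.
    """
    config = config or PipelineConfig()
    if not report.text:
        raise InputError(f"report {report.note_id}: empty text")
    matches = [
        rtype
        for rtype, markers in config.signatures.items()
        if markers and all(_find(report.text, m, 0, config) >= 0 for m in markers)
    ]
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        logger.warning(
            "report %s matches multiple type signatures %s; typed unknown",
            report.note_id,
            matches,
        )
    return "unknown"


def extract_sections(
    report: RawReport, report_type: str, config: Optional[PipelineConfig] = None
) -> dict[str, SectionSpan]:
    """Segment a typed report into named sections with absolute offsets.

    All types may yield a ``summary`` section (between the summary-start and
    summary-end markers, exclusive of both); surgical reports additionally
    yield ``sample_name`` and ``diagnosis`` value spans.  A summary whose end
    marker is missing runs to the end of the text (logged, not an error).
    """
    config = config or PipelineConfig()
    if report_type not in REPORT_TYPES:
        raise InputError(f"cannot segment report of type {report_type!r}")
    text = report.text
    sections: dict[str, SectionSpan] = {}

    start = _find(text, config.summary_start, 0, config)
    if start >= 0:
        body_start = start + len(config.summary_start)
        end = _find(text, config.summary_end, body_start, config)
        if end < 0:
            logger.warning(
                "report %s: %r without %r; summary runs to end of text",
                report.note_id,
                config.summary_start,
                config.summary_end,
            )
            end = len(text)
        sections["summary"] = _trimmed_span(text, body_start, end)

    if report_type == "surgical":
        for name, marker in (
            ("sample_name", config.sample_name_marker),
            ("diagnosis", config.diagnosis_marker),
        ):
            pos = _find(text, marker, 0, config)
            if pos < 0:
                continue
            value_start = pos + len(marker)
            eol = text.find("\n", value_start)
            if eol < 0:
                eol = len(text)
            sections[name] = _trimmed_span(text, value_start, eol)
    return sections


def extract_surgical_entities(
    report: RawReport, config: Optional[PipelineConfig] = None
) -> list[SurgicalEntity]:
    """Extract the single (specimen site, diagnosis) pair of a surgical report.

    One pair per report by design (multi-organ reports are out of scope).
    A report missing either marker is skipped with a logged extraction
    failure and yields an empty list.
    """
    config = config or PipelineConfig()
    sections = extract_sections(report, "surgical", config)
    if "sample_name" not in sections or "diagnosis" not in sections:
        missing = [k for k in ("sample_name", "diagnosis") if k not in sections]
        logger.warning(
            "report %s: surgical extraction failed, missing %s; skipped",
            report.note_id,
            missing,
        )
        return []
    sample = sections["sample_name"]
    diag = sections["diagnosis"]
    if not diag.text:
        logger.warning("report %s: empty diagnosis; skipped", report.note_id)
        return []
    entity = ExtractedEntity(
        section_source_value="surgical",
        lexical_variant=diag.text,
        raw_value="",
        snippet=diag.text,
        offset_start=diag.offset_start,
        offset_end=diag.offset_end,
        sub_id=report.sub_id or find_sub_id(report.text, config),
    )
    return [SurgicalEntity(specimen_name=sample.text, diagnosis=diag.text, entity=entity)]


def extract_biomarker_blocks(
    report: RawReport, config: Optional[PipelineConfig] = None
) -> list[BiomarkerBlock]:
    """Locate the hyphen-delimited biomarker tables of an IHC/molecular report.

    Tables are bounded by lines made of at least ``hyphen_min`` hyphens;
    consecutive delimiter lines are paired first-with-second and so on.
    The header of a table is the nearest preceding non-empty, non-delimiter
    line (the test name in molecular reports).  An unmatched opening
    delimiter extends the table to the end of the text with a warning.
    """
    config = config or PipelineConfig()
    text = report.text
    rule = re.compile(rf"^-{{{config.hyphen_min},}}[ \t]*$", re.MULTILINE)
    fences = list(rule.finditer(text))
    blocks: list[BiomarkerBlock] = []
    for i in range(0, len(fences), 2):
        open_f = fences[i]
        body_start = open_f.end()
        if text[body_start : body_start + 1] == "\n":
            body_start += 1
        if i + 1 < len(fences):
            body_end = fences[i + 1].start()
        else:
            logger.warning(
                "report %s: unmatched table delimiter; table runs to end of text",
                report.note_id,
            )
            body_end = len(text)
        header = ""
        for line in reversed(text[: open_f.start()].splitlines()):
            stripped = line.strip()
            if stripped and not rule.match(stripped):
                header = stripped
                break
        blocks.append(
            BiomarkerBlock(header=header, text=text[body_start:body_end], base_offset=body_start)
        )
    return blocks


def parse_biomarker_block(
    block_text: str,
    base_offset: int = 0,
    config: Optional[PipelineConfig] = None,
    section_source_value: str = "",
    sub_id: str = "",
) -> list[ExtractedEntity]:
    """Parse ``name | value`` rows of one biomarker table into entities.

    A row splits at its FIRST bar: the biomarker name on the left, the raw
    result value on the right (values may contain further bars).  Rows
    without a bar, or with an empty name, are skipped and logged — never
    abort the table.  Offsets are absolute via ``base_offset``.
    """
    config = config or PipelineConfig()
    entities: list[ExtractedEntity] = []
    pos = 0
    for line in block_text.splitlines(keepends=True):
        raw = line.rstrip("\n")
        stripped = raw.strip()
        if stripped:
            if config.bar not in stripped:
                logger.warning("row without %r skipped: %r", config.bar, stripped)
            else:
                name, _, value = stripped.partition(config.bar)
                name = name.strip()
                value = value.strip()
                if not name:
                    logger.warning("row with empty biomarker name skipped: %r", stripped)
                else:
                    lead = len(raw) - len(raw.lstrip())
                    start = base_offset + pos + lead
                    entities.append(
                        ExtractedEntity(
                            section_source_value=section_source_value,
                            lexical_variant=name,
                            raw_value=value,
                            snippet=stripped,
                            offset_start=start,
                            offset_end=start + len(stripped),
                            sub_id=sub_id,
                        )
                    )
        pos += len(line)
    return entities


def count_block_rows(block_text: str) -> int:
    """Number of candidate data rows (non-empty lines) in a table body."""
    return sum(1 for line in block_text.splitlines() if line.strip())


def find_sub_id(text: str, config: Optional[PipelineConfig] = None) -> str:
    """First surgical pathology number in the text, or an empty string."""
    config = config or PipelineConfig()
    m = re.search(config.sub_id_pattern, text)
    return m.group(0) if m else ""


def _find(text: str, needle: str, start: int, config: PipelineConfig) -> int:
    if config.case_sensitive:
        return text.find(needle, start)
    m = re.compile(re.escape(needle), re.IGNORECASE).search(text, start)
    return m.start() if m else -1


def _trimmed_span(text: str, start: int, end: int) -> SectionSpan:
    """Shrink [start, end) to exclude surrounding whitespace."""
    chunk = text[start:end]
    lead = len(chunk) - len(chunk.lstrip())
    trail = len(chunk) - len(chunk.rstrip())
    s, e = start + lead, end - trail
    if s >= e:  # all-whitespace section
        return SectionSpan("", start, start)
    return SectionSpan(text[s:e], s, e)
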