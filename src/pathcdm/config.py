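"""Run configuration for the extraction pipeline.

Everything that varies between report dialects is configuration rather than
code: the per-type signature markers used for report-type detection, section
delimiters, the biomarker-table geometry (minimum hyphen-run length, the
column separator bar), the surgical-number pattern, and the normalization
switches.  Defaults are the literals of the source dialect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for an invalid run configuration."""


def _default_signatures() -> dict[str, list[str]]:
    return {
        "surgical": ["SAMPLE NAME:", "DIAGNOSIS:"],
        "ihc": ["IMMUNOCHEMISTRY TEST REPORT"],
        "molecular": ["MOLECULAR STUDY REPORT"],
    }


def _default_corpus_columns() -> dict[str, str]:
    return {
        "note_id": "note_id",
        "person_id": "person_id",
        "report_type": "report_type",
        "sub_id": "sub_id",
        "note_date": "note_date",
        "text": "text",
    }


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the source dialect as defaults.

    Attributes
    ----------
    signatures
        Per-report-type marker strings; a report is assigned the unique type
        whose markers ALL occur in its text.
    summary_start, summary_end
        Delimiters of the free-text summary section; the span between them
        (exclusive of the markers) is the summary.
    sample_name_marker, diagnosis_marker
        Line markers of the surgical-report fields.
    hyphen_min
        Minimum length of a hyphen run delimiting a biomarker table.
    bar
        Column separator inside a biomarker-table row; rows split at the
        FIRST bar (names may not contain it, values may).
    sub_id_pattern
        Regex for the surgical pathology number linking assay reports back
        to the specimen, e.g. ``"S 110023456"``.
    case_sensitive
        Marker matching mode; the source dialect prints uppercase markers.
    replicate_legacy_negation
        When true, a leading "no ..." phrase without the word "negative" is
        classified positive — the legacy error mode — instead of
        negative+negated.
    braf_more_than_one
        When true, BRAF aggregates positive only for >=2 positive attributes
        (the literal printed rule); default false treats BRAF like NRAS/KRAS
        (>=1 positive).
    key_offset
        Added to every surrogate key, for merging runs.
    run_date
        ISO date stamped on records whose report carries no date.
    """

    signatures: dict[str, list[str]] = field(default_factory=_default_signatures)
    summary_start: str = "SUMMARY:"
    summary_end: str = "EXAMINER:"
    sample_name_marker: str = "SAMPLE NAME:"
    diagnosis_marker: str = "DIAGNOSIS:"
    hyphen_min: int = 3
    bar: str = "|"
    sub_id_pattern: str = r"S \d{9}"
    case_sensitive: bool = True
    replicate_legacy_negation: bool = False
    braf_more_than_one: bool = False
    key_offset: int = 0
    run_date: str = "1970-01-01"
    corpus_columns: dict[str, str] = field(default_factory=_default_corpus_columns)

    def __post_init__(self) -> None:
        if self.hyphen_min < 1:
            raise ConfigError("hyphen_min must be >= 1")
        if len(self.bar) != 1:
            raise ConfigError("bar must be a single character")
        unknown = set(self.signatures) - {"surgical", "ihc", "molecular"}
        if unknown:
            raise ConfigError(f"unknown report types in signatures: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a configuration from a YAML (or JSON) mapping file."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if raw is None:
            return cls()
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
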