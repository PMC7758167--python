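"""Concept dictionary: loading, validation and standard-vocabulary lookups.

Mapping is dictionary-driven by design (determinism over recall): a
versioned, human-editable YAML file bundled with the package maps

* canonical biomarker/test names → LOINC-coded MEASUREMENT concepts,
* normalized result categories → value concepts (SNOMED "Positive" etc.),
* (diagnosis, site) pairs → ICD-O-3 source and SNOMED standard condition
  concepts,
* report types and molecular test names → NOTE_NLP section concepts,
* named fact relationships and CDM domains → their concept identifiers,

plus the alias table used during name canonicalization and the
normalization lexicons.  Concept id 0 is the only unmapped sentinel; every
lookup is total and never raises for an unknown key.

Entries whose identifiers are locally minted (absent from the standard
vocabularies) are flagged ``custom: true`` and surface in the coverage
audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import yaml

logger = logging.getLogger(__name__)


class DictionaryError(ValueError):
    """Raised when a dictionary file fails schema validation; the message
    lists every offending entry."""


@dataclass(frozen=True)
class MeasurementConcept:
    concept_id: int
    code: str
    concept_name: str
    custom: bool = False


@dataclass(frozen=True)
class ConditionConcept:
    source_concept_id: int
    standard_concept_id: int
    icdo3_code: str = ""
    custom: bool = False


@dataclass(frozen=True)
class SectionConcept:
    concept_id: int
    source_value: str


@dataclass(frozen=True)
class RelationshipConcept:
    concept_id: int
    inverse_concept_id: int
    custom: bool = False


@dataclass
class ConceptDictionary:
    """In-memory form of the concept dictionary file."""

    version: int
    aliases: dict[str, str] = field(default_factory=dict)
    measurement_map: dict[str, MeasurementConcept] = field(default_factory=dict)
    value_map: dict[str, int] = field(default_factory=dict)
    condition_map: dict[tuple[str, str], ConditionConcept] = field(default_factory=dict)
    section_map: dict[str, SectionConcept] = field(default_factory=dict)
    relationship_concepts: dict[str, RelationshipConcept] = field(default_factory=dict)
    domain_concepts: dict[str, int] = field(default_factory=dict)
    lexicons: dict[str, list[str]] = field(default_factory=dict)


def bundled_dictionary_path() -> Path:
    """Path of the concept dictionary shipped with the package."""
    return Path(str(resources.files("pathcdm").joinpath("data/dictionary.yaml")))


def load_dictionary(path: str | Path | None = None) -> ConceptDictionary:
    """Load and validate a concept dictionary file (bundled one by default).

    Rejects, listing every offence: duplicate canonical names, concept-id
    collisions between measurement entries, negative identifiers, alias
    targets absent from the measurement map, and malformed rows.
    """
    path = Path(path) if path is not None else bundled_dictionary_path()
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict) or not raw:
        raise DictionaryError(f"{path}: empty or non-mapping dictionary file")
    errors: list[str] = []

    def _id(value: Any, where: str) -> int:
        if not isinstance(value, int) or isinstance(value, bool) or value < 0:
            errors.append(f"{where}: concept id must be a non-negative integer, got {value!r}")
            return 0
        return value

    d = ConceptDictionary(version=int(raw.get("version", 0)))

    seen_ids: dict[int, str] = {}
    for row in raw.get("measurements", []) or []:
        name = str(row.get("name", "")).strip()
        if not name:
            errors.append(f"measurements: entry without a name: {row!r}")
            continue
        if name in d.measurement_map:
            errors.append(f"measurements: duplicate canonical name {name!r}")
            continue
        cid = _id(row.get("concept_id"), f"measurements[{name}]")
        if cid and cid in seen_ids:
            errors.append(
                f"measurements[{name}]: concept_id {cid} collides with {seen_ids[cid]!r}"
            )
        seen_ids.setdefault(cid, name)
        d.measurement_map[name] = MeasurementConcept(
            concept_id=cid,
            code=str(row.get("code", "") or ""),
            concept_name=str(row.get("concept_name", "") or ""),
            custom=bool(row.get("custom", False)),
        )

    for row in raw.get("values", []) or []:
        category = str(row.get("category", "")).strip()
        if not category:
            errors.append(f"values: entry without a category: {row!r}")
            continue
        if category in d.value_map:
            errors.append(f"values: duplicate category {category!r}")
            continue
        d.value_map[category] = _id(row.get("concept_id"), f"values[{category}]")

    for row in raw.get("conditions", []) or []:
        diagnosis = _norm_key(str(row.get("diagnosis", "")))
        site = _norm_key(str(row.get("site", "") or ""))
        if not diagnosis:
            errors.append(f"conditions: entry without a diagnosis: {row!r}")
            continue
        key = (diagnosis, site)
        if key in d.condition_map:
            errors.append(f"conditions: duplicate (diagnosis, site) {key!r}")
            continue
        d.condition_map[key] = ConditionConcept(
            source_concept_id=_id(row.get("source_concept_id"), f"conditions[{key}]"),
            standard_concept_id=_id(row.get("standard_concept_id"), f"conditions[{key}]"),
            icdo3_code=str(row.get("icdo3", "") or ""),
            custom=bool(row.get("custom", False)),
        )

    for row in raw.get("sections", []) or []:
        key = str(row.get("key", "")).strip()
        if not key:
            errors.append(f"sections: entry without a key: {row!r}")
            continue
        if key in d.section_map:
            errors.append(f"sections: duplicate key {key!r}")
            continue
        d.section_map[key] = SectionConcept(
            concept_id=_id(row.get("concept_id"), f"sections[{key}]"),
            source_value=str(row.get("source_value", "") or ""),
        )

    for name, row in (raw.get("relationships", {}) or {}).items():
        d.relationship_concepts[str(name)] = RelationshipConcept(
            concept_id=_id(row.get("concept_id"), f"relationships[{name}]"),
            inverse_concept_id=_id(row.get("inverse_concept_id"), f"relationships[{name}]"),
            custom=bool(row.get("custom", False)),
        )

    for name, cid in (raw.get("domains", {}) or {}).items():
        d.domain_concepts[str(name)] = _id(cid, f"domains[{name}]")

    for raw_name, target in (raw.get("aliases", {}) or {}).items():
        d.aliases[str(raw_name)] = str(target)
        if str(target) not in d.measurement_map and str(target) not in d.section_map:
            errors.append(f"aliases: target {target!r} of {raw_name!r} not in measurement map")

    for name, words in (raw.get("lexicons", {}) or {}).items():
        d.lexicons[str(name)] = [str(w) for w in (words or [])]

    if errors:
        raise DictionaryError(f"{path}: invalid dictionary:\n  " + "\n  ".join(errors))
    return d


def serialize_dictionary(d: ConceptDictionary) -> str:
    """Render a dictionary back to its YAML file form (keys sorted)."""
    raw: dict[str, Any] = {
        "version": d.version,
        "aliases": dict(sorted(d.aliases.items())),
        "measurements": [
            {
                "name": name,
                "concept_id": m.concept_id,
                "code": m.code,
                "concept_name": m.concept_name,
                **({"custom": True} if m.custom else {}),
            }
            for name, m in sorted(d.measurement_map.items())
        ],
        "values": [
            {"category": c, "concept_id": cid} for c, cid in sorted(d.value_map.items())
        ],
        "conditions": [
            {
                "diagnosis": diag,
                "site": site,
                "source_concept_id": c.source_concept_id,
                "standard_concept_id": c.standard_concept_id,
                "icdo3": c.icdo3_code,
                **({"custom": True} if c.custom else {}),
            }
            for (diag, site), c in sorted(d.condition_map.items())
        ],
        "sections": [
            {"key": k, "concept_id": s.concept_id, "source_value": s.source_value}
            for k, s in sorted(d.section_map.items())
        ],
        "relationships": {
            name: {
                "concept_id": r.concept_id,
                "inverse_concept_id": r.inverse_concept_id,
                **({"custom": True} if r.custom else {}),
            }
            for name, r in sorted(d.relationship_concepts.items())
        },
        "domains": dict(sorted(d.domain_concepts.items())),
        "lexicons": {name: list(words) for name, words in sorted(d.lexicons.items())},
    }
    return yaml.safe_dump(raw, sort_keys=False, allow_unicode=True)


def lookup_measurement(canonical_name: str, d: ConceptDictionary) -> tuple[int, str, str]:
    """(concept_id, code, concept_name) for a canonical name; (0, "", "")
    when unmapped — never an exception."""
    m = d.measurement_map.get(canonical_name)
    if m is None:
        return (0, "", "")
    return (m.concept_id, m.code, m.concept_name)


def lookup_value(category: str, d: ConceptDictionary) -> int:
    """Value concept id for a normalized category; 0 when unmapped."""
    return d.value_map.get(category, 0)


def lookup_condition(diagnosis: str, site: str, d: ConceptDictionary) -> tuple[int, int]:
    """(source_concept_id, standard_concept_id) for a diagnosis at a site.

    Keys are matched after lowercasing and whitespace collapsing; a
    site-specific entry wins over the site-agnostic one.  Unmapped →
    (0, 0) with a logged vocabulary gap.
    """
    diag = _norm_key(diagnosis)
    entry = d.condition_map.get((diag, _norm_key(site))) or d.condition_map.get((diag, ""))
    if entry is None:
        logger.info("vocabulary gap: unmapped diagnosis %r (site %r)", diagnosis, site)
        return (0, 0)
    return (entry.source_concept_id, entry.standard_concept_id)


def lookup_section(report_type_or_test: str, d: ConceptDictionary) -> int:
    """Section concept id for a report type or molecular test name; 0 when
    unknown."""
    entry = d.section_map.get(report_type_or_test)
    return entry.concept_id if entry else 0


def lookup_section_label(report_type_or_test: str, d: ConceptDictionary) -> str:
    """The section_source_value label for a report type or test name."""
    entry = d.section_map.get(report_type_or_test)
    return entry.source_value if entry else report_type_or_test


def audit_dictionary(d: ConceptDictionary) -> dict[str, int]:
    """Coverage audit: distinct entry counts and how many are locally minted."""
    return {
        "measurements": len(d.measurement_map),
        "custom_measurements": sum(1 for m in d.measurement_map.values() if m.custom),
        "values": len(d.value_map),
        "conditions": len(d.condition_map),
        "custom_conditions": sum(1 for c in d.condition_map.values() if c.custom),
        "sections": len(d.section_map),
        "aliases": len(d.aliases),
        "relationships": len(d.relationship_concepts),
        "domains": len(d.domain_concepts),
    }


def _norm_key(text: str) -> str:
    return " ".join(text.lower().split())
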