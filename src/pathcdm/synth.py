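"""Synthetic pathology-report corpora with gold annotations.

Generates the three report dialects the pipeline consumes — surgical
specimen, immunohistochemistry and molecular study — from the same
template fragments the extraction rules target ("SAMPLE NAME:",
"DIAGNOSIS:", "SUMMARY: ... EXAMINER:", hyphen-fenced "name | value"
tables, "S"-prefixed surgical pathology numbers), together with gold
annotations produced jointly with the text (never re-derived from it):
expected entities with exact character offsets, normalized categories,
molecular test summaries and specimen linkage ids.

A corruption harness injects the error modes a production run must
survive: dropped section markers, rows whose column bar is missing,
"No ..." negation phrases and whitespace noise; the gold is updated to the
expected skip/negation behaviour so corrupted corpora remain fully
testable.

One explicitly seeded pseudorandom stream per corpus; a given seed fully
determines the output.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from pathcdm.normalize import MSI_MARKERS
from pathcdm.parser import RawReport

#: Default IHC panel: canonical biomarker names with per-marker positivity
#: probabilities loosely following the observed positive/negative balance of
#: colorectal IHC panels (EGFR and mismatch-repair stains mostly positive,
#: p53/C-erbB2 mostly negative).
DEFAULT_IHC_PANEL: tuple[tuple[str, float], ...] = (
    ("EGFR", 0.8),
    ("Ki-67", 0.9),
    ("hMLH1", 0.85),
    ("p53", 0.35),
    ("CD3", 0.5),
    ("C-erbB2", 0.25),
)

#: Raw-name qualifiers as printed in reports (stripped by canonicalization).
RAW_NAME_QUALIFIERS = {"EGFR": "EGFR (GI)"}

MUTATION_ATTRIBUTES: dict[str, tuple[str, ...]] = {
    "NRAS mutation": ("Codon 12 (exon 2)", "Codon 13 (exon 2)", "Codon 61 (exon 3)"),
    "KRAS mutation": ("Codon 12 (exon 2)", "Codon 13 (exon 2)", "Codon 61 (exon 3)"),
    "BRAF mutation": ("V600E", "K601E"),
    "MSI": MSI_MARKERS,
}

SITES = (
    "sigmoid colon",
    "ascending colon",
    "rectum",
    "transverse colon",
    "cecum",
    "descending colon",
)

DIAGNOSES = (
    "tubular adenoma, nos",
    "adenocarcinoma, nos",
    "tubulovillous adenoma, nos",
    "mucinous adenocarcinoma",
    "neuroendocrine tumor, nos",
)

NEGATION_PHRASES = (
    "No endolymphatic tumor emboli",
    "No lymphoepithelial lesion",
    "No tumor cells identified",
)

POSITIVE_IHC_VALUES = ("1+/3", "2+/3", "3+/3", "Positive")
POSITIVE_MOLECULAR_VALUES = ("Positive", "Missense mutation [c.38G>A, p.Gly14Asp]")
NEGATIVE_MOLECULAR_VALUES = ("Negative", "Not detected")

CORRUPTION_MODES = ("drop_marker", "remove_bar", "inject_no_phrase", "whitespace_noise")


class ParameterError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass
class GeneratorParams:
    """Knobs of the corpus generator; the seed fully determines the output."""

    n_patients: int = 10
    surgical_per_patient: int = 1
    ihc_per_patient: int = 1
    molecular_per_patient: int = 1
    ihc_panel: Sequence[tuple[str, float]] = DEFAULT_IHC_PANEL
    molecular_tests: Sequence[str] = tuple(MUTATION_ATTRIBUTES)
    mutation_positive_prob: float = 0.2
    msi_positive_prob: float = 0.15
    negation_phrase_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [p for _, p in self.ihc_panel] + [
            self.mutation_positive_prob,
            self.msi_positive_prob,
            self.negation_phrase_prob,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParameterError("probabilities must lie in [0, 1]")
        if min(self.n_patients, self.surgical_per_patient) < 0:
            raise ParameterError("counts must be non-negative")
        unknown = set(self.molecular_tests) - set(MUTATION_ATTRIBUTES)
        if unknown:
            raise ParameterError(f"unknown molecular tests: {sorted(unknown)}")


@dataclass
class GoldEntity:
    """Expected extraction + normalization outcome for one entity."""

    section: str  # report type, or molecular test name
    lexical_variant: str  # raw name as printed
    canonical_name: str
    raw_value: str
    snippet: str
    offset_start: int
    offset_end: int
    category: str  # normalized category; "" for surgical diagnosis entities
    negated: bool = False
    test_name: str = ""  # owning molecular test, "" otherwise


@dataclass
class GoldAnnotation:
    """Per-report gold: entities, summaries and linkage, generated jointly
    with the text."""

    note_id: str
    report_type: str
    sub_id: str
    entities: list[GoldEntity] = field(default_factory=list)
    summaries: list[tuple[str, str]] = field(default_factory=list)
    specimen_name: str = ""
    diagnosis: str = ""
    expected_parse_failure: bool = False
    n_skipped_rows: int = 0


class _Builder:
    """Accumulates report text while tracking absolute character offsets."""

    def __init__(self) -> None:
        self._parts: list[str] = []
        self._len = 0

    def add(self, text: str) -> int:
        """Append text, returning its starting offset."""
        start = self._len
        self._parts.append(text)
        self._len += len(text)
        return start

    def line(self, text: str = "") -> int:
        start = self.add(text)
        self.add("\n")
        return start

    def text(self) -> str:
        return "".join(self._parts)


def generate_corpus(
    params: Optional[GeneratorParams] = None,
) -> tuple[list[RawReport], list[GoldAnnotation]]:
    """Generate a corpus of the three dialects with gold annotations."""
    params = params or GeneratorParams()
    rng = random.Random(params.seed)
    reports: list[RawReport] = []
    golds: list[GoldAnnotation] = []
    note_seq = 0
    for p in range(params.n_patients):
        person_id = f"P{p + 1:04d}"
        sub_id = f"S {110000000 + p:09d}"
        for _ in range(params.surgical_per_patient):
            note_seq += 1
            reports_gold = _surgical_report(f"N{note_seq:05d}", person_id, sub_id, rng)
            reports.append(reports_gold[0])
            golds.append(reports_gold[1])
        for _ in range(params.ihc_per_patient):
            note_seq += 1
            r, g = _ihc_report(f"N{note_seq:05d}", person_id, sub_id, rng, params)
            reports.append(r)
            golds.append(g)
        for _ in range(params.molecular_per_patient):
            note_seq += 1
            r, g = _molecular_report(f"N{note_seq:05d}", person_id, sub_id, rng, params)
            reports.append(r)
            golds.append(g)
    return reports, golds


def _surgical_report(
    note_id: str, person_id: str, sub_id: str, rng: random.Random
) -> tuple[RawReport, GoldAnnotation]:
    site = rng.choice(SITES)
    diagnosis = rng.choice(DIAGNOSES)
    b = _Builder()
    b.line("SURGICAL PATHOLOGY REPORT")
    b.line(f"Pathology No: {sub_id}")
    b.line()
    b.add("SAMPLE NAME: ")
    b.line(site)
    b.add("DIAGNOSIS: ")
    diag_start = b.add(diagnosis)
    b.line()
    b.line()
    b.line("EXAMINER: staff pathologist")
    text = b.text()
    gold = GoldAnnotation(
        note_id=note_id,
        report_type="surgical",
        sub_id=sub_id,
        specimen_name=site,
        diagnosis=diagnosis,
        entities=[
            GoldEntity(
                section="surgical",
                lexical_variant=diagnosis,
                canonical_name=diagnosis,
                raw_value="",
                snippet=diagnosis,
                offset_start=diag_start,
                offset_end=diag_start + len(diagnosis),
                category="",
            )
        ],
    )
    report = RawReport(
        note_id=note_id, person_id=person_id, text=text, report_type="surgical", sub_id=sub_id
    )
    return report, gold


def _ihc_report(
    note_id: str,
    person_id: str,
    sub_id: str,
    rng: random.Random,
    params: GeneratorParams,
) -> tuple[RawReport, GoldAnnotation]:
    b = _Builder()
    b.line("IMMUNOCHEMISTRY TEST REPORT")
    b.line(f"Pathology No: {sub_id}")
    b.line()
    b.line("-" * 40)
    entities: list[GoldEntity] = []
    for name, p_positive in params.ihc_panel:
        raw_name = RAW_NAME_QUALIFIERS.get(name, name)
        positive = rng.random() < p_positive
        negated = False
        if positive:
            value = rng.choice(POSITIVE_IHC_VALUES)
            category = "positive"
        elif rng.random() < params.negation_phrase_prob:
            value = rng.choice(NEGATION_PHRASES)
            category, negated = "negative", True
        else:
            value = "Negative"
            category = "negative"
        row = f"{raw_name} | {value}"
        start = b.line(row)
        entities.append(
            GoldEntity(
                section="ihc",
                lexical_variant=raw_name,
                canonical_name=name,
                raw_value=value,
                snippet=row,
                offset_start=start,
                offset_end=start + len(row),
                category=category,
                negated=negated,
            )
        )
    b.line("-" * 40)
    b.line("SUMMARY: see individual stain results. EXAMINER: staff pathologist")
    report = RawReport(
        note_id=note_id, person_id=person_id, text=b.text(), report_type="ihc", sub_id=sub_id
    )
    gold = GoldAnnotation(
        note_id=note_id, report_type="ihc", sub_id=sub_id, entities=entities
    )
    return report, gold


def _molecular_report(
    note_id: str,
    person_id: str,
    sub_id: str,
    rng: random.Random,
    params: GeneratorParams,
) -> tuple[RawReport, GoldAnnotation]:
    b = _Builder()
    b.line("MOLECULAR STUDY REPORT")
    b.line(f"Pathology No: {sub_id}")
    b.line()
    entities: list[GoldEntity] = []
    summaries: list[tuple[str, str]] = []
    for test in params.molecular_tests:
        b.line(test)
        b.line("-" * 36)
        n_positive = 0
        for attribute in MUTATION_ATTRIBUTES[test]:
            p = params.msi_positive_prob if test == "MSI" else params.mutation_positive_prob
            positive = rng.random() < p
            if positive:
                value = rng.choice(POSITIVE_MOLECULAR_VALUES)
                category = "positive"
                n_positive += 1
            else:
                value = rng.choice(NEGATIVE_MOLECULAR_VALUES)
                category = "negative"
            row = f"{attribute} | {value}"
            start = b.line(row)
            entities.append(
                GoldEntity(
                    section=test,
                    lexical_variant=attribute,
                    canonical_name=_strip_qualifier(attribute),
                    raw_value=value,
                    snippet=row,
                    offset_start=start,
                    offset_end=start + len(row),
                    category=category,
                    test_name=test,
                )
            )
        b.line("-" * 36)
        summaries.append((test, _summary_category(test, n_positive)))
    b.line("SUMMARY: see individual test results. EXAMINER: staff pathologist")
    report = RawReport(
        note_id=note_id,
        person_id=person_id,
        text=b.text(),
        report_type="molecular",
        sub_id=sub_id,
    )
    gold = GoldAnnotation(
        note_id=note_id,
        report_type="molecular",
        sub_id=sub_id,
        entities=entities,
        summaries=summaries,
    )
    return report, gold


def _summary_category(test: str, n_positive: int) -> str:
    if test == "MSI":
        return "msi_high" if n_positive >= 2 else ("msi_low" if n_positive == 1 else "mss")
    return "positive" if n_positive >= 1 else "negative"


def _strip_qualifier(name: str) -> str:
    return " ".join(re.sub(r"\s*\([^)]*\)", "", name).split())


# ---------------------------------------------------------------------------
# Corruption harness


def corrupt_corpus(
    corpus: tuple[list[RawReport], list[GoldAnnotation]],
    modes: Sequence[str],
    seed: int,
    rate: float = 0.5,
) -> tuple[list[RawReport], list[GoldAnnotation]]:
    """Apply corruption modes to a fraction of eligible reports.

    The gold is updated to the expected downstream behaviour: dropped
    markers make the surgical report an expected parse failure, removed
    bars make the affected rows expected skips (molecular summaries are
    recomputed over the surviving attributes), injected "No ..." phrases
    flip the gold category to negative+negated, and whitespace noise
    shifts offsets without changing any expectation.
    """
    unknown = set(modes) - set(CORRUPTION_MODES)
    if unknown:
        raise ParameterError(f"unknown corruption modes: {sorted(unknown)}")
    rng = random.Random(seed)
    out_reports: list[RawReport] = []
    out_golds: list[GoldAnnotation] = []
    for report, gold in zip(*corpus):
        text = report.text
        gold = _copy_gold(gold)
        if "drop_marker" in modes and gold.report_type == "surgical" and rng.random() < rate:
            text = text.replace("DIAGNOSIS:", "DIAGNOSIS-", 1)  # same length: no shifts
            gold.entities = []
            gold.diagnosis = ""
            gold.expected_parse_failure = True
        if (
            "remove_bar" in modes
            and gold.report_type in ("ihc", "molecular")
            and gold.entities
            and rng.random() < rate
        ):
            victim = rng.randrange(len(gold.entities))
            e = gold.entities[victim]
            bar_pos = e.offset_start + e.snippet.index("|")
            text = text[:bar_pos] + " " + text[bar_pos + 1 :]  # same length: no shifts
            del gold.entities[victim]
            gold.n_skipped_rows += 1
            if gold.report_type == "molecular":
                gold.summaries = _recompute_summaries(gold)
        if "inject_no_phrase" in modes and gold.report_type == "ihc" and gold.entities:
            for e in gold.entities:
                if e.category == "positive" and rng.random() < rate:
                    phrase = rng.choice(NEGATION_PHRASES)
                    text = _replace_value(text, gold, e, phrase)
                    e.category, e.negated = "negative", True
        if "whitespace_noise" in modes and rng.random() < rate:
            text = _pad_line_ends(text, gold, rng)
        out_reports.append(
            RawReport(
                note_id=report.note_id,
                person_id=report.person_id,
                text=text,
                report_type=report.report_type,
                sub_id=report.sub_id,
                note_date=report.note_date,
            )
        )
        out_golds.append(gold)
    return out_reports, out_golds


def _replace_value(text: str, gold: GoldAnnotation, e: GoldEntity, new_value: str) -> str:
    """Swap one row's raw value in place, shifting later gold offsets."""
    value_start = e.offset_start + (len(e.snippet) - len(e.raw_value))
    delta = len(new_value) - len(e.raw_value)
    text = text[:value_start] + new_value + text[value_start + len(e.raw_value) :]
    e.snippet = e.snippet[: len(e.snippet) - len(e.raw_value)] + new_value
    e.raw_value = new_value
    e.offset_end = e.offset_start + len(e.snippet)
    if delta:
        for other in gold.entities:
            if other is not e and other.offset_start > value_start:
                other.offset_start += delta
                other.offset_end += delta
    return text


def _pad_line_ends(text: str, gold: GoldAnnotation, rng: random.Random) -> str:
    """Append trailing spaces to a few lines, shifting later gold offsets."""
    lines = text.split("\n")
    out: list[str] = []
    pos = 0  # cursor in ORIGINAL coordinates; shifts are keyed to them
    shifts: list[tuple[int, int]] = []  # (original position, inserted length)
    for line in lines:
        pad = " " * rng.randrange(3) if line.strip() and rng.random() < 0.3 else ""
        out.append(line + pad)
        if pad:
            shifts.append((pos + len(line), len(pad)))
        pos += len(line) + 1
    for e in gold.entities:
        delta = sum(n for p, n in shifts if p <= e.offset_start)
        e.offset_start += delta
        e.offset_end += delta
    return "\n".join(out)


def _recompute_summaries(gold: GoldAnnotation) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    for test, _ in gold.summaries:
        n_positive = sum(
            1 for e in gold.entities if e.test_name == test and e.category == "positive"
        )
        out.append((test, _summary_category(test, n_positive)))
    return out


def _copy_gold(gold: GoldAnnotation) -> GoldAnnotation:
    return GoldAnnotation(
        note_id=gold.note_id,
        report_type=gold.report_type,
        sub_id=gold.sub_id,
        entities=[GoldEntity(**asdict(e)) for e in gold.entities],
        summaries=list(gold.summaries),
        specimen_name=gold.specimen_name,
        diagnosis=gold.diagnosis,
        expected_parse_failure=gold.expected_parse_failure,
        n_skipped_rows=gold.n_skipped_rows,
    )


# ---------------------------------------------------------------------------
# Gold serialization


def save_gold(golds: Sequence[GoldAnnotation], path: str | Path) -> None:
    """Write gold annotations to JSON."""
    data = [asdict(g) for g in golds]
    Path(path).write_text(json.dumps(data, indent=1), encoding="utf-8")


def load_gold(path: str | Path) -> list[GoldAnnotation]:
    """Read gold annotations from JSON."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    golds = []
    for g in data:
        entities = [GoldEntity(**e) for e in g.pop("entities", [])]
        summaries = [tuple(s) for s in g.pop("summaries", [])]
        golds.append(GoldAnnotation(entities=entities, summaries=summaries, **g))
    return golds
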