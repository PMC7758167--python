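"""Biomarker-name canonicalization and result-value normalization.

IHC results arrive as score strings ("1+/3", "2+/3"), category words
("Positive", "Negative") or short narratives ("No endolymphatic tumor
emboli").  The site's scoring convention maps any score of 1+ and above to
*positive*.  A leading, word-bounded "no ..." is a negation phrase and is
classified negative with the negation flag set; narratives that merely
contain "negative" are negative without negation.  Molecular results are
either category words or mutation narratives ("Missense mutation
[c.38G>A, p.Gly14Asp]"), the latter counting as positive with the
narrative preserved verbatim.

Per-attribute molecular results aggregate to test-level summaries:
RAS/RAF mutation tests are positive iff at least one codon attribute is
positive; the five-marker MSI panel (BAT26, BAT25, D5S346, D17S250,
D2S123) classifies as MSI-H with >=2 positive markers, MSI-L with exactly
one, MSS with none.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from pathcdm.config import PipelineConfig

logger = logging.getLogger(__name__)

CATEGORIES = ("positive", "negative", "msi_high", "msi_low", "mss", "unknown")

#: The MSI panel marker names, in reporting order.
MSI_MARKERS = ("BAT26", "BAT25", "D5S346", "D17S250", "D2S123")

#: Canonical molecular test labels handled by the aggregator.
MOLECULAR_TESTS = ("NRAS mutation", "KRAS mutation", "BRAF mutation", "MSI")

_SCORE_RE = re.compile(r"^\s*([0-9]+)\s*\+\s*/\s*[0-9]+\s*$")
_NO_PREFIX_RE = re.compile(r"^no\b", re.IGNORECASE)
_MUTATION_HINT_RE = re.compile(r"\bmutation\b|\[[cpgmnr]\.", re.IGNORECASE)

_DEFAULT_NEGATIVE_LEXICON = ("negative", "not detected", "none identified")


class AggregationError(ValueError):
    """Raised for a molecular test name the aggregator does not know."""


@dataclass
class NormalizedResult:
    """Categorical result with negation flag; the raw string is preserved
    verbatim in ``narrative``."""

    category: str
    negated: bool
    narrative: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.negated and self.category not in ("negative", "unknown"):
            raise ValueError("negated results must be negative or unknown")


@dataclass
class MolecularSummary:
    """Test-level aggregate over per-attribute molecular results."""

    test_name: str
    attributes: list[tuple[str, NormalizedResult]] = field(default_factory=list)
    summary_category: str = "unknown"


def canonicalize_name(raw_name: str, aliases: Optional[dict[str, str]] = None) -> str:
    """Regularize a biomarker/test name: drop parenthetical qualifiers,
    collapse whitespace, then apply the alias table.

    Never fails: unknown names are returned cleaned but un-aliased, so that
    downstream concept lookup can report them as unmapped rather than lose
    them.  E.g. ``"EGFR (GI)"`` → ``"EGFR"``.
    """
    cleaned = re.sub(r"\s*\([^)]*\)", "", raw_name)
    cleaned = " ".join(cleaned.split())
    if aliases:
        return aliases.get(cleaned, cleaned)
    return cleaned


def normalize_ihc_value(
    raw_value: str, config: Optional[PipelineConfig] = None
) -> NormalizedResult:
    """Normalize an IHC raw result string to a categorical result.

    Rules, in order: an ``n+/m`` score with n >= 1 is positive; a leading
    word-bounded "no" marks a negation phrase (negative, negated); the word
    "negative" anywhere marks negative; the word "positive" marks positive;
    anything else is unknown.  The raw string is kept as the narrative.
    """
    config = config or PipelineConfig()
    value = raw_value.strip()
    lowered = value.lower()
    m = _SCORE_RE.match(value)
    if m and int(m.group(1)) >= 1:
        return NormalizedResult("positive", False, raw_value)
    if _NO_PREFIX_RE.match(value) and "negative" not in lowered:
        if config.replicate_legacy_negation:
            # Legacy error mode: rules keyed on the word "negative" only, so
            # negation phrases fell through to positive.
            return NormalizedResult("positive", False, raw_value)
        return NormalizedResult("negative", True, raw_value)
    if "negative" in lowered:
        return NormalizedResult("negative", False, raw_value)
    if "positive" in lowered:
        return NormalizedResult("positive", False, raw_value)
    return NormalizedResult("unknown", False, raw_value)


def normalize_molecular_value(
    raw_value: str, negative_lexicon: Sequence[str] = _DEFAULT_NEGATIVE_LEXICON
) -> NormalizedResult:
    """Normalize a molecular raw result to a categorical result.

    "Positive", or a mutation narrative (the word "mutation" or an
    HGVS-like bracketed change such as ``[c.38G>A, p.Gly14Asp]``), is
    positive with the narrative preserved verbatim; the negative lexicon
    ("Negative", "Not detected", ...; config-extensible) is negative;
    anything else is unknown.
    """
    value = raw_value.strip()
    lowered = value.lower()
    if any(term in lowered for term in negative_lexicon):
        return NormalizedResult("negative", False, raw_value)
    if "positive" in lowered or _MUTATION_HINT_RE.search(value):
        return NormalizedResult("positive", False, raw_value)
    return NormalizedResult("unknown", False, raw_value)


def aggregate_molecular(
    test_name: str,
    attribute_results: Sequence[tuple[str, NormalizedResult]],
    config: Optional[PipelineConfig] = None,
) -> MolecularSummary:
    """Aggregate per-attribute molecular results into a test-level summary.

    Mutation tests (NRAS/KRAS/BRAF) are positive iff at least one attribute
    is positive.  MSI counts positive markers over the five-marker panel:
    >=2 → MSI-H, exactly 1 → MSI-L, 0 → MSS.  Missing attributes count as
    non-positive.  The BRAF threshold can be raised to two via
    ``braf_more_than_one`` (the literal legacy rule).
    """
    config = config or PipelineConfig()
    if test_name not in MOLECULAR_TESTS:
        raise AggregationError(f"unknown molecular test {test_name!r}")
    n_positive = sum(1 for _, r in attribute_results if r.category == "positive")
    if test_name == "MSI":
        if n_positive >= 2:
            category = "msi_high"
        elif n_positive == 1:
            category = "msi_low"
        else:
            category = "mss"
    else:
        threshold = 2 if (test_name == "BRAF mutation" and config.braf_more_than_one) else 1
        category = "positive" if n_positive >= threshold else "negative"
    return MolecularSummary(
        test_name=test_name,
        attributes=list(attribute_results),
        summary_category=category,
    )
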