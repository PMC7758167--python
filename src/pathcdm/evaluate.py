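"""Precision / recall / F-measure harness for extraction quality.

The harness distinguishes two levels of agreement, mirroring a manual
audit in which reviewers judge separately whether an entity was *found*
and whether its transformed value is *correct*:

* **recall** counts gold entities that were located at all — matched on
  ``(note_id, offset_start, offset_end, lexical_variant)``;
* **precision** counts predictions that are fully correct — the span key
  plus the normalized category.

With every located entity also normalized correctly the two coincide.
F is the harmonic mean of the two percentages.  Matching is exact-key;
partial-overlap credit is out of scope.  Values are kept at full
precision internally and rounded half-up only at presentation (one
decimal for precision/recall, two for F).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from pathcdm.synth import GoldAnnotation

#: Full exact-match key of one entity; the first four fields are the span key.
EntityKey = tuple[str, int, int, str, str]


@dataclass
class EvalResult:
    """Extraction quality on one report set, percent scale."""

    entity_count: int  # gold entities
    extracted_count: int  # predicted entities
    true_positives: int  # fully correct predictions (precision numerator)
    found_count: int  # gold entities located (recall numerator)
    precision: float
    recall: float
    f_measure: float

    @classmethod
    def from_counts(
        cls,
        true_positives: int,
        extracted: int,
        gold: int,
        found: Optional[int] = None,
    ) -> "EvalResult":
        """Compute P/R/F from raw counts.

        ``found`` (the recall numerator) defaults to ``true_positives``,
        the strict reading in which only a fully correct prediction counts
        as recalled.  An empty prediction against an empty gold is perfect
        agreement (100/100/100); otherwise empty denominators score zero.
        """
        found = true_positives if found is None else found
        if true_positives > min(extracted, gold) or found > gold:
            raise ValueError("hit counts cannot exceed the totals")
        if extracted == 0 and gold == 0:
            p = r = 100.0
        else:
            p = 100.0 * true_positives / extracted if extracted else 0.0
            r = 100.0 * found / gold if gold else 0.0
        f = 2 * p * r / (p + r) if (p + r) else 0.0
        return cls(
            entity_count=gold,
            extracted_count=extracted,
            true_positives=true_positives,
            found_count=found,
            precision=p,
            recall=r,
            f_measure=f,
        )

    def formatted(self) -> dict[str, str]:
        """Presentation form: half-up rounding at the customary precision."""
        return {
            "precision": _round(self.precision, "0.1"),
            "recall": _round(self.recall, "0.1"),
            "f_measure": _round(self.f_measure, "0.01"),
        }


def evaluate(
    predicted: Iterable[EntityKey], gold: Iterable[EntityKey] | Sequence[GoldAnnotation]
) -> EvalResult:
    """Score predicted entity keys against gold."""
    gold = list(gold)
    if gold and isinstance(gold[0], GoldAnnotation):
        gold_set = set(gold_keys(gold))  # type: ignore[arg-type]
    else:
        gold_set = set(gold)  # type: ignore[arg-type]
    pred_set = set(predicted)
    tp = len(pred_set & gold_set)
    found = len({k[:4] for k in pred_set} & {k[:4] for k in gold_set})
    return EvalResult.from_counts(tp, len(pred_set), len(gold_set), found=found)


def gold_keys(golds: Sequence[GoldAnnotation]) -> list[EntityKey]:
    """Exact-match keys of every gold entity in a corpus."""
    return [
        (g.note_id, e.offset_start, e.offset_end, e.canonical_name, e.category)
        for g in golds
        for e in g.entities
    ]


def _round(value: float, quantum: str) -> str:
    return str(Decimal(repr(value)).quantize(Decimal(quantum), rounding=ROUND_HALF_UP))
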