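# Methods

## The extraction model

`pathcdm` treats a pathology report as a semi-structured document in one of
three dialects — surgical specimen, immunohistochemistry (IHC), molecular
study — and extracts facts with deterministic pattern rules rather than a
learned model.  The assumptions this rests on:

* **Marker-anchored structure.**  The fields of interest sit behind literal
  markers (`SAMPLE NAME:`, `DIAGNOSIS:`) or between delimiters
  (`SUMMARY: … EXAMINER:`), and biomarker results sit in tables fenced by
  runs of hyphens with one `name | value` row per result.  All of these
  literals are configuration (`PipelineConfig`), so another institution's
  dialect is a config change, not a code change.
* **One specimen per surgical report.**  Multi-organ surgical reports are
  out of scope; a surgical report yields exactly one (site, diagnosis)
  pair, one SPECIMEN row and one CONDITION_OCCURRENCE row.
* **Specimen-number linkage.**  IHC and molecular reports reference the
  surgical specimen through an `S`-prefixed pathology number
  (default pattern `S \d{9}`); record linkage additionally requires
  person-id agreement, so a stray number in another patient's report never
  creates a relationship.

Offsets are 0-based, half-open `[start, end)` spans of the trimmed snippet
only, serialized `"start,end"`.  The invariant enforced throughout:
slicing the original text with an entity's offsets reproduces its snippet
byte for byte.

## Normalization rules

IHC values, in rule order (first hit wins):

| rule | category |
| --- | --- |
| score `n+/m`, n ≥ 1 (site convention: 1+, 2+, 3+ all count as expressed) | positive |
| leading word-bounded `no …` without the word "negative" | negative, `Negated=TRUE` |
| contains "negative" | negative |
| contains "positive" | positive |
| otherwise | unknown |

The negation rule exists because phrases like "No endolymphatic tumor
emboli" are classically misread as positive by rules keyed only on the
word "negative"; `replicate_legacy_negation=True` restores that legacy
error mode so the failure can be demonstrated in tests.  Intermediate
categories (equivocal, graded HER2-style scores) are not modelled and
fall to *unknown*; that is a deliberate scope limit, not an oversight.

Molecular values: the negative lexicon ("negative", "not detected",
"none identified" — extensible via the dictionary) wins first; then
"positive" or a mutation narrative (the word "mutation", or an HGVS-like
bracketed change such as `[c.38G>A, p.Gly14Asp]`) maps to positive with
the narrative preserved verbatim.  Unknown categories are kept and
emitted with value concept 0 — no entity is silently lost.

Aggregation to test level: NRAS/KRAS/BRAF are positive iff ≥ 1 attribute
(codon) is positive; MSI counts positive markers over
{BAT26, BAT25, D5S346, D17S250, D2S123}: ≥ 2 → MSI-H, 1 → MSI-L, 0 → MSS.
Missing attributes count as non-positive.  A stricter BRAF variant that
requires ≥ 2 positive attributes circulates in some rule sheets; it is
inconsistent with the sibling tests and with clinical usage, so the
default is ≥ 1 with `braf_more_than_one=True` available to restore the
strict variant.  Only
the aggregate reaches MEASUREMENT; per-codon detail stays in NOTE_NLP.

## The concept dictionary

Mapping is a versioned YAML file (`src/pathcdm/data/dictionary.yaml`), not
a live vocabulary service: determinism and auditability over recall.
Diagnosis keys match after lowercasing and whitespace collapsing; there is
no fuzzy matching.  Identifiers the standard vocabularies do not provide
here are locally minted (`2000000xxx`, or the SNOMED source code for the
two relationship concepts) and flagged `custom: true`; `audit-dict`
reports how many entries are custom.  Rows with an empty LOINC `code` are
mapped concepts whose code is simply not recorded yet (documented TODO
rows).  The bundled file carries 20 IHC biomarkers, the 4 molecular
tests, 6 condition entries, section/value/relationship/domain concepts and
the normalization lexicons; a production deployment would extend it, not
edit code.

TERM_MODIFIERS serialization is schema-guarded: only
`Negated, value_as_concept_id, value_as_narrative, sub_id,
section_source_value`, always in that order, `key=value` joined by `"; "`.

## Synthetic corpora

The generator emits the three dialects from the same literal fragments the
parser targets, with gold annotations built jointly with the text (never
re-derived from it): entity offsets, normalized categories, test
summaries, linkage ids.  Defaults: 10 patients × (1 surgical + 1 IHC +
1 molecular) report; a 6-marker IHC panel with per-marker positivity
probabilities (0.25–0.9, mismatch-repair and proliferation stains mostly
positive, p53/C-erbB2 mostly negative); mutation attribute positivity
0.2; MSI marker positivity 0.15; negation-phrase probability 0.1.  One
`random.Random(seed)` stream per corpus; a seed fully determines the
bytes.

What the generator does **not** emulate: realistic report-length and
narrative variation, typos beyond the configured corruption modes,
multi-organ surgical reports, non-English text, and institution-specific
template drift.  Passing the end-to-end identity test (precision =
recall = 100 on generated corpora) therefore shows the pipeline is exact
on its own dialect grammar — it does not certify performance on any real
hospital's reports.

The corruption harness perturbs generated corpora in ways that preserve a
computable gold: dropped `DIAGNOSIS:` markers (expected parse failure,
counted in the run report), bar removal by in-place character replacement
(expected row skip; molecular summaries recomputed over surviving
attributes), "No …" phrase injection (gold flips to negative+negated;
offsets of later entities shifted by the edit delta) and trailing-space
noise (offsets shifted, expectations unchanged).

## Evaluation

Precision and recall use different numerators, matching how a manual
audit scores separately whether an entity was *found* and whether its
transformed value is *correct*: recall counts gold entities matched on
the span key `(note_id, offset_start, offset_end, lexical_variant)`;
precision counts predictions that also match the normalized category.
Matching is exact-key; partial-overlap credit is out of scope.  Metrics
are kept at full float precision and rounded half-up only for display
(one decimal for P/R, two for F, with F computed from the unrounded
percentages).

## Numerical and degenerate-input choices

* Empty corpus → five header-only CSVs and a zero-count run report.
* Empty summary between adjacent delimiters → empty string with a
  zero-length span; a missing end delimiter extends the summary to the
  end of text with a warning.
* Rows without a bar, rows with an empty name, reports missing required
  markers, and facts without a matching specimen are skipped *and
  counted*; duplicate FACT_RELATIONSHIP rows and duplicate specimens are
  deduplicated with warnings.
* Surrogate keys are dense from 1 per run; `key_offset` shifts them for
  merge scenarios.  Reports without dates get the configured `run_date`.
* Output CSVs are sorted by surrogate key (FACT_RELATIONSHIP by full row)
  so reruns are byte-identical.

## Problem sizes used in the test suite

Unit tests run on single reports and 15-report corpora; the corpus-level
property tests use a 201-report corpus (67 patients × 3 dialects,
≈ 1,700 entities) for offset fidelity, extraction identity, relationship
symmetry and rerun determinism, and 60-report corpora for the corruption
properties.  The whole suite completes in a few seconds on one CPU.

## Known limitations

* Binary result semantics: graded/equivocal IHC readings collapse to
  positive/negative/unknown.
* Dictionary coverage is the bundled starter set; real deployments need
  the full institutional biomarker and diagnosis panels.
* No sentence-level NLP: free-narrative diagnosis text is carried
  verbatim, not decomposed.
* The two relationship concepts and several condition/value concepts are
  locally minted pending standard-vocabulary curation (flagged `custom`).
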