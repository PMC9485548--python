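# Methods

## The extraction model

A body-function (BF) mention is assembled, not recognized in one shot: the
page is decomposed into scopes, independent annotators deposit evidence
spans, and a mention is emitted for every scope that holds both a BF
*type* (strength / range of motion / reflex) and at least one *qualifier*,
with any *body locations* in the scope attached. The schema requires a
qualifier; a type term alone ("no clonus noted") is never a mention, and
a location alone never is either.

**Scopes.** The default scope is the sentence. Slot-value lines
(`label: value` on one line, value non-empty and not ending in a period)
use label and value *jointly* as the scope, because the label routinely
supplies the type ("Muscle strength: 4/5") or the location ("Cervical:
flexion 45 degrees"). When a sentence holds qualifiers but no type, the
scope expands leftward to the governing section header; if the header
names a BF type, one discontiguous mention per qualifier is created with
the header as type evidence (`from_context=True`), taking locations from
the qualifier's comma-delimited phrase. Phrases are approximated by
comma/semicolon-delimited sub-sentences throughout; no phrase chunker is
used.

**Section rigidity.** A section opens only at column 0, where a known
section name (or an ALL-CAPS run of ≤4 tokens) is followed by a colon or
ends the line. Indented and mid-line headings are deliberately missed:
that rigidity is characteristic of fielded systems on this material and
is a documented error source, so it is the default behavior, with
`sections.midline: true` relaxing it to indented headers. Requiring the
colon (or a name-only line) is this package's own reading — without it,
every narrative sentence beginning with a section word ("Strength 5/5 in
the arm.") would be swallowed as a heading.

**Confounder masking.** Evidence that overlaps a confounder hit *or
shares a comma-delimited phrase with one* is removed before assembly.
Character overlap alone is too narrow: a pain score "7/10" sits next to
the word "pain" without touching it. Phrase-scope masking is monotone —
removing confounder entries can only add mentions, never remove them.

**Assertion filtering.** Trigger phrases in the sentence before the
mention's first local fragment mark it historical ("history of", "h/o"),
hypothetical ("if", "should", "instructed to"), or conditional ("when",
"as needed", "with activity"); mentions in filtered sections (History,
Plan of Care, ...) are removed outright; only asserted mentions are
emitted. Bare calendar dates do **not** trigger the historical status by
default — date-triggered filtering is an over-zealous behavior that
discards valid exam findings, and is available behind
`history.dates_trigger: true` for comparison runs.

**Attachment choices.** One mention is emitted per type span, and all
in-scope qualifiers attach to it (multiple type spans share qualifiers
rather than partitioning them — flagged as a reviewable choice). A
location hit nested inside the type term itself ("biceps" within "biceps
reflex") is not attached as a standalone location. Adjacent location
hits separated only by whitespace merge, so laterality fuses with its
anatomy ("right" + "arm" → "right arm").

## Qualifier polarity

Per qualifier, rules apply in order; the first that fires wins:

1. dictionary polarity attribute (curated per term: "decreased" −1,
   "full" +1, ...);
2. strength mention + fraction: +1 iff numerator = denominator (5/5 and
   10/10 are equivalent, as are 4/5 and 9/10);
3. ROM mention + degrees: +1 iff the reading is 45 or 50 degrees. This
   is an empirical shortcut kept on purpose: building per-joint norm
   tables was judged not worth the return, and in the motivating data
   essentially every at-level degree reading was 45 or 50;
4. reflex mention + score on the 0–4+ scale: +1 only for exactly "2+"
   (brisk, normal);
5. reflex mention whose scope mentions clonus: any numeric qualifier
   scores −1;
6. dictionary qualifier without an attribute: 0.

Dictionary-before-numeric precedence is this package's choice (the
attributes were manually curated, so they outrank heuristics). A numeric
qualifier under a mismatched type (a degrees reading on a strength
mention) has no rule and scores 0, logged at debug level. The
mention-level polarity is the first non-zero per-qualifier value in
reading order (else 0); per-qualifier values are also emitted, since the
mention-level reduction is a convenience, not part of the rule set.

## Evaluation conventions

Entity matching is one-to-one greedy in span order; `overlap` (same
label, ≥1 shared character) is the default and `exact` (identical
fragments) is also exposed, because span-matching criteria are rarely
comparable across systems otherwise. Precision, recall, and F1 use the
zero-denominator → 0 convention and 4-decimal round-half-even reporting.
Token-based accuracy is the Jaccard ratio TP/(TP+FP+FN) over token-label
pairs; this is a documented convention of this package, not an attempt
to match any particular legacy "accuracy" column. Polarity accuracy is
scored only over entity-matched pairs as 100·TP/(TP+FN) per class — the
mention is already found, so false positives do not exist by
construction; a class absent from gold is reported as undefined rather
than 0. Inter-annotator agreement is entity F1 with one annotator as
gold; macro F1 averages labels unweighted.

## The synthetic generator

`synthgen` emulates the surface phenomena of OCR'd physical-exam pages:
repeated clinic headers and `Page n of m` footers; exam sections; three
mention realizations (narrative sentence, slot-value line, bare type
header over qualifier-only body lines); distractors with gold absence
(pain and vision scores, straight-leg-raise, historical sentences,
filtered History/Plan sections); and OCR corruption. Defaults encode the
study conditions: every page carries at least 2 mentions, a truncated
geometric count with mean ≈ 4.5 and maximum 23, ~35% slot-value and ~30%
context-section realizations, and an 80/20 train/test split in the
manifest. Generation uses one seeded `random.Random` stream and is
byte-identical per (seed, config).

Corruption is an explicit edit map, never a re-search: space deletion
removes single spaces between word characters with probability
`p_space_deletion` per boundary; column munging interleaves and fuses
the lines of a mid-page block (probability `p_column_munge` per page)
and re-tags gold mentions inside the block as `PossibleBF`, the label
used for unreadable regions. `PossibleBF` is generated for realism but
deliberately **excluded** from scoring on both sides — masking known-bad
regions at evaluation time would inflate the results.

The generator's vocabulary is a strict subset of the packaged lexicons
(a unit test enforces this), which makes the end-to-end recovery
property exact: on a zero-noise corpus, entity F1 is 1.0, so any
regression indicates a pipeline bug rather than a vocabulary gap. What
passing that property does *not* show: coverage of real clinical
vocabulary (the packaged lexicons are a few dozen entries per category,
not the tens of thousands a production dictionary holds), free-text
paraphrase, misspellings beyond deleted spaces, or cross-page section
continuation. Measured numbers on synthetic pages are upper bounds, not
forecasts for real corpora.

## Triage

Per-line structural features (case of the first token, leading
whitespace, indentation vs the previous line, punctuation and digit
counts, length, token count, and a text-tiling-style cohesion shift — 1
minus the shared-token Jaccard with the previous line) are aggregated
per page as means and standard deviations plus page-level counts
(~21 dimensions). The canonical feature list for this kind of
OCR-quality clustering is much longer and unpublished; this set is an
honest, extensible approximation. PCA standardizes columns (zero-variance
columns dropped), uses SVD, and fixes signs so the largest-magnitude
loading of each component is positive. Term ranking counts longest-match
lexicon hits per page; stratified sampling cuts the ranked list into
equal-count bins and draws uniformly per bin, remainder to the densest
bins, seeded.

## Numerical and degenerate-input choices

- Offsets are 0-based half-open everywhere (brat-compatible).
- Matching normalization: lowercase, hyphen→space, token-edge punctuation
  stripped, whitespace collapsed; variant expansion is a fixed 3-rule
  approximation (case, regular plural of the final token, hyphen/space
  alternation) of full lexical-variant generation.
- Numeric patterns reject date-like contexts (`03/14/2017` is not a
  fraction) and require the `+` suffix for reflex scores during page
  annotation (a bare digit 0–4 is too ambiguous on a page); the parser
  still classifies a bare "0"–"4" as a reflex score when a qualifier
  surface is examined directly.
- Header/footer masking: lines repeated (after digit normalization) on
  ≥60% of pages, restricted to the first/last 3 lines; both thresholds
  are configurable; a single-page batch falls back to date/page-number
  patterns.
- Empty inputs return empty structures, never errors; a mention without
  qualifiers is a schema violation and raises.

## Problem sizes

The recovery property is checked on 120 generated pages and the noise
monotonicity on 40 pages per corruption level (0, 0.05, 0.2 deleted-space
probability, tolerance 0.02 for sampling noise); both finish in seconds
on one CPU. Larger corpora change none of the checked properties, only
the tightness of the sampling tolerance.

## Known limitations

- Negation of the BF concept itself (beyond qualifier polarity) is out of
  scope, as are coreference and cross-page assembly.
- The ROM 45/50-degree rule is location-blind by design and wrong for
  joints whose normal range is elsewhere.
- Context expansion only recovers a missing *type* from headers; a
  missing location is not recovered.
- Section headers that begin mid-line are missed unless
  `sections.midline` is set, and slot values never span lines — both
  reproduce documented failure modes of this system family.
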