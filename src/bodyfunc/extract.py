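"""Assemble body-function mentions from evidence spans.

A body-function (BF) mention requires a BF *type* (strength, range of
motion, reflex) and at least one *qualifier*, optionally with one or more
body *locations*, all within the scope of a phrase or sentence.  Slot-value
lines use label and value jointly as the scope (the label often supplies
the type or the location).  When a qualifier has no type evidence in its
sentence, the scope expands leftward to the governing section header: a
header like "Strength:" supplies the missing type and yields a
discontiguous, from-context mention.

Confounder hits (pain scores, vision fractions, straight-leg-raise...)
mask co-located evidence before assembly.  After assembly, mentions in
historical / hypothetical / conditional scopes or inside filtered sections
are suppressed; only asserted mentions are emitted by default.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

from .config import RunConfig
from .decompose import PageDoc, Sentence, tokenize
from .lexicon import (
    Category,
    EvidenceSpan,
    Lexicon,
    QUALIFIER_CATEGORIES,
    TYPE_CATEGORIES,
    lookup,
)

log = logging.getLogger(__name__)


class Assertion(str, Enum):
    ASSERTED = "ASSERTED"
    HISTORICAL = "HISTORICAL"
    HYPOTHETICAL = "HYPOTHETICAL"
    CONDITIONAL = "CONDITIONAL"
    NEGATED_SCOPE = "NEGATED_SCOPE"


@dataclass
class BFMention:
    bf_type: Category
    type_evidence: EvidenceSpan
    qualifiers: list[EvidenceSpan]
    locations: list[EvidenceSpan] = field(default_factory=list)
    polarity: int = 0
    qualifier_polarities: list[int] = field(default_factory=list)
    assertion: Assertion = Assertion.ASSERTED
    from_context: bool = False
    scope_text: str = ""
    page_id: str = ""

    @property
    def fragments(self) -> list[tuple[int, int]]:
        """Union of member fragments; fragments separated only by
        whitespace are merged, others stay discontiguous."""
        frags = sorted(
            f
            for span in [self.type_evidence, *self.qualifiers, *self.locations]
            for f in span.fragments
        )
        return _merge_ws(frags, self._page_text)

    # page text is attached at assembly so fragment merging can inspect gaps
    _page_text: str = ""


def _merge_ws(frags: list[tuple[int, int]], text: str) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in frags:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(end, merged[-1][1]))
        elif merged and not text[merged[-1][1] : start].strip():
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


# ---------------------------------------------------------------------------
# evidence annotation

_FRACTION_RE = re.compile(r"(?<![\d/.])(\d+)\s*/\s*(\d+)(?![\d/])")
_DEGREES_RE = re.compile(r"\b(\d+)\s*(degrees?)\b", re.IGNORECASE)
_REFLEX_SCORE_RE = re.compile(r"(?<![\d/+.])([0-4])\+(?!\d)")


def annotate_evidence(page: PageDoc, lexicons: dict[Category, Lexicon]) -> list[EvidenceSpan]:
    """Dictionary hits across all category lexicons plus numeric-qualifier
    regex hits (fractions "5/5", degrees "45 degrees", reflex scores "2+")."""
    spans: list[EvidenceSpan] = []
    for lexicon in lexicons.values():
        for span in lookup(page.tokens, lexicon):
            span.text = page.text[span.start : span.end]
            spans.append(span)
    taken: list[tuple[int, int]] = []
    for pattern in (_DEGREES_RE, _FRACTION_RE, _REFLEX_SCORE_RE):
        for m in pattern.finditer(page.text):
            if any(m.start() < e and s < m.end() for s, e in taken):
                continue
            taken.append((m.start(), m.end()))
            spans.append(
                EvidenceSpan(
                    category=Category.NUMERIC_QUALIFIER,
                    fragments=[(m.start(), m.end())],
                    text=m.group(),
                )
            )
    spans.sort(key=lambda s: (s.start, s.category.value))
    return spans


# ---------------------------------------------------------------------------
# confounder masking

_PHRASE_SPLIT_RE = re.compile(r"[,;]")


def _phrase_ranges(sentence: Sentence) -> list[tuple[int, int]]:
    """Comma/semicolon-delimited sub-sentence ranges (phrase approximation)."""
    ranges = []
    cursor = 0
    for m in _PHRASE_SPLIT_RE.finditer(sentence.text):
        ranges.append((sentence.start + cursor, sentence.start + m.start()))
        cursor = m.end()
    ranges.append((sentence.start + cursor, sentence.end))
    return ranges


def mask_confounders(
    evidence: list[EvidenceSpan], page: PageDoc | None = None
) -> list[EvidenceSpan]:
    """Remove evidence co-located with a confounder hit.

    A non-confounder span is masked when it overlaps a confounder span or
    shares a comma-delimited phrase with one (a pain confounder masks the
    "7/10" score next to it even without character overlap).  Confounder
    spans themselves are then dropped.
    """
    confounders = [s for s in evidence if s.category is Category.CONFOUNDER]
    if not confounders:
        return [s for s in evidence if s.category is not Category.CONFOUNDER]
    blocked: list[tuple[int, int]] = [(c.start, c.end) for c in confounders]
    if page is not None:
        for sentence in page.sentences:
            for ps, pe in _phrase_ranges(sentence):
                if any(c.start < pe and ps < c.end for c in confounders):
                    blocked.append((ps, pe))
    kept = []
    for span in evidence:
        if span.category is Category.CONFOUNDER:
            continue
        if any(span.start < e and s < span.end for s, e in blocked):
            continue
        kept.append(span)
    return kept


# ---------------------------------------------------------------------------
# assembly

_LATERALITY = {
    "left", "right", "bilateral", "bilaterally", "both", "proximal", "distal",
}


def _scope_ranges(page: PageDoc, sentence: Sentence) -> list[tuple[int, int]]:
    if sentence.slot_index is not None:
        sv = page.slot_values[sentence.slot_index]
        return [sv.label_span, sv.value_span]
    return [(sentence.start, sentence.end)]


def _in_ranges(span: EvidenceSpan, ranges: list[tuple[int, int]]) -> bool:
    return any(s <= span.start < e for s, e in ranges)


def _merge_locations(locations: list[EvidenceSpan], text: str) -> list[EvidenceSpan]:
    """Merge adjacent location spans separated only by whitespace, so
    laterality modifiers fuse with their anatomy ("right" + "arm")."""
    locations = sorted(locations, key=lambda s: s.start)
    merged: list[EvidenceSpan] = []
    for span in locations:
        if merged and not text[merged[-1].end : span.start].strip() and span.start >= merged[-1].end:
            prev = merged[-1]
            frag = (prev.start, span.end)
            merged[-1] = EvidenceSpan(
                category=Category.LOCATION,
                fragments=[frag],
                text=text[frag[0] : frag[1]],
                concept_id=prev.concept_id or span.concept_id,
            )
        else:
            merged.append(span)
    return merged


def assemble_mentions(
    page: PageDoc, evidence: list[EvidenceSpan]
) -> tuple[list[BFMention], list[Sentence]]:
    """Per-scope assembly.

    Returns the contiguous mentions plus the sentences that held a
    qualifier without type evidence (candidates for context expansion).
    One mention is emitted per type span; all qualifiers and locations in
    the scope attach to it.
    """
    mentions: list[BFMention] = []
    unbound: list[Sentence] = []
    for sentence in page.sentences:
        ranges = _scope_ranges(page, sentence)
        in_scope = [s for s in evidence if _in_ranges(s, ranges)]
        types = [s for s in in_scope if s.category in TYPE_CATEGORIES]
        quals = [s for s in in_scope if s.category in QUALIFIER_CATEGORIES]
        locs = _merge_locations(
            [s for s in in_scope if s.category is Category.LOCATION], page.text
        )
        if types and quals:
            scope_text = " ".join(page.text[s:e] for s, e in ranges)
            for t in types:
                # a location hit nested inside the type term ("biceps"
                # within "biceps reflex") is not a standalone location
                mention = BFMention(
                    bf_type=t.category,
                    type_evidence=t,
                    qualifiers=sorted(quals, key=lambda s: s.start),
                    locations=[l for l in locs if not l.overlaps(t)],
                    scope_text=scope_text,
                    page_id=page.page_id,
                )
                mention._page_text = page.text
                mentions.append(mention)
        elif quals and not types:
            unbound.append(sentence)
    return mentions, unbound


def expand_context(
    page: PageDoc,
    unbound: list[Sentence],
    evidence: list[EvidenceSpan],
    lexicons: dict[Category, Lexicon],
) -> list[BFMention]:
    """Recover mentions whose type lives in the governing section header.

    For a sentence holding qualifiers but no type evidence, the scope
    expands left/up to the section header; if the header names a BF type,
    one discontiguous mention is created per qualifier, taking the
    locations from the qualifier's comma-delimited phrase.
    """
    mentions: list[BFMention] = []
    for sentence in unbound:
        section = page.section_at(sentence.start)
        if section is None:
            continue
        header_tokens = tokenize(
            page.text[section.name_span[0] : section.name_span[1]],
            offset=section.name_span[0],
        )
        header_hit: EvidenceSpan | None = None
        for cat in TYPE_CATEGORIES:
            lexicon = lexicons.get(cat)
            if lexicon is None:
                continue
            hits = lookup(header_tokens, lexicon)
            hits = [h for h in hits if h.category is cat]
            if hits:
                header_hit = hits[0]
                header_hit.text = page.text[header_hit.start : header_hit.end]
                break
        if header_hit is None:
            continue
        quals = [
            s
            for s in evidence
            if s.category in QUALIFIER_CATEGORIES
            and sentence.start <= s.start < sentence.end
        ]
        locs = [
            s
            for s in evidence
            if s.category is Category.LOCATION
            and sentence.start <= s.start < sentence.end
        ]
        phrases = _phrase_ranges(sentence)
        for q in sorted(quals, key=lambda s: s.start):
            phrase = next((p for p in phrases if p[0] <= q.start < p[1]), None)
            local_locs = (
                _merge_locations(
                    [l for l in locs if phrase and phrase[0] <= l.start < phrase[1]],
                    page.text,
                )
                if phrase
                else []
            )
            mention = BFMention(
                bf_type=header_hit.category,
                type_evidence=header_hit,
                qualifiers=[q],
                locations=local_locs,
                from_context=True,
                scope_text=page.text[sentence.start : sentence.end],
                page_id=page.page_id,
            )
            mention._page_text = page.text
            mentions.append(mention)
    return mentions


# ---------------------------------------------------------------------------
# assertion filtering

_HISTORICAL_TRIGGERS = ("history of", "hx of", "h/o", "past history", "previously")
_HYPOTHETICAL_TRIGGERS = ("if ", "should ", "in case", "instructed to")
_CONDITIONAL_TRIGGERS = ("as needed", "prn", "with activity", "upon exertion", "when ")
_DATE_RE = re.compile(r"\b\d{1,2}/\d{1,2}/\d{2,4}\b")


def _local_start(mention: BFMention) -> int:
    """First character of the mention's contiguous (non-header) evidence."""
    spans = mention.qualifiers + mention.locations
    if not mention.from_context:
        spans = spans + [mention.type_evidence]
    return min(s.start for s in spans)


def filter_assertions(
    mentions: list[BFMention], page: PageDoc, config: RunConfig | None = None
) -> list[BFMention]:
    """Classify each mention's assertion status and keep asserted ones.

    Trigger phrases occurring in the mention's sentence before its first
    local fragment mark it historical / hypothetical / conditional.
    Mentions inside filtered sections are removed outright.  Bare dates
    only trigger HISTORICAL when ``history.dates_trigger`` is set (that
    over-zealous behavior is off by default).
    """
    config = config or RunConfig()
    kept: list[BFMention] = []
    for mention in mentions:
        start = _local_start(mention)
        section = page.section_at(start)
        if section is not None and section.filtered:
            continue
        sentence = next(
            (s for s in page.sentences if s.start <= start < s.end), None
        )
        status = Assertion.ASSERTED
        if sentence is not None:
            left = page.text[sentence.start : start].lower()
            if any(t in left for t in _HISTORICAL_TRIGGERS):
                status = Assertion.HISTORICAL
            elif config.history_dates_trigger and _DATE_RE.search(sentence.text):
                status = Assertion.HISTORICAL
            elif any(t in left for t in _HYPOTHETICAL_TRIGGERS):
                status = Assertion.HYPOTHETICAL
            elif any(t in left for t in _CONDITIONAL_TRIGGERS):
                status = Assertion.CONDITIONAL
        mention.assertion = status
        if status is Assertion.ASSERTED:
            kept.append(mention)
        elif status is Assertion.CONDITIONAL and not config.filters_conditional:
            mention.assertion = Assertion.ASSERTED
            kept.append(mention)
    return kept


# ---------------------------------------------------------------------------
# pipeline

def extract_page(
    page: PageDoc,
    lexicons: dict[Category, Lexicon],
    config: RunConfig | None = None,
    masked: list[tuple[int, int]] | None = None,
) -> list[BFMention]:
    """Full extraction for one decomposed page: annotate evidence, drop
    masked (header/footer) regions, mask confounders, assemble, expand
    context, filter assertions, and assign polarity."""
    from .polarity import assign_polarity, qualifier_polarities

    config = config or RunConfig()
    evidence = annotate_evidence(page, lexicons)
    if masked:
        evidence = [
            s for s in evidence if not any(s.start < e and m < s.end for m, e in masked)
        ]
    evidence = mask_confounders(evidence, page)
    mentions, unbound = assemble_mentions(page, evidence)
    mentions.extend(expand_context(page, unbound, evidence, lexicons))
    mentions = filter_assertions(mentions, page, config)
    for mention in mentions:
        mention.qualifier_polarities = qualifier_polarities(mention)
        mention.polarity = assign_polarity(mention)
    mentions.sort(key=lambda m: (m.fragments[0], m.bf_type.value))
    return mentions
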