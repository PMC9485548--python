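"""Qualifier polarity: -1 below-level, 0 ambiguous, +1 at-or-above-level.

Each qualifier of a mention is assigned a functioning polarity by rule:

1. a polarity attribute carried from the dictionary entry wins
   ("decreased", "impaired" carry -1; "full", "normal" carry +1);
2. a fraction qualifier on a Strength mention is +1 iff it equals one
   (5/5, 10/10), else -1;
3. a degree qualifier on a ROM mention is +1 iff it reads 45 or 50
   degrees, else -1 — an empirical shortcut kept deliberately: in the
   motivating data every at-level degree reading was 45 or 50;
4. a reflex-score qualifier on a Reflex mention is +1 only for exactly
   "2+" (brisk, normal), else -1;
5. any numeric qualifier on a Reflex mention whose scope mentions clonus
   is -1;
6. a dictionary qualifier without an attribute is 0 (no assignment).

The mention-level polarity is the first qualifier's non-zero result in
reading order, else 0.  Per-qualifier values are kept alongside.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

from .lexicon import Category

if TYPE_CHECKING:  # pragma: no cover
    from .extract import BFMention

log = logging.getLogger(__name__)


class NumericKind(str, Enum):
    FRACTION = "FRACTION"
    DEGREES = "DEGREES"
    REFLEX_SCORE = "REFLEX_SCORE"
    PLAIN = "PLAIN"


@dataclass(frozen=True)
class NumericQualifier:
    kind: NumericKind
    numerator: float | None = None
    denominator: float | None = None
    value: float | None = None
    plus: bool = False


_FRACTION_RE = re.compile(r"^(\d+)\s*/\s*(\d+)$")
_DEGREES_RE = re.compile(r"^(\d+)\s*degrees?$", re.IGNORECASE)
_REFLEX_RE = re.compile(r"^([0-4])(\+?)$")


def parse_numeric_qualifier(text: str) -> NumericQualifier:
    """Classify a qualifier surface as fraction, degrees, reflex score, or
    plain text.  Unparseable input is PLAIN, never an error."""
    text = text.strip()
    m = _FRACTION_RE.match(text)
    if m and int(m.group(2)) > 0:
        return NumericQualifier(
            NumericKind.FRACTION, numerator=int(m.group(1)), denominator=int(m.group(2))
        )
    m = _DEGREES_RE.match(text)
    if m:
        return NumericQualifier(NumericKind.DEGREES, value=int(m.group(1)))
    m = _REFLEX_RE.match(text)
    if m:
        return NumericQualifier(
            NumericKind.REFLEX_SCORE, value=int(m.group(1)), plus=m.group(2) == "+"
        )
    return NumericQualifier(NumericKind.PLAIN)


def qualifier_polarity(qualifier, bf_type: Category, scope_text: str = "") -> int:
    """Polarity of a single qualifier evidence span within a mention of
    *bf_type*; *scope_text* is the mention's sentence (for clonus)."""
    if qualifier.polarity_attr is not None:
        return qualifier.polarity_attr
    nq = parse_numeric_qualifier(qualifier.text)
    if nq.kind is NumericKind.FRACTION and bf_type is Category.STRENGTH:
        return 1 if nq.numerator == nq.denominator else -1
    if nq.kind is NumericKind.DEGREES and bf_type is Category.ROM:
        return 1 if nq.value in (45, 50) else -1
    if nq.kind is NumericKind.REFLEX_SCORE and bf_type is Category.REFLEX:
        return 1 if (nq.value == 2 and nq.plus) else -1
    if (
        bf_type is Category.REFLEX
        and nq.kind is not NumericKind.PLAIN
        and "clonus" in scope_text.lower()
    ):
        return -1
    if qualifier.category is Category.QUALIFIER:
        return 0
    if nq.kind is not NumericKind.PLAIN:
        # numeric qualifier under a mismatched BF type: no rule applies
        log.debug("cross-type numeric qualifier %r under %s -> 0", qualifier.text, bf_type)
    return 0


def qualifier_polarities(mention: "BFMention") -> list[int]:
    if not mention.qualifiers:
        raise ValueError("mention has no qualifiers (schema requires at least one)")
    return [
        qualifier_polarity(q, mention.bf_type, mention.scope_text)
        for q in mention.qualifiers
    ]


def assign_polarity(mention: "BFMention") -> int:
    """Mention-level polarity: first non-zero per-qualifier value in
    reading order, else 0."""
    for value in qualifier_polarities(mention):
        if value != 0:
            return value
    return 0
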