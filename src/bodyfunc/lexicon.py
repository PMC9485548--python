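"""Category-tagged lexicons with variant expansion and longest-match lookup.

The extraction pipeline is dictionary-driven: every body-function type
(strength, range of motion, reflex), body location, textual qualifier,
confounder, and section name is recognized by looking tokens up in a
category-tagged lexicon.  Entries may carry a concept identifier (SNOMED /
UMLS), semantic types, and an optional polarity attribute in {-1, 0, +1}
used later by the qualifier-polarity annotator.

Lookup is case-insensitive, greedy longest-match per start position, and
runs independently per category: hits from *different* categories may
overlap (e.g. "plantar flexion" as ROM and "plantar" as reflex), hits
within one category never do.
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class Category(str, Enum):
    """Lexicon / evidence categories."""

    STRENGTH = "STRENGTH"
    ROM = "ROM"
    REFLEX = "REFLEX"
    LOCATION = "LOCATION"
    QUALIFIER = "QUALIFIER"
    CONFOUNDER = "CONFOUNDER"
    SECTION_ALLOW = "SECTION_ALLOW"
    SECTION_FILTER = "SECTION_FILTER"
    # assigned by regex annotators, never loaded from a TSV:
    NUMERIC_QUALIFIER = "NUMERIC_QUALIFIER"


#: categories that constitute body-function *type* evidence
TYPE_CATEGORIES = (Category.STRENGTH, Category.ROM, Category.REFLEX)
#: categories that constitute *qualifier* evidence
QUALIFIER_CATEGORIES = (Category.QUALIFIER, Category.NUMERIC_QUALIFIER)

LEXICON_HEADER = ["surface", "category", "concept_id", "semantic_types", "polarity"]

_VALID_POLARITY = {"": None, "-1": -1, "0": 0, "1": 1, "+1": 1}


class LexiconError(ValueError):
    """Malformed lexicon file or row."""


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    category: Category
    concept_id: str | None = None
    semantic_types: tuple[str, ...] = ()
    polarity_attr: int | None = None

    def __post_init__(self) -> None:
        if not self.surface.strip():
            raise LexiconError("lexicon entry surface is empty")
        if self.polarity_attr not in (None, -1, 0, 1):
            raise LexiconError(f"polarity attribute {self.polarity_attr!r} not in -1/0/1")


@dataclass
class EvidenceSpan:
    """A dictionary or numeric-pattern hit, with character-offset provenance.

    ``fragments`` is a sorted list of half-open ``(start, end)`` character
    ranges; almost always a single fragment, but discontiguous mentions
    (section-header context) produce multi-fragment spans downstream.
    """

    category: Category
    fragments: list[tuple[int, int]]
    text: str
    concept_id: str | None = None
    polarity_attr: int | None = None

    @property
    def start(self) -> int:
        return self.fragments[0][0]

    @property
    def end(self) -> int:
        return self.fragments[-1][1]

    def overlaps(self, other: "EvidenceSpan") -> bool:
        return any(
            a0 < b1 and b0 < a1
            for a0, a1 in self.fragments
            for b0, b1 in other.fragments
        )


def normalize(text: str) -> str:
    """Canonical matching form: lowercase, hyphens to spaces, token-edge
    punctuation stripped, whitespace collapsed.

    OCR output is erratic in case and hyphenation, so matching happens in
    this canonical space rather than on raw surfaces.
    """
    words = []
    for raw in text.lower().replace("-", " ").split():
        stripped = raw.strip(string.punctuation)
        words.append(stripped if stripped else raw)
    return " ".join(words)


def expand_variants(entry: LexiconEntry) -> list[str]:
    """Deterministic lexical-variant expansion: case folding, regular plural
    of the final token, and hyphen/space alternation.

    A small fixed approximation of full lexical-variant generation; the
    original surface always comes first and duplicates are removed.
    """
    base = " ".join(entry.surface.split())
    forms = [base, base.lower()]
    for form in list(forms):
        last = form.split()[-1].split("-")[-1]
        if last.isalpha() and len(last) > 1:
            if last.lower().endswith(("s", "x", "z", "ch", "sh")):
                forms.append(form + "es")
            else:
                forms.append(form + "s")
    for form in list(forms):
        if "-" in form:
            forms.append(form.replace("-", " "))
        if " " in form:
            forms.append(form.replace(" ", "-"))
    seen: dict[str, None] = {}
    for form in forms:
        seen.setdefault(form, None)
    return list(seen)


class Lexicon:
    """An indexed set of :class:`LexiconEntry`.

    The index maps the canonical form of every generated variant to its
    entry (first entry wins on collision), per category.
    """

    def __init__(self, entries: Iterable[LexiconEntry] = ()) -> None:
        self.entries: list[LexiconEntry] = []
        self._index: dict[Category, dict[str, LexiconEntry]] = {}
        self._max_tokens: dict[Category, int] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: LexiconEntry) -> None:
        self.entries.append(entry)
        cat_index = self._index.setdefault(entry.category, {})
        for variant in expand_variants(entry):
            key = normalize(variant)
            if key and key not in cat_index:
                cat_index[key] = entry
                n_words = len(key.split())
                if n_words > self._max_tokens.get(entry.category, 0):
                    self._max_tokens[entry.category] = n_words

    def categories(self) -> list[Category]:
        return list(self._index)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: str) -> bool:
        key = normalize(surface)
        return any(key in idx for idx in self._index.values())

    def get(self, surface: str, category: Category) -> LexiconEntry | None:
        return self._index.get(category, {}).get(normalize(surface))

    def merge(self, other: "Lexicon") -> "Lexicon":
        return Lexicon([*self.entries, *other.entries])


def load_lexicon(path: str | Path, default_category: Category | None = None) -> Lexicon:
    """Load a TSV lexicon (columns: surface, category, concept_id,
    semantic_types, polarity).

    An empty ``category`` cell falls back to *default_category*; unknown
    category labels and polarity values outside {-1, 0, 1} raise
    :class:`LexiconError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise LexiconError(f"{path}: empty file, expected header row") from None
        if [h.strip() for h in header] != LEXICON_HEADER:
            raise LexiconError(f"{path}: bad header {header!r}, expected {LEXICON_HEADER}")
        entries = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            # allow trailing columns to be omitted by editors
            row = list(row) + [""] * (len(LEXICON_HEADER) - len(row))
            if len(row) != len(LEXICON_HEADER):
                raise LexiconError(f"{path}:{lineno}: expected {len(LEXICON_HEADER)} columns, got {len(row)}")
            surface, cat_label, concept_id, sem_types, polarity = (c.strip() for c in row)
            if cat_label:
                try:
                    category = Category(cat_label)
                except ValueError:
                    raise LexiconError(f"{path}:{lineno}: unknown category {cat_label!r}") from None
            elif default_category is not None:
                category = default_category
            else:
                raise LexiconError(f"{path}:{lineno}: missing category and no default given")
            if category is Category.NUMERIC_QUALIFIER:
                raise LexiconError(f"{path}:{lineno}: {cat_label!r} is regex-assigned, not loadable")
            if polarity not in _VALID_POLARITY:
                raise LexiconError(f"{path}:{lineno}: polarity {polarity!r} not in {{-1,0,1}}")
            entries.append(
                LexiconEntry(
                    surface=surface,
                    category=category,
                    concept_id=concept_id or None,
                    semantic_types=tuple(t.strip() for t in sem_types.split(",") if t.strip()),
                    polarity_attr=_VALID_POLARITY[polarity],
                )
            )
    return Lexicon(entries)


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write entries back out as TSV (inverse of :func:`load_lexicon`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(LEXICON_HEADER)
        for e in lexicon.entries:
            writer.writerow(
                [
                    e.surface,
                    e.category.value,
                    e.concept_id or "",
                    ",".join(e.semantic_types),
                    "" if e.polarity_attr is None else str(e.polarity_attr),
                ]
            )


_DEFAULT_FILES = {
    Category.STRENGTH: "strength.tsv",
    Category.ROM: "rom.tsv",
    Category.REFLEX: "reflex.tsv",
    Category.LOCATION: "location.tsv",
    Category.QUALIFIER: "qualifier.tsv",
    Category.CONFOUNDER: "confounder.tsv",
    Category.SECTION_ALLOW: "sections_allow.tsv",
    Category.SECTION_FILTER: "sections_filter.tsv",
}


def load_default_lexicons(
    overrides: dict[str, str] | None = None
) -> dict[Category, Lexicon]:
    """The packaged mini-lexicons (a few dozen entries per category),
    optionally overridden per category name with TSV paths."""
    from importlib.resources import files

    data_dir = files("bodyfunc") / "data"
    overrides = overrides or {}
    lexicons: dict[Category, Lexicon] = {}
    for category, filename in _DEFAULT_FILES.items():
        if category.value in overrides:
            lexicons[category] = load_lexicon(overrides[category.value], category)
        else:
            lexicons[category] = load_lexicon(str(data_dir / filename), category)
    return lexicons


def lookup(tokens: Sequence, lexicon: Lexicon) -> list[EvidenceSpan]:
    """Greedy left-to-right longest-match lookup over tokens with offsets.

    Each token must expose ``.start``, ``.end`` and ``.text``.  Matching is
    run independently per category present in the lexicon, so spans of
    different categories may overlap while spans within one category never
    do.  Returns spans sorted by (start, category).
    """
    spans: list[EvidenceSpan] = []
    n = len(tokens)
    for category in lexicon.categories():
        index = lexicon._index[category]
        max_len = lexicon._max_tokens.get(category, 1)
        i = 0
        while i < n:
            hit = None
            for width in range(min(max_len, n - i), 0, -1):
                window = " ".join(tokens[j].text for j in range(i, i + width))
                entry = index.get(normalize(window))
                if entry is not None:
                    hit = (width, entry)
                    break
            if hit is None:
                i += 1
                continue
            width, entry = hit
            start, end = tokens[i].start, tokens[i + width - 1].end
            spans.append(
                EvidenceSpan(
                    category=category,
                    fragments=[(start, end)],
                    text="",  # filled by caller when source text is at hand
                    concept_id=entry.concept_id,
                    polarity_attr=entry.polarity_attr,
                )
            )
            i += width
    spans.sort(key=lambda s: (s.start, s.category.value))
    return spans
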