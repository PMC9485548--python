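"""Page decomposition: lines, sections, slot values, sentences, tokens.

Clinical pages that went through OCR are highly formatted: section headers
("MOTOR:", "REFLEXES:") scope the lines beneath them, and many lines are
slot-value constructs ("Muscle strength: 5/5") where the label poses the
question and the value answers it.  Everything downstream (mention
assembly, context expansion, assertion filtering) works on the structures
produced here, and every structure carries 0-based half-open character
offsets into the original page text.

Section detection is deliberately rigid: a section opens only at column 0,
where a known section name (or a short ALL-CAPS run) is followed by a
colon or ends the line.  Indented or mid-line headings are not detected
unless ``sections.midline`` is enabled; this mirrors how such systems
behave on real pages and is a documented error source.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .lexicon import Category, Lexicon, lookup, normalize

#: token pattern: alphanumeric runs keeping internal "/", "+", "-" so that
#: "5/5", "2+", "45" and "range-of-motion" survive as single tokens;
#: any other non-space character is its own token.
_TOKEN_RE = re.compile(r"[0-9A-Za-z]+(?:[/+\-][0-9A-Za-z]+)*\+?|\S")

_SENT_SPLIT_RE = re.compile(r"[.!?]+\s+(?=[A-Z])")
_CAPS_HEADER_RE = re.compile(r"^([A-Z][A-Z0-9/ \t]*?):")
_DATEISH_RE = re.compile(
    r"^\s*(page\s+\d+(\s+of\s+\d+)?|\d{1,2}/\d{1,2}/\d{2,4})\s*$", re.IGNORECASE
)


@dataclass(frozen=True)
class Span:
    start: int
    end: int
    text: str


class Token(Span):
    pass


class Line(Span):
    pass


@dataclass(frozen=True)
class Sentence(Span):
    #: index into PageDoc.slot_values when this sentence is a slot value's value
    slot_index: int | None = None


@dataclass(frozen=True)
class Section:
    name_span: tuple[int, int]
    name: str
    body_span: tuple[int, int]
    filtered: bool


@dataclass(frozen=True)
class SlotValue:
    label_span: tuple[int, int]
    value_span: tuple[int, int]
    line_index: int


@dataclass
class PageDoc:
    page_id: str
    text: str
    lines: list[Line] = field(default_factory=list)
    sections: list[Section] = field(default_factory=list)
    slot_values: list[SlotValue] = field(default_factory=list)
    sentences: list[Sentence] = field(default_factory=list)
    tokens: list[Token] = field(default_factory=list)

    def section_at(self, pos: int) -> Section | None:
        """The section whose body contains character position *pos*."""
        for section in self.sections:
            if section.body_span[0] <= pos < section.body_span[1]:
                return section
        return None


def segment_lines(text: str) -> list[Line]:
    """Split on newline; the newline character belongs to its line, and the
    concatenation of line texts reproduces the input exactly."""
    lines: list[Line] = []
    start = 0
    while start < len(text):
        nl = text.find("\n", start)
        end = len(text) if nl == -1 else nl + 1
        lines.append(Line(start, end, text[start:end]))
        start = end
    return lines


def tokenize(text: str, offset: int = 0) -> list[Token]:
    """Offset-preserving tokenization; *offset* shifts spans so tokens of a
    slice still index into the full page."""
    return [
        Token(m.start() + offset, m.end() + offset, m.group())
        for m in _TOKEN_RE.finditer(text)
    ]


def _line_content(line: Line) -> str:
    return line.text.rstrip("\n")


def _match_section_name(
    content: str, allow: Lexicon, filter_lex: Lexicon, midline: bool
) -> tuple[int, int, str, bool] | None:
    """Return (name_start, name_end, name, filtered) relative to the line
    content if the line opens a section, else None."""
    lead = 0
    if midline:
        lead = len(content) - len(content.lstrip())
    elif content[:1].isspace():
        return None  # rigid: sections start at column 0 only
    body = content[lead:]
    if not body:
        return None
    tokens = tokenize(body)
    for lexicon, filtered in ((filter_lex, True), (allow, False)):
        best = None
        for width in range(min(6, len(tokens)), 0, -1):
            window = " ".join(t.text for t in tokens[:width])
            entry = lexicon.get(window, Category.SECTION_FILTER if filtered else Category.SECTION_ALLOW)
            if entry is None:
                continue
            name_end = tokens[width - 1].end
            tail = body[name_end:]
            # a section only opens when the name is followed by a colon or
            # is the entire line; otherwise it is narrative text
            if tail.lstrip().startswith(":") or not tail.strip():
                best = (lead + tokens[0].start, lead + name_end, body[tokens[0].start:name_end], filtered)
                break
        if best:
            return best
    # ALL-CAPS heuristic: <=4 all-caps tokens ending in a colon open an
    # unknown, non-filtered section (the published section lists are small
    # and incomplete, so unseen headers still need to scope their bodies)
    caps = _CAPS_HEADER_RE.match(body)
    if caps and len(caps.group(1).split()) <= 4:
        name = caps.group(1).strip()
        return (lead, lead + len(caps.group(1)), name, False)
    return None


def detect_sections(
    page: PageDoc, allow: Lexicon, filter_lex: Lexicon, midline: bool = False
) -> list[Section]:
    """Find section-opening lines and compute each section's body span
    (from after the name/colon to the next section start or page end)."""
    openings: list[tuple[int, int, int, str, bool]] = []  # line start, name span..., name, filtered
    for line in page.lines:
        content = _line_content(line)
        m = _match_section_name(content, allow, filter_lex, midline)
        if m is None:
            continue
        ns, ne, name, filtered = m
        openings.append((line.start, line.start + ns, line.start + ne, name, filtered))
    sections = []
    for i, (line_start, ns, ne, name, filtered) in enumerate(openings):
        after = page.text[ne:]
        skip = len(after) - len(after.lstrip(" \t"))
        body_start = ne + skip
        if page.text[body_start : body_start + 1] == ":":
            body_start += 1
        body_end = openings[i + 1][0] if i + 1 < len(openings) else len(page.text)
        sections.append(Section((ns, ne), name, (body_start, body_end), filtered))
    return sections


_SLOT_RE = re.compile(r"^(\s*)([^:\n]+?)\s*:\s*(\S.*?)\s*$")


def detect_slot_values(line: Line, line_index: int = 0) -> SlotValue | None:
    """Detect a ``label: value`` construct on one line.

    The label is 1-6 tokens; the value is non-empty and does not end in a
    period (slot values never cross line boundaries and never end in '.').
    Section-name-only lines must be excluded by the caller.
    """
    m = _SLOT_RE.match(_line_content(line))
    if m is None:
        return None
    label, value = m.group(2), m.group(3)
    if value.endswith("."):
        return None
    if not 1 <= len(tokenize(label)) <= 6:
        return None
    label_start = line.start + m.start(2)
    value_start = line.start + m.start(3)
    return SlotValue(
        label_span=(label_start, label_start + len(label)),
        value_span=(value_start, value_start + len(value)),
        line_index=line_index,
    )


def chunk_sentences(page: PageDoc) -> list[Sentence]:
    """Sentence segmentation aware of slot values and section boundaries.

    A slot value's value is exactly one sentence.  Other text is grouped
    into blocks of consecutive non-blank, non-header, non-slot lines that
    share a section scope, then split at sentence-final punctuation
    followed by whitespace and an uppercase letter.  Sentences never cross
    section boundaries.
    """
    header_lines = set()
    boundary_at = set()
    for section in page.sections:
        for idx, line in enumerate(page.lines):
            if line.start <= section.name_span[0] < line.end:
                boundary_at.add(idx)
                # name-only header line: nothing after the colon
                content = _line_content(line)
                tail = page.text[section.body_span[0] : line.start + len(content)]
                if not tail.strip():
                    header_lines.add(idx)
    slot_by_line = {sv.line_index: i for i, sv in enumerate(page.slot_values)}

    sentences: list[Sentence] = []
    block: list[Line] = []

    def flush() -> None:
        if not block:
            return
        start, end = block[0].start, block[-1].end
        chunk = page.text[start:end]
        cursor = 0
        pieces = []
        for m in _SENT_SPLIT_RE.finditer(chunk):
            pieces.append((cursor, m.end()))
            cursor = m.end()
        pieces.append((cursor, len(chunk)))
        for a, b in pieces:
            raw = chunk[a:b]
            lstrip = len(raw) - len(raw.lstrip())
            rstrip = len(raw) - len(raw.rstrip())
            if raw.strip():
                s, e = start + a + lstrip, start + b - rstrip
                sentences.append(Sentence(s, e, page.text[s:e]))
        block.clear()

    for idx, line in enumerate(page.lines):
        if idx in boundary_at:
            flush()
        if idx in header_lines or not _line_content(line).strip():
            flush()
            continue
        if idx in slot_by_line:
            flush()
            sv = page.slot_values[slot_by_line[idx]]
            s, e = sv.value_span
            sentences.append(Sentence(s, e, page.text[s:e], slot_index=slot_by_line[idx]))
            continue
        if idx in boundary_at:
            # section line with a same-line tail: the tail starts a block
            section = page.section_at(line.end - 1) or page.section_at(line.start)
            tail_start = None
            for sec in page.sections:
                if line.start <= sec.name_span[0] < line.end:
                    tail_start = sec.body_span[0]
            if tail_start is not None and page.text[tail_start : line.end].strip():
                block.append(Line(tail_start, line.end, page.text[tail_start : line.end]))
            continue
        block.append(line)
    flush()
    sentences.sort(key=lambda s: s.start)
    return sentences


def decompose(
    text: str,
    page_id: str = "",
    allow: Lexicon | None = None,
    filter_lex: Lexicon | None = None,
    midline: bool = False,
) -> PageDoc:
    """Full decomposition of one page; pure function of its inputs."""
    page = PageDoc(page_id=page_id, text=text)
    page.lines = segment_lines(text)
    page.tokens = tokenize(text)
    allow = allow or Lexicon()
    filter_lex = filter_lex or Lexicon()
    page.sections = detect_sections(page, allow, filter_lex, midline=midline)
    name_only = set()
    for section in page.sections:
        for idx, line in enumerate(page.lines):
            if line.start <= section.name_span[0] < line.end:
                content = _line_content(line)
                if not page.text[section.body_span[0] : line.start + len(content)].strip():
                    name_only.add(idx)
    slot_values = []
    for idx, line in enumerate(page.lines):
        if idx in name_only:
            continue
        sv = detect_slot_values(line, idx)
        if sv is not None:
            slot_values.append(sv)
    page.slot_values = slot_values
    page.sentences = chunk_sentences(page)
    return page


def strip_header_footer(
    pages: list[PageDoc], min_page_fraction: float = 0.6, edge_lines: int = 3
) -> dict[str, list[tuple[int, int]]]:
    """Mask repeated page headers/footers across a batch.

    A line (restricted to the first/last *edge_lines* lines of a page,
    digits normalized so "Page 1 of 9" and "Page 2 of 9" agree) that
    repeats on at least *min_page_fraction* of the pages is masked on
    every page where it occurs.  A single-page batch falls back to masking
    edge lines that look like dates or page numbers.
    """

    def norm_key(line: Line) -> str:
        return re.sub(r"\d+", "#", normalize(_line_content(line)))

    masked: dict[str, list[tuple[int, int]]] = {p.page_id: [] for p in pages}
    if len(pages) == 1:
        page = pages[0]
        for line in _edge(page, edge_lines):
            if _DATEISH_RE.match(_line_content(line)):
                masked[page.page_id].append((line.start, line.end))
        return masked

    counts: dict[str, int] = {}
    for page in pages:
        for key in {norm_key(ln) for ln in _edge(page, edge_lines) if _line_content(ln).strip()}:
            counts[key] = counts.get(key, 0) + 1
    threshold = min_page_fraction * len(pages)
    repeated = {k for k, c in counts.items() if c >= threshold}
    for page in pages:
        for line in _edge(page, edge_lines):
            if _line_content(line).strip() and norm_key(line) in repeated:
                masked[page.page_id].append((line.start, line.end))
    return masked


def _edge(page: PageDoc, edge_lines: int) -> list[Line]:
    if len(page.lines) <= 2 * edge_lines:
        return list(page.lines)
    return list(page.lines[:edge_lines]) + list(page.lines[-edge_lines:])
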