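"""Seeded generator of synthetic clinical exam pages with gold standoff
annotations and optional OCR-noise corruption.

The real corpus this package targets (OCR'd disability-claim pages) is
access-restricted, so this module fabricates pages with the same surface
phenomena: physical-exam sections (MOTOR, REFLEXES, ...), slot-value
lines ("Muscle strength: 5/5"), narrative sentences with body-function
mentions, bare section headers whose bodies carry only qualifiers
(context mentions), repeated page headers/footers, distractors (pain
scores, vision fractions, straight-leg-raise), and OCR corruption
(deleted spaces, munged two-column blocks).

Every generated mention's type / qualifier / location spans and polarity
are recorded as gold; the generator's vocabulary is a subset of the
packaged mini-lexicons, so on a zero-noise corpus a correct extraction
pipeline recovers the gold exactly.  Pages per seed are byte-identical
across runs.
"""

from __future__ import annotations

import json
import math
import random
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from types import SimpleNamespace

from .extract import Assertion, BFMention
from .lexicon import Category, EvidenceSpan
from .standoff import Annotation, mentions_to_annotations, write_ann

# ---------------------------------------------------------------------------
# vocabulary (kept a strict subset of the packaged lexicons; a unit test
# enforces the subset relation)

STRENGTH_TERMS = ["Strength", "Muscle strength", "Motor strength", "Grip strength"]
ROM_TERMS = ["Range of motion", "ROM", "Flexion", "Extension", "Abduction", "Dorsiflexion"]
REFLEX_TERMS = ["Reflexes", "Patellar reflex", "Biceps reflex", "Achilles reflex"]
#: word qualifiers with their dictionary polarity attribute (None = no attribute)
WORD_QUALIFIERS = {
    "decreased": -1,
    "impaired": -1,
    "limited": -1,
    "reduced": -1,
    "diminished": -1,
    "weak": -1,
    "full": 1,
    "normal": 1,
    "intact": 1,
    "brisk": 1,
    "preserved": 1,
    "trace": None,
    "fair": None,
    "symmetric": None,
    "equal": None,
}
ANATOMY = [
    "arm", "shoulder", "knee", "elbow", "wrist", "hip", "ankle", "hand",
    "leg", "upper extremity", "lower extremity", "cervical spine",
    "lumbar spine", "biceps", "quadriceps",
]
LATERALITY = ["left", "right", "both", "bilateral"]
#: section headers usable for context mentions: each is both an allowed
#: section name and a BF type term
CONTEXT_HEADERS = {
    "Strength": Category.STRENGTH,
    "Muscle strength": Category.STRENGTH,
    "REFLEXES": Category.REFLEX,
    "Range of motion": Category.ROM,
    "ROM": Category.ROM,
}
PLAIN_SECTIONS = ["PHYSICAL EXAM", "MOTOR", "NEURO", "MUSCULOSKELETAL", "EXTREMITIES", "OBJECTIVE"]
DISTRACTORS = [
    "Pain 7/10 today.",
    "Vision 20/20 bilaterally.",
    "SLR negative on the left.",
    "Blood pressure 120/80 this visit.",
    "No clonus noted.",
    "Gait steady without assistance.",
]
HEADER_LINE = "ACME REGIONAL MEDICAL CENTER 555-0100"

_TYPE_TERMS = {
    Category.STRENGTH: STRENGTH_TERMS,
    Category.ROM: ROM_TERMS,
    Category.REFLEX: REFLEX_TERMS,
}


@dataclass
class NoiseConfig:
    p_space_deletion: float = 0.0
    p_column_munge: float = 0.0
    header_footer: bool = True


@dataclass
class GenConfig:
    seed: int = 0
    n_pages: int = 10
    mentions_min: int = 2
    mentions_max: int = 23
    mentions_mean: float = 4.5
    p_slot_value: float = 0.35
    p_context_section: float = 0.30
    p_distractor: float = 0.5
    train_fraction: float = 0.8
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if isinstance(self.noise, dict):
            self.noise = NoiseConfig(**self.noise)
        if self.n_pages < 1:
            raise ValueError("n_pages must be >= 1")
        for p in (self.p_slot_value, self.p_context_section, self.p_distractor,
                  self.noise.p_space_deletion, self.noise.p_column_munge):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


# ---------------------------------------------------------------------------
# page building

class _PageBuilder:
    def __init__(self, page_id: str) -> None:
        self.page_id = page_id
        self.parts: list[str] = []
        self.offset = 0
        self.mentions: list[BFMention] = []

    def add_line(self, text: str = "") -> int:
        start = self.offset
        self.parts.append(text + "\n")
        self.offset += len(text) + 1
        return start

    @property
    def text(self) -> str:
        return "".join(self.parts)


def _spans_from_parts(parts: list[tuple[str, str | None]], start: int):
    """Assemble a string from (text, role) parts; return the string and the
    absolute span of each role-tagged part."""
    text = ""
    spans: list[tuple[str, int, int, str]] = []
    for piece, role in parts:
        if role is not None:
            spans.append((role, start + len(text), start + len(text) + len(piece), piece))
        text += piece
    return text, spans


def _mention_from_spans(
    builder: _PageBuilder,
    bf_type: Category,
    spans,
    qual_polarities: list[int],
    from_context: bool = False,
    type_span: tuple[int, int, str] | None = None,
) -> BFMention:
    type_ev = None
    quals: list[EvidenceSpan] = []
    locs: list[EvidenceSpan] = []
    for role, s, e, text in spans:
        ev = EvidenceSpan(category=bf_type if role == "type" else Category.QUALIFIER
                          if role == "qual" else Category.LOCATION,
                          fragments=[(s, e)], text=text)
        if role == "type":
            type_ev = ev
        elif role == "qual":
            quals.append(ev)
        elif role == "loc":
            locs.append(ev)
    if type_span is not None:
        s, e, text = type_span
        type_ev = EvidenceSpan(category=bf_type, fragments=[(s, e)], text=text)
    mention = BFMention(
        bf_type=bf_type,
        type_evidence=type_ev,
        qualifiers=quals,
        locations=locs,
        qualifier_polarities=qual_polarities,
        polarity=next((p for p in qual_polarities if p != 0), 0),
        assertion=Assertion.ASSERTED,
        from_context=from_context,
        page_id=builder.page_id,
    )
    builder.mentions.append(mention)
    return mention


def _numeric_qualifier(bf_type: Category, rng: random.Random) -> tuple[str, int]:
    """A numeric qualifier surface and its gold polarity under the rules."""
    if bf_type is Category.STRENGTH:
        n = rng.choice([2, 3, 4, 5, 5, 5])
        return f"{n}/5", 1 if n == 5 else -1
    if bf_type is Category.ROM:
        d = rng.choice([30, 45, 50, 60, 90, 110])
        return f"{d} degrees", 1 if d in (45, 50) else -1
    score = rng.choice(["1+", "2+", "2+", "3+", "4+"])
    return score, 1 if score == "2+" else -1


def _word_qualifier(rng: random.Random) -> tuple[str, int]:
    word = rng.choice(sorted(WORD_QUALIFIERS))
    attr = WORD_QUALIFIERS[word]
    return word, 0 if attr is None else attr


def _location(rng: random.Random) -> str:
    lat = rng.choice(LATERALITY)
    anat = rng.choice(ANATOMY)
    if lat == "both" and " " not in anat:
        anat += "s"
    return f"{lat} {anat}"


def _narrative(builder: _PageBuilder, rng: random.Random) -> None:
    bf_type = rng.choice(list(_TYPE_TERMS))
    term = rng.choice(_TYPE_TERMS[bf_type])
    if rng.random() < 0.6:
        qual, pol = _numeric_qualifier(bf_type, rng)
    else:
        qual, pol = _word_qualifier(rng)
    loc = _location(rng)
    if qual in WORD_QUALIFIERS and rng.random() < 0.4:
        # qualifier-first construction: "Decreased range of motion in ..."
        parts = [(qual.capitalize(), "qual"), (" ", None), (term.lower(), "type"),
                 (" in the ", None), (loc, "loc"), (".", None)]
    elif rng.random() < 0.25:
        parts = [(term, "type"), (" ", None), (qual, "qual"), (".", None)]
    else:
        parts = [(term, "type"), (" ", None), (qual, "qual"),
                 (" in the ", None), (loc, "loc"), (".", None)]
    start = builder.offset
    text, spans = _spans_from_parts(parts, start)
    builder.add_line(text)
    m = _mention_from_spans(builder, bf_type, spans, [pol])
    m._page_text = ""  # filled at finalize


def _slot_value(builder: _PageBuilder, rng: random.Random) -> None:
    bf_type = rng.choice(list(_TYPE_TERMS))
    if bf_type is Category.ROM and rng.random() < 0.5:
        # location-as-label slot: "Cervical spine: flexion 45 degrees"
        anat = rng.choice(["Cervical spine", "Lumbar spine", "Shoulder", "Knee"])
        verb = rng.choice(["flexion", "extension", "abduction"])
        qual, pol = _numeric_qualifier(Category.ROM, rng)
        parts = [(anat, "loc"), (": ", None), (verb, "type"), (" ", None), (qual, "qual")]
    else:
        term = rng.choice(_TYPE_TERMS[bf_type])
        if rng.random() < 0.7:
            qual, pol = _numeric_qualifier(bf_type, rng)
        else:
            qual, pol = _word_qualifier(rng)
        parts = [(term, "type"), (": ", None), (qual, "qual")]
        if rng.random() < 0.3:
            parts += [(" ", None), ("bilaterally", "loc")]
    start = builder.offset
    text, spans = _spans_from_parts(parts, start)
    builder.add_line(text)
    _mention_from_spans(builder, bf_type, spans, [pol])


def _context_section(builder: _PageBuilder, rng: random.Random) -> int:
    """A bare type header whose body lines carry only qualifiers; yields
    1-2 discontiguous from-context mentions."""
    header = rng.choice(sorted(CONTEXT_HEADERS))
    bf_type = CONTEXT_HEADERS[header]
    h_start = builder.offset
    builder.add_line(header + ":")
    type_span = (h_start, h_start + len(header), header)
    if rng.random() < 0.35:
        qual, pol = _numeric_qualifier(bf_type, rng)
        parts = [(qual, "qual"), (" throughout.", None)]
        start = builder.offset
        text, spans = _spans_from_parts(parts, start)
        builder.add_line(text)
        _mention_from_spans(builder, bf_type, spans, [pol],
                            from_context=True, type_span=type_span)
        return 1
    q1, p1 = _numeric_qualifier(bf_type, rng)
    q2, p2 = _numeric_qualifier(bf_type, rng)
    parts = [("Right", "loc1"), (" ", None), (q1, "qual1"), (", ", None),
             ("Left", "loc2"), (" ", None), (q2, "qual2"), (".", None)]
    start = builder.offset
    text, spans = _spans_from_parts(parts, start)
    builder.add_line(text)
    for suffix, pol in (("1", p1), ("2", p2)):
        sub = [(role[:-1], s, e, t) for role, s, e, t in spans if role.endswith(suffix)]
        _mention_from_spans(builder, bf_type, sub, [pol],
                            from_context=True, type_span=type_span)
    return 2


def _filtered_section(builder: _PageBuilder, rng: random.Random) -> None:
    """Historical / plan content whose BF-like sentences must NOT be gold."""
    name = rng.choice(["HISTORY", "PLAN OF CARE", "PLAN"])
    builder.add_line(name + ":")
    if name == "HISTORY":
        bf_type = rng.choice(list(_TYPE_TERMS))
        term = rng.choice(_TYPE_TERMS[bf_type])
        qual, _ = _numeric_qualifier(bf_type, rng)
        builder.add_line(f"{term} {qual} in the {_location(rng)} at that time.")
    else:
        builder.add_line(f"Continue home program for the {_location(rng)}.")


def _draw_mention_count(config: GenConfig, rng: random.Random) -> int:
    extra_mean = max(config.mentions_mean - config.mentions_min, 0.01)
    p = 1.0 / (1.0 + extra_mean)
    u = rng.random()
    extra = int(math.log(max(1.0 - u, 1e-12)) / math.log(1.0 - p))
    return min(config.mentions_min + extra, config.mentions_max)


def generate_page(
    config: GenConfig,
    rng: random.Random,
    page_id: str = "page_0001",
    page_no: int = 1,
    n_total: int = 1,
) -> tuple[str, list[Annotation], int]:
    """Generate one page.  Returns (text, gold annotations, mention count).

    Noise (space deletion, column munge) is applied when configured; gold
    offsets are remapped through the edit map and mentions rendered
    unreadable by munging are re-tagged PossibleBF.
    """
    b = _PageBuilder(page_id)
    if config.noise.header_footer:
        b.add_line(HEADER_LINE)
        b.add_line(f"Exam date: {rng.randint(1,12):02d}/{rng.randint(1,28):02d}/{rng.randint(2013,2018)}")
        b.add_line()
    target = _draw_mention_count(config, rng)
    made = 0
    since_section = 99
    while made < target:
        if since_section >= 3 and rng.random() < 0.5:
            b.add_line(rng.choice(PLAIN_SECTIONS) + ":")
            since_section = 0
        r = rng.random()
        remaining = target - made
        if r < config.p_context_section and remaining >= 1:
            made += _context_section(b, rng)
            since_section = 0
        elif r < config.p_context_section + config.p_slot_value:
            _slot_value(b, rng)
            made += 1
        else:
            _narrative(b, rng)
            made += 1
        since_section += 1
        if rng.random() < config.p_distractor / 2:
            b.add_line(rng.choice(DISTRACTORS))
        if rng.random() < 0.2:
            b.add_line()
    if rng.random() < 0.4:
        b.add_line()
        _filtered_section(b, rng)
    if config.noise.header_footer:
        b.add_line()
        b.add_line(f"Page {page_no} of {n_total}")
    text = b.text
    page_like = SimpleNamespace(page_id=page_id, text=text)
    for mention in b.mentions:
        mention._page_text = text
        mention.scope_text = ""
    annotations = mentions_to_annotations(page_like, b.mentions)
    n_mentions = len(b.mentions)
    if config.noise.p_space_deletion > 0 or config.noise.p_column_munge > 0:
        text, annotations, _ = corrupt_ocr(text, annotations, config.noise, rng)
    return text, annotations, n_mentions


# ---------------------------------------------------------------------------
# OCR corruption

def corrupt_ocr(
    text: str,
    gold: list[Annotation],
    noise: NoiseConfig,
    rng: random.Random,
) -> tuple[str, list[Annotation], list[tuple[int, int]]]:
    """Apply OCR-style corruption and remap gold through an explicit edit
    map (never by re-searching, so duplicated substrings stay unambiguous).

    Column munging interleaves the lines of a block (two fused columns);
    gold mentions with a fragment inside the munged block are re-tagged
    ``PossibleBF``.  Space deletion removes single spaces between word
    characters with the configured probability.
    """
    possible_regions: list[tuple[int, int]] = []
    annotations = [Annotation(a.page_id, a.label, list(a.fragments), a.text, dict(a.attrs))
                   for a in gold]

    # --- column munge: permute whole lines of a block
    if noise.p_column_munge > 0 and rng.random() < noise.p_column_munge:
        bounds = [0] + [m.end() for m in re.finditer(r"\n", text)]
        lines = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        if text and not text.endswith("\n"):
            lines.append((bounds[-1], len(text)))
        max_k = (len(lines) - 7) // 2
        if max_k >= 2:
            k = min(rng.choice([2, 3]), max_k)
            first = rng.randrange(3, len(lines) - 3 - 2 * k + 1)
            block = lines[first : first + 2 * k]
            col_a, col_b = block[:k], block[k:]
            new_order = []
            for a_piece, b_piece in zip(col_a, col_b):
                new_order += [a_piece, b_piece]
            pieces = lines[:first] + new_order + lines[first + 2 * k :]
            # fuse each interleaved pair: drop the newline of the first of
            # the pair to emulate columns read across
            fused_newlines = {a_piece for a_piece, _ in zip(col_a, col_b)}
            new_text = []
            mapping: list[tuple[int, int, int]] = []  # old_start, old_end, new_start
            cursor = 0
            for s, e in pieces:
                piece = text[s:e]
                if (s, e) in fused_newlines and piece.endswith("\n"):
                    piece = piece[:-1] + " "
                mapping.append((s, e, cursor))
                new_text.append(piece)
                cursor += len(piece)
            text = "".join(new_text)
            block_old = (block[0][0], block[-1][1])

            def remap_start(pos: int) -> int | None:
                for s, e, ns in mapping:
                    if s <= pos < e:
                        return ns + (pos - s)
                return None

            def remap_end(pos: int) -> int | None:
                inner = remap_start(pos - 1)
                return None if inner is None else inner + 1

            block_new_lo = min(ns for s, e, ns in mapping if block_old[0] <= s < block_old[1])
            block_new_hi = max(ns + (e - s) for s, e, ns in mapping if block_old[0] <= s < block_old[1])
            possible_regions.append((block_new_lo, block_new_hi))

            retagged: list[Annotation] = []
            dropped_component_keys: set[tuple] = set()
            for ann in annotations:
                in_block = any(block_old[0] <= s < block_old[1] for s, _ in ann.fragments)
                new_frags = [(remap_start(s), remap_end(e)) for s, e in ann.fragments]
                ann.fragments = [(s, e) for s, e in new_frags if s is not None and e is not None]
                if not in_block:
                    retagged.append(ann)
                    continue
                if ann.label == "BodyFunction":
                    retagged.append(
                        Annotation(ann.page_id, "PossibleBF", ann.fragments, ann.text)
                    )
                # component annotations inside the block are dropped
            annotations = retagged

    # --- space deletion between word characters
    if noise.p_space_deletion > 0:
        deletions = [
            m.start()
            for m in re.finditer(r"(?<=\w) (?=\w)", text)
            if rng.random() < noise.p_space_deletion
        ]
        if deletions:
            dels = sorted(deletions)
            new_text = []
            prev = 0
            for d in dels:
                new_text.append(text[prev:d])
                prev = d + 1
            new_text.append(text[prev:])
            text = "".join(new_text)

            def shift(pos: int) -> int:
                import bisect

                return pos - bisect.bisect_left(dels, pos)

            for ann in annotations:
                ann.fragments = [(shift(s), shift(e)) for s, e in ann.fragments]
            possible_regions = [(shift(s), shift(e)) for s, e in possible_regions]

    for ann in annotations:
        ann.text = " ".join(text[s:e] for s, e in ann.fragments)
    return text, annotations, possible_regions


# ---------------------------------------------------------------------------
# corpus writing

def generate_corpus(config: GenConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Write ``page_####.txt`` / ``page_####.ann`` pairs plus a manifest
    (seed, config, per-page mention counts, 80/20 train/test split).
    Same seed and config produce a byte-identical corpus."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)
    pages = []
    for i in range(1, config.n_pages + 1):
        page_id = f"page_{i:04d}"
        text, annotations, n_mentions = generate_page(
            config, rng, page_id=page_id, page_no=i, n_total=config.n_pages
        )
        (out / f"{page_id}.txt").write_text(text, encoding="utf-8")
        write_ann(annotations, out / f"{page_id}.ann")
        pages.append({"page_id": page_id, "n_mentions": n_mentions})
    n_train = round(config.train_fraction * config.n_pages)
    split_rng = random.Random(config.seed + 1)
    train_ids = set(split_rng.sample(range(config.n_pages), n_train))
    for i, page in enumerate(pages):
        page["split"] = "train" if i in train_ids else "test"
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "pages": pages,
        "n_train": n_train,
        "n_test": config.n_pages - n_train,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
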