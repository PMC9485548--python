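"""Brat-style standoff annotation reading and writing.

Entities: ``T<n>\t<Label> <start> <end>[;<start> <end>]\t<text>`` with
0-based half-open offsets; discontiguous fragments are semicolon-joined
and their texts space-joined.  Attributes: ``A<n>\t<Name> T<m> <value>``
(Polarity in {-1, 0, 1} and Assertion status here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

TYPE_LABELS = {"STRENGTH": "Strength", "ROM": "ROM", "REFLEX": "Reflex"}


@dataclass
class Annotation:
    page_id: str
    label: str
    fragments: list[tuple[int, int]]
    text: str = ""
    attrs: dict[str, str] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.fragments[0][0]

    @property
    def end(self) -> int:
        return self.fragments[-1][1]

    def key(self) -> tuple:
        return (self.page_id, self.label, tuple(self.fragments))


class StandoffError(ValueError):
    pass


def write_ann(annotations: list[Annotation], path: str | Path) -> None:
    path = Path(path)
    lines = []
    a_counter = 0
    for i, ann in enumerate(sorted(annotations, key=lambda a: (a.fragments, a.label)), start=1):
        frag_str = ";".join(f"{s} {e}" for s, e in ann.fragments)
        text = ann.text.replace("\n", " ")
        lines.append(f"T{i}\t{ann.label} {frag_str}\t{text}")
        for name, value in sorted(ann.attrs.items()):
            a_counter += 1
            lines.append(f"A{a_counter}\t{name} T{i} {value}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_ann(path: str | Path, page_id: str | None = None, text: str | None = None) -> list[Annotation]:
    """Parse a .ann file; *text*, when given, is used to recover fragment
    texts exactly (the .ann text column flattens newlines)."""
    path = Path(path)
    page_id = page_id if page_id is not None else path.stem
    by_tid: dict[str, Annotation] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if line.startswith("T"):
            if len(parts) < 2:
                raise StandoffError(f"{path}:{lineno}: malformed entity line")
            tid = parts[0]
            label_and_spans = parts[1]
            surface = parts[2] if len(parts) > 2 else ""
            label, _, span_str = label_and_spans.partition(" ")
            fragments = []
            for frag in span_str.split(";"):
                try:
                    s, e = (int(x) for x in frag.split())
                except ValueError:
                    raise StandoffError(f"{path}:{lineno}: bad span {frag!r}") from None
                fragments.append((s, e))
            if text is not None:
                surface = " ".join(text[s:e] for s, e in fragments)
            by_tid[tid] = Annotation(page_id, label, fragments, surface)
        elif line.startswith("A"):
            if len(parts) < 2:
                raise StandoffError(f"{path}:{lineno}: malformed attribute line")
            fields = parts[1].split()
            if len(fields) != 3:
                raise StandoffError(f"{path}:{lineno}: attribute needs name, target, value")
            name, target, value = fields
            if target not in by_tid:
                raise StandoffError(f"{path}:{lineno}: attribute targets unknown {target}")
            by_tid[target].attrs[name] = value
    return sorted(by_tid.values(), key=lambda a: (a.fragments, a.label))


def mentions_to_annotations(page, mentions) -> list[Annotation]:
    """Expand extracted mentions into standoff entities: one BodyFunction
    per mention plus its type/qualifier/location component spans (shared
    components deduplicated)."""
    out: list[Annotation] = []
    seen: set[tuple] = set()

    def emit(ann: Annotation) -> None:
        if ann.key() not in seen:
            seen.add(ann.key())
            out.append(ann)

    for mention in mentions:
        frags = mention.fragments
        emit(
            Annotation(
                page.page_id,
                "BodyFunction",
                frags,
                " ".join(page.text[s:e] for s, e in frags),
                attrs={
                    "Polarity": str(mention.polarity),
                    "Assertion": mention.assertion.value,
                },
            )
        )
        emit(
            Annotation(
                page.page_id,
                TYPE_LABELS[mention.bf_type.value],
                list(mention.type_evidence.fragments),
                mention.type_evidence.text,
            )
        )
        for q, qpol in zip(mention.qualifiers, mention.qualifier_polarities or [0] * len(mention.qualifiers)):
            emit(
                Annotation(
                    page.page_id,
                    "Qualifier",
                    list(q.fragments),
                    q.text,
                    attrs={"Polarity": str(qpol)},
                )
            )
        for loc in mention.locations:
            emit(Annotation(page.page_id, "BodyLocation", list(loc.fragments), loc.text))
    return out
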