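"""Span-level evaluation against gold standoff annotations.

Entity-based mode matches whole annotations one-to-one (greedy, in span
order) under either OVERLAP (same label, at least one overlapping
character) or EXACT (identical fragments and label) criteria; unmatched
system spans are false positives, unmatched gold spans false negatives.
Token-based mode assigns label sets to tokens and scores per token, with
token accuracy reported as the Jaccard ratio TP/(TP+FP+FN).

Polarity accuracy is scored only over entity-matched mention pairs, as
100 * TP/(TP+FN) per polarity class: the machine has already found the
mention, so there are no false positives by construction.

Inter-annotator agreement is the same entity F1 with one annotator as
gold and the other as system; F1 is symmetric under that swap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .decompose import PageDoc
from .standoff import Annotation


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def prf_from_counts(counts: EvalCounts) -> tuple[float, float, float]:
    """Precision, recall, F1 with the zero-denominator -> 0 convention,
    reported to 4 decimals (round half to even)."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return round(p, 4), round(r, 4), round(f1, 4)


@dataclass
class EvalReport:
    mode: str
    matching: str
    per_label: dict[str, EvalCounts] = field(default_factory=dict)
    token_accuracy: float | None = None

    def metrics(self, label: str) -> tuple[float, float, float]:
        return prf_from_counts(self.per_label[label])

    @property
    def macro_f1(self) -> float:
        if not self.per_label:
            return 0.0
        f1s = [prf_from_counts(c)[2] for c in self.per_label.values()]
        return round(sum(f1s) / len(f1s), 4)

    @property
    def micro(self) -> tuple[float, float, float]:
        total = EvalCounts()
        for c in self.per_label.values():
            total = total + c
        return prf_from_counts(total)

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "matching": self.matching,
            "per_label": {},
            "macro_f1": self.macro_f1,
        }
        for label, counts in sorted(self.per_label.items()):
            p, r, f1 = prf_from_counts(counts)
            out["per_label"][label] = {
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "precision": p,
                "recall": r,
                "f1": f1,
            }
        if self.token_accuracy is not None:
            out["token_accuracy"] = self.token_accuracy
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")


def _frag_overlap(a: Annotation, b: Annotation) -> bool:
    return any(s0 < e1 and s1 < e0 for s0, e0 in a.fragments for s1, e1 in b.fragments)


def entity_eval(
    gold: list[Annotation],
    system: list[Annotation],
    matching: str = "overlap",
    return_pairs: bool = False,
):
    """One-to-one greedy matching in span order.

    With ``return_pairs=True`` also returns the list of matched
    (gold, system) annotation pairs (used for polarity scoring).
    """
    if matching not in ("overlap", "exact"):
        raise ValueError(f"matching must be 'overlap' or 'exact', got {matching!r}")
    report = EvalReport(mode="entity", matching=matching)
    pairs: list[tuple[Annotation, Annotation]] = []
    pages = sorted({a.page_id for a in gold} | {a.page_id for a in system})
    for page_id in pages:
        g = sorted((a for a in gold if a.page_id == page_id), key=lambda a: (a.fragments, a.label))
        s = sorted((a for a in system if a.page_id == page_id), key=lambda a: (a.fragments, a.label))
        matched_gold: set[int] = set()
        for sys_ann in s:
            hit = None
            for j, gold_ann in enumerate(g):
                if j in matched_gold or gold_ann.label != sys_ann.label:
                    continue
                if matching == "exact":
                    ok = gold_ann.fragments == sys_ann.fragments
                else:
                    ok = _frag_overlap(gold_ann, sys_ann)
                if ok:
                    hit = j
                    break
            counts = report.per_label.setdefault(sys_ann.label, EvalCounts())
            if hit is None:
                counts.fp += 1
            else:
                matched_gold.add(hit)
                counts.tp += 1
                pairs.append((g[hit], sys_ann))
        for j, gold_ann in enumerate(g):
            if j not in matched_gold:
                report.per_label.setdefault(gold_ann.label, EvalCounts()).fn += 1
    if return_pairs:
        return report, pairs
    return report


def token_eval(
    gold: list[Annotation], system: list[Annotation], pages: list[PageDoc]
) -> EvalReport:
    """Token-level scoring: a token carries label L when it overlaps any
    L-labeled fragment; per-label TP/FP/FN over token-label pairs."""
    report = EvalReport(mode="token", matching="overlap")
    grand = EvalCounts()
    for page in pages:
        g_page = [a for a in gold if a.page_id == page.page_id]
        s_page = [a for a in system if a.page_id == page.page_id]
        for token in page.tokens:

            def labels(annotations):
                return {
                    a.label
                    for a in annotations
                    if any(token.start < e and s < token.end for s, e in a.fragments)
                }

            gl, sl = labels(g_page), labels(s_page)
            for label in gl | sl:
                counts = report.per_label.setdefault(label, EvalCounts())
                if label in gl and label in sl:
                    counts.tp += 1
                    grand.tp += 1
                elif label in sl:
                    counts.fp += 1
                    grand.fp += 1
                else:
                    counts.fn += 1
                    grand.fn += 1
    denom = grand.tp + grand.fp + grand.fn
    report.token_accuracy = round(grand.tp / denom, 4) if denom else 0.0
    return report


def polarity_accuracy(
    pairs: list[tuple[int, int]]
) -> dict[int, float | None]:
    """Per-class accuracy 100 * TP/(TP+FN) over (gold, system) polarity
    pairs from entity-matched mentions; a class absent from gold is
    reported as None (undefined), not 0."""
    out: dict[int, float | None] = {}
    for cls in (-1, 0, 1):
        in_class = [(g, s) for g, s in pairs if g == cls]
        if not in_class:
            out[cls] = None
            continue
        correct = sum(1 for g, s in in_class if s == g)
        out[cls] = round(100.0 * correct / len(in_class), 1)
    return out


def iaa(
    ann_a: list[Annotation], ann_b: list[Annotation]
) -> tuple[float, dict[str, float]]:
    """Inter-annotator agreement: macro F1 (unweighted mean over labels)
    plus per-label F1, annotator A as gold and B as system with overlap
    matching."""
    report = entity_eval(ann_a, ann_b, matching="overlap")
    per_label = {label: prf_from_counts(c)[2] for label, c in report.per_label.items()}
    return report.macro_f1, per_label
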