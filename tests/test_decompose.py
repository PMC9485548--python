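"""Page decomposition: lines, tokens, sections, slot values, sentences,
header/footer masking."""

import pytest
from hypothesis import given, settings, strategies as st

from bodyfunc.decompose import (
    PageDoc,
    decompose,
    detect_slot_values,
    segment_lines,
    strip_header_footer,
    tokenize,
)


class TestLines:
    def test_two_lines_trailing_newline_attached(self):
        lines = segment_lines("a\nb")
        assert [(l.start, l.end) for l in lines] == [(0, 2), (2, 3)]
        assert lines[0].text == "a\n"

    def test_empty_text(self):
        assert segment_lines("") == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ab c\n:.5/", max_size=200))
    def test_lines_partition_text(self, text):
        lines = segment_lines(text)
        assert "".join(l.text for l in lines) == text
        for line in lines:
            assert text[line.start : line.end] == line.text


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("5/5", ["5/5"]),
            ("2+", ["2+"]),
            ("", []),
            ("Strength: 5/5.", ["Strength", ":", "5/5", "."]),
            ("45 degrees", ["45", "degrees"]),
            ("range-of-motion", ["range-of-motion"]),
        ],
    )
    def test_examples(self, text, expected):
        tokens = tokenize(text)
        assert [t.text for t in tokens] == expected
        for token in tokens:
            assert text[token.start : token.end] == token.text


class TestSections:
    def test_lexicon_header_detected(self, allow, filter_lex):
        page = decompose("MOTOR:\n5/5 throughout.\n", allow=allow, filter_lex=filter_lex)
        assert [s.name for s in page.sections] == ["MOTOR"]
        assert not page.sections[0].filtered

    def test_indented_header_not_detected(self, allow, filter_lex):
        page = decompose("  Strength: 5/5\n", allow=allow, filter_lex=filter_lex)
        assert page.sections == []

    def test_midline_flag_relaxes_rigidity(self, allow, filter_lex):
        page = decompose("  Motor:\n", allow=allow, filter_lex=filter_lex, midline=True)
        assert [s.name for s in page.sections] == ["Motor"]

    def test_filter_lexicon_marks_filtered(self, allow, filter_lex):
        page = decompose("History:\nold events\n", allow=allow, filter_lex=filter_lex)
        assert page.sections[0].filtered

    def test_allcaps_unknown_header(self, allow, filter_lex):
        page = decompose("LAB RESULTS:\nwbc 5\n", allow=allow, filter_lex=filter_lex)
        assert [s.name for s in page.sections] == ["LAB RESULTS"]
        assert not page.sections[0].filtered

    def test_narrative_line_starting_with_section_word(self, allow, filter_lex):
        # a section term followed by narrative (no colon) stays narrative
        page = decompose("Strength 5/5 in the arm.\n", allow=allow, filter_lex=filter_lex)
        assert page.sections == []

    def test_body_extends_to_next_section(self, allow, filter_lex):
        text = "MOTOR:\nline one.\nREFLEXES:\nline two.\n"
        page = decompose(text, allow=allow, filter_lex=filter_lex)
        motor, reflexes = page.sections
        assert text[motor.body_span[0] : motor.body_span[1]] == "\nline one.\n"
        assert reflexes.body_span[1] == len(text)


class TestSlotValues:
    @pytest.mark.parametrize(
        "line,label,value",
        [
            ("Reflexes: 2+ bilaterally", "Reflexes", "2+ bilaterally"),
            ("Cervical: flexion 45 degrees", "Cervical", "flexion 45 degrees"),
        ],
    )
    def test_detected(self, line, label, value):
        (ln,) = segment_lines(line)
        sv = detect_slot_values(ln)
        assert line[sv.label_span[0] : sv.label_span[1]] == label
        assert line[sv.value_span[0] : sv.value_span[1]] == value

    @pytest.mark.parametrize(
        "line",
        [
            "He walked to the store.",      # no colon / ends in period
            "Plan: continue as before.",     # value ends in period
            "a b c d e f g h: value",        # label too long
            "Label:",                        # empty value
        ],
    )
    def test_rejected(self, line):
        (ln,) = segment_lines(line)
        assert detect_slot_values(ln) is None


class TestSentences:
    def test_split_on_period_uppercase(self, allow, filter_lex):
        page = decompose("Strength 5/5. ROM full.\n", allow=allow, filter_lex=filter_lex)
        assert [s.text for s in page.sentences] == ["Strength 5/5.", "ROM full."]

    def test_empty_page(self, allow, filter_lex):
        assert decompose("", allow=allow, filter_lex=filter_lex).sentences == []

    def test_slot_value_is_one_sentence(self, allow, filter_lex):
        page = decompose("Muscle strength: 4/5\n", allow=allow, filter_lex=filter_lex)
        (sentence,) = page.sentences
        assert sentence.text == "4/5"
        assert sentence.slot_index == 0

    def test_sentence_never_crosses_section(self, allow, filter_lex):
        text = "Some text without period\nMOTOR:\nmore text.\n"
        page = decompose(text, allow=allow, filter_lex=filter_lex)
        boundary = page.sections[0].name_span[0]
        for s in page.sentences:
            assert s.end <= boundary or s.start >= boundary

    def test_offsets_round_trip(self, allow, filter_lex):
        text = "MOTOR:\nStrength 5/5 in the arm. ROM full.\nReflexes: 2+\n"
        page = decompose(text, allow=allow, filter_lex=filter_lex)
        for span in [*page.lines, *page.sentences, *page.tokens]:
            assert text[span.start : span.end] == span.text

    def test_decomposition_pure(self, allow, filter_lex):
        text = "MOTOR:\nStrength 5/5.\n"
        a = decompose(text, allow=allow, filter_lex=filter_lex)
        b = decompose(text, allow=allow, filter_lex=filter_lex)
        assert a.sentences == b.sentences
        assert a.sections == b.sections


class TestHeaderFooter:
    def make_pages(self, bodies, header=None, footer=None):
        pages = []
        for i, body in enumerate(bodies):
            parts = []
            if header:
                parts.append(header)
            parts.append(body)
            if footer:
                parts.append(footer.format(i=i + 1, n=len(bodies)))
            page = PageDoc(page_id=f"p{i}", text="\n".join(parts) + "\n")
            page.lines = segment_lines(page.text)
            pages.append(page)
        return pages

    def test_repeated_footer_masked_with_digit_normalization(self):
        # body lines vary by letters (digit variation would be collapsed
        # by the normalization that lets "Page 1 of 9" match "Page 2 of 9")
        pages = self.make_pages(
            [f"body {'x' * (i + 1)}.\nmid {'y' * (i + 1)}.\nend {'z' * (i + 1)}."
             for i in range(5)],
            footer="Page {i} of {n}",
        )
        masks = strip_header_footer(pages)
        assert all(masks[p.page_id] for p in pages)
        for page in pages:
            (span,) = masks[page.page_id]
            assert "Page" in page.text[span[0] : span[1]]

    def test_no_repeats_no_masks(self):
        pages = self.make_pages(
            [f"unique line {'q' * (i + 1)}.\nsecond {'z' * (i + 1)}au" for i in range(4)]
        )
        masks = strip_header_footer(pages)
        assert all(not v for v in masks.values())

    def test_header_on_four_of_five_pages(self):
        pages = self.make_pages(
            [f"ACME CLINIC 555-0100\nbody {'x' * (i + 1)}.\nmid {'y' * (i + 1)}.\n"
             f"tail {'z' * (i + 1)}." for i in range(4)]
            + ["other start\nbody unique.\nmid alone.\ntail solo."]
        )
        masks = strip_header_footer(pages)
        assert sum(1 for v in masks.values() if v) == 4

    def test_single_page_masks_dateish_only(self):
        pages = self.make_pages(["03/14/2017\nreal content here.\nmore content."])
        masks = strip_header_footer(pages)
        (span,) = masks["p0"]
        assert pages[0].text[span[0] : span[1]].strip() == "03/14/2017"
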