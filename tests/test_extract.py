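"""Mention assembly: evidence annotation, confounder masking, scoping,
context expansion, assertion filtering."""

import pytest

import bodyfunc as bf
from bodyfunc.config import RunConfig
from bodyfunc.extract import (
    Assertion,
    annotate_evidence,
    assemble_mentions,
    expand_context,
    extract_page,
    filter_assertions,
    mask_confounders,
)
from bodyfunc.lexicon import Category


def page_of(text, lexicons):
    return bf.decompose(
        text,
        page_id="p",
        allow=lexicons[Category.SECTION_ALLOW],
        filter_lex=lexicons[Category.SECTION_FILTER],
    )


def cats(evidence):
    return sorted((e.category.value, e.text) for e in evidence)


class TestEvidence:
    def test_strength_fraction_location(self, lexicons):
        page = page_of("Strength 5/5 in the right arm.\n", lexicons)
        ev = annotate_evidence(page, lexicons)
        got = cats(ev)
        assert ("STRENGTH", "Strength") in got
        assert ("NUMERIC_QUALIFIER", "5/5") in got
        assert ("LOCATION", "right") in got and ("LOCATION", "arm") in got

    def test_empty_page(self, lexicons):
        assert annotate_evidence(page_of("", lexicons), lexicons) == []

    def test_slr_is_confounder_not_rom(self, lexicons):
        page = page_of("SLR negative today.\n", lexicons)
        ev = annotate_evidence(page, lexicons)
        assert ("CONFOUNDER", "SLR") in cats(ev)
        assert not any(e.category is Category.ROM for e in ev)

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("graded 2+ today", "2+"),
            ("flexion to 45 degrees", "45 degrees"),
            ("rated 3/5 overall", "3/5"),
        ],
    )
    def test_numeric_patterns(self, text, expected, lexicons):
        page = page_of(text + "\n", lexicons)
        numeric = [
            e for e in annotate_evidence(page, lexicons)
            if e.category is Category.NUMERIC_QUALIFIER
        ]
        assert [e.text for e in numeric] == [expected]

    def test_dates_not_fractions(self, lexicons):
        page = page_of("Seen on 03/14/2017 for exam.\n", lexicons)
        assert not any(
            e.category is Category.NUMERIC_QUALIFIER
            for e in annotate_evidence(page, lexicons)
        )


class TestConfounderMasking:
    def test_vision_fraction_masked(self, lexicons):
        page = page_of("Vision 20/20 bilaterally.\n", lexicons)
        ev = mask_confounders(annotate_evidence(page, lexicons), page)
        assert ev == []

    def test_pain_score_masked_same_phrase(self, lexicons):
        page = page_of("Pain 7/10 today.\n", lexicons)
        ev = mask_confounders(annotate_evidence(page, lexicons), page)
        assert not any(e.category is Category.NUMERIC_QUALIFIER for e in ev)

    def test_no_confounders_identity(self, lexicons):
        page = page_of("Strength 5/5 in the right arm.\n", lexicons)
        ev = annotate_evidence(page, lexicons)
        assert mask_confounders(ev, page) == ev

    def test_masking_is_monotone(self, lexicons):
        """Removing confounder entries never decreases the mention count."""
        text = "Pain 7/10 today.\nStrength 5/5 in the right arm.\n"
        page = page_of(text, lexicons)
        with_conf = extract_page(page, lexicons)
        stripped = dict(lexicons)
        stripped[Category.CONFOUNDER] = bf.Lexicon()
        without_conf = extract_page(page, stripped)
        assert len(without_conf) >= len(with_conf)


class TestAssembly:
    def test_narrative_mention(self, lexicons):
        page = page_of("ROM full in both shoulders.\n", lexicons)
        (m,) = extract_page(page, lexicons)
        assert m.bf_type is Category.ROM
        assert [q.text for q in m.qualifiers] == ["full"]
        assert [l.text for l in m.locations] == ["both shoulders"]
        assert not m.from_context

    def test_location_alone_no_mention(self, lexicons):
        page = page_of("the shoulder\n", lexicons)
        assert extract_page(page, lexicons) == []

    def test_slot_label_supplies_location(self, lexicons):
        page = page_of("Cervical: flexion 45 degrees\n", lexicons)
        (m,) = extract_page(page, lexicons)
        assert m.bf_type is Category.ROM
        assert [l.text for l in m.locations] == ["Cervical"]
        assert m.polarity == 1

    def test_type_nested_location_not_attached(self, lexicons):
        page = page_of("Biceps reflex 2+ in the left arm.\n", lexicons)
        (m,) = extract_page(page, lexicons)
        assert m.bf_type is Category.REFLEX
        assert [l.text for l in m.locations] == ["left arm"]

    def test_every_mention_has_qualifier_and_stays_in_sentence(self, lexicons):
        text = "MOTOR:\nStrength 5/5 in the right arm. ROM full.\nReflexes 2+.\n"
        page = page_of(text, lexicons)
        mentions = extract_page(page, lexicons)
        assert len(mentions) == 3
        for m in mentions:
            assert m.qualifiers
            if not m.from_context:
                sentence = next(
                    s for s in page.sentences
                    if s.start <= m.fragments[0][0] < s.end
                )
                assert all(fs >= sentence.start and fe <= sentence.end
                           for fs, fe in m.fragments)

    def test_deterministic(self, lexicons):
        text = "Strength 4/5 in the left arm.\nReflexes: 2+ bilaterally\n"
        page = page_of(text, lexicons)
        a = [(m.bf_type, m.fragments, m.polarity) for m in extract_page(page, lexicons)]
        b = [(m.bf_type, m.fragments, m.polarity) for m in extract_page(page, lexicons)]
        assert a == b


class TestContextExpansion:
    def test_strength_header_two_mentions(self, lexicons):
        page = page_of("Strength:\nRight 4/5, Left 5/5.\n", lexicons)
        mentions = extract_page(page, lexicons)
        assert len(mentions) == 2
        assert all(m.from_context and m.bf_type is Category.STRENGTH for m in mentions)
        assert [m.polarity for m in mentions] == [-1, 1]
        assert [[l.text for l in m.locations] for m in mentions] == [["Right"], ["Left"]]

    def test_reflexes_header(self, lexicons):
        page = page_of("REFLEXES:\n2+ throughout.\n", lexicons)
        (m,) = extract_page(page, lexicons)
        assert m.from_context and m.bf_type is Category.REFLEX
        assert m.polarity == 1

    def test_non_bf_header_no_mention(self, lexicons):
        page = page_of("ASSESSMENT:\nimproved overall, 4/5 at best.\n", lexicons)
        assert extract_page(page, lexicons) == []

    def test_header_fragment_is_discontiguous(self, lexicons):
        page = page_of("Strength:\n5/5 throughout.\n", lexicons)
        (m,) = extract_page(page, lexicons)
        assert len(m.fragments) == 2  # header + local evidence


class TestAssertionFiltering:
    def test_history_of_suppressed(self, lexicons):
        page = page_of("History of decreased ROM in the left knee.\n", lexicons)
        assert extract_page(page, lexicons) == []
        ev = mask_confounders(annotate_evidence(page, lexicons), page)
        mentions, _ = assemble_mentions(page, ev)
        filter_assertions(mentions, page)
        assert mentions[0].assertion is Assertion.HISTORICAL

    def test_filtered_section_removed(self, lexicons):
        page = page_of("Plan of Care:\nStrength 5/5 in the right arm.\n", lexicons)
        assert extract_page(page, lexicons) == []

    def test_no_triggers_all_asserted(self, lexicons):
        page = page_of("Strength 5/5 in the right arm.\n", lexicons)
        (m,) = extract_page(page, lexicons)
        assert m.assertion is Assertion.ASSERTED

    def test_dates_trigger_flag(self, lexicons):
        text = "Strength 4/5 in the left arm on 01/02/2016.\n"
        page = page_of(text, lexicons)
        assert len(extract_page(page, lexicons)) == 1  # default: dates ignored
        strict = RunConfig(history_dates_trigger=True)
        assert extract_page(page, lexicons, strict) == []

    def test_conditional_flag(self, lexicons):
        text = "When lifting, strength 4/5 in the left arm.\n"
        page = page_of(text, lexicons)
        assert extract_page(page, lexicons) == []
        lax = RunConfig(filters_conditional=False)
        assert len(extract_page(page, lexicons, lax)) == 1
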