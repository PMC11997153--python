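"""Span-containment composition of phrases and attributes."""

from itertools import combinations

import pytest
from hypothesis import given, settings, strategies as st

from szfreq import (
    AttributeSet,
    AttributeSpan,
    AttributeType,
    PhraseSet,
    Span,
    compose,
    compose_within_phrases,
)
from szfreq.synthetic import GeneratorConfig, generate

T = AttributeType


def brute_force_compose(phrases, attributes):
    """Independent oracle: enumerate attribute subsets, keep the maximal
    subsets fully contained in some phrase."""
    attrs = list(attributes)
    best = {}
    for r in range(1, len(attrs) + 1):
        for combo in combinations(attrs, r):
            for phrase in phrases:
                if all(phrase.contains(a.span) for a in combo):
                    cur = best.get(phrase, ())
                    if len(combo) > len(cur):
                        best[phrase] = combo
    return {phrase: frozenset(combo) for phrase, combo in best.items()}


class TestCompose:
    def test_worked_example_yields_two_structured_frequencies(
        self, worked_phrases, worked_attributes
    ):
        structured, report = compose(worked_phrases, worked_attributes)
        assert len(structured) == 2
        first, second = structured
        assert [(a.attr_type.value, a.surface) for a in first.attributes] == [
            ("Event", "Right arm clonic"), ("Quantity", "1"),
            ("Duration", "2"), ("Temporal unit", "weeks"),
        ]
        assert [(a.attr_type.value, a.surface) for a in second.attributes] == [
            ("Event", "GTC"), ("Quantity", "one"),
            ("Duration", "2"), ("Temporal unit", "months"),
        ]
        assert not report.empty_phrases and not report.orphan_attributes

    def test_phrase_with_trailing_period_still_composes(self):
        # phrase "Few per hour." (with period); attributes inside
        text = "Few per hour."
        phrases = PhraseSet((Span(0, 12),))
        attributes = AttributeSet((
            AttributeSpan(Span(0, 2), T.QUANTITY, "Few"),
            AttributeSpan(Span(8, 11), T.TEMPORAL_UNIT, "hour"),
        ))
        (freq,), _ = compose(phrases, attributes)
        assert freq.surface(T.QUANTITY) == "Few"
        assert freq.surface(T.TEMPORAL_UNIT) == "hour"

    def test_straddling_attribute_is_orphaned(self):
        phrases = PhraseSet((Span(0, 5),))
        attributes = AttributeSet((AttributeSpan(Span(4, 8), T.QUANTITY, "cross"),))
        structured, report = compose(phrases, attributes)
        assert structured == []
        assert report.orphan_attributes == [attributes[0]]
        assert report.empty_phrases == [Span(0, 5)]

    def test_empty_phrase_reported_not_emitted(self, worked_attributes):
        phrases = PhraseSet((Span(0, 31), Span(34, 55), Span(56, 56)))
        # span (56,56) would be out of range for the text, but compose is
        # purely positional; it contains no attribute
        structured, report = compose(phrases, worked_attributes)
        assert len(structured) == 2
        assert report.empty_phrases == [Span(56, 56)]

    def test_partition_property_on_generated_corpora(self, small_corpus):
        for seg in small_corpus:
            structured, report = compose(seg.gold_phrases, seg.gold_attributes)
            grouped = [a for f in structured for a in f.attributes]
            assert sorted(grouped + report.orphan_attributes, key=lambda a: a.span) == list(
                seg.gold_attributes
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_equivalence_with_brute_force_oracle(self, seed):
        (seg,) = generate(
            GeneratorConfig(size=1, seed=seed, freq_count_probs=(0, 0.4, 0.4, 0.15, 0.05))
        )
        if len(seg.gold_attributes) > 8:
            return  # oracle is exponential; keep the instances small
        structured, _ = compose(seg.gold_phrases, seg.gold_attributes)
        expected = brute_force_compose(seg.gold_phrases, seg.gold_attributes)
        assert {f.phrase: frozenset(f.attributes) for f in structured} == expected

    def test_order_invariance_after_canonical_sorting(self, worked_attributes):
        shuffled = AttributeSet(tuple(reversed(worked_attributes.spans)))
        phrases = PhraseSet((Span(34, 55), Span(0, 31)))
        a, _ = compose(phrases, shuffled)
        b, _ = compose(PhraseSet((Span(0, 31), Span(34, 55))), worked_attributes)
        assert a == b


class TestComposeWithinPhrases:
    def test_gold_replaying_extractor_matches_compose(self, worked_segment):
        text = worked_segment.text
        gold_attrs = worked_segment.gold_attributes

        def replay(sub: str):
            # return the gold attributes local to whichever phrase sub is
            offset = text.index(sub)
            local = [
                a.shift(-offset)
                for a in gold_attrs
                if offset <= a.span.start and a.span.end < offset + len(sub)
            ]
            return AttributeSet(tuple(local))

        via_phrases = compose_within_phrases(text, worked_segment.gold_phrases, replay)
        direct, _ = compose(worked_segment.gold_phrases, gold_attrs)
        assert via_phrases == direct

    def test_whole_text_attributes_avoid_event_duration_absorption(self):
        # "1–2 minutes" is an event duration, not a frequency; whole-text
        # attribute extraction leaves it out, so the first structured
        # frequency is [Event, Quantity=10, Temporal unit=day]
        text = (
            "automotor seizure lasting 1–2 minutes happening up to 10 times "
            "per day. Progress to tonic-clonic seizures (once every 3–4 months)"
        )

        def span_of(sub, from_=0):
            i = text.index(sub, from_)
            return Span(i, i + len(sub) - 1)

        phrases = PhraseSet((span_of("automotor seizure lasting 1–2 minutes happening up to 10 times per day"),
                             span_of("tonic-clonic seizures (once every 3–4 months")))
        attributes = AttributeSet((
            AttributeSpan(span_of("automotor seizure"), T.EVENT, "automotor seizure"),
            AttributeSpan(span_of("10"), T.QUANTITY, "10"),
            AttributeSpan(span_of("day"), T.TEMPORAL_UNIT, "day"),
            AttributeSpan(span_of("tonic-clonic seizures"), T.EVENT, "tonic-clonic seizures"),
            AttributeSpan(span_of("once"), T.QUANTITY, "once"),
            AttributeSpan(span_of("3"), T.MIN_DURATION, "3"),
            AttributeSpan(span_of("4", text.index("3–4")), T.MAX_DURATION, "4"),
            AttributeSpan(span_of("months"), T.TEMPORAL_UNIT, "months"),
        ))
        structured, _ = compose(phrases, attributes)
        first = structured[0]
        assert [(a.attr_type.value, a.surface) for a in first.attributes] == [
            ("Event", "automotor seizure"), ("Quantity", "10"), ("Temporal unit", "day"),
        ]
        second = structured[1]
        assert [(a.attr_type.value, a.surface) for a in second.attributes] == [
            ("Event", "tonic-clonic seizures"), ("Quantity", "once"),
            ("Minimum duration", "3"), ("Maximum duration", "4"),
            ("Temporal unit", "months"),
        ]

    def test_empty_phrase_set_gives_empty_result(self):
        assert compose_within_phrases("text", PhraseSet(), lambda s: AttributeSet()) == []

    def test_extractor_failure_skips_phrase(self, worked_segment):
        def broken(sub: str):
            raise RuntimeError("model unavailable")

        assert compose_within_phrases(
            worked_segment.text, worked_segment.gold_phrases, broken
        ) == []
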