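"""Pluggable extractor contract and a deterministic rule-based extractor.

The toolkit consumes extractor output through a small contract — anything
that maps segment text to phrase/attribute span sets.  Two reference
implementations ship:

* :class:`RuleExtractor` — a lexicon + pattern grammar over the surface
  language of seizure-frequency narratives (numerals, number words,
  per/every constructions, ranges, year intervals, ages, periodic words and
  a seizure-event lexicon).  It exists as a fully reproducible floor and a
  pipeline exerciser, not as a competitive clinical NLP system.
* :class:`GoldReplayExtractor` — replays a segment's gold annotation
  verbatim; the perfect oracle for end-to-end pipeline tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .schema import (
    AnnotatedSegment,
    AttributeSet,
    AttributeSpan,
    AttributeType,
    PhraseSet,
    SchemaError,
    Span,
)

T = AttributeType

_NUM = r"\d+(?:\.\d+)?"
_NUMW = (
    r"once|twice|thrice|one|two|three|four|five|six|seven|eight|nine|ten"
    r"|eleven|twelve"
)
_VAGUE = r"few|couple|several"
_X = rf"(?:{_NUM}|{_NUMW})"
_XQ = rf"(?:{_NUM}|{_NUMW}|{_VAGUE})"
_UNIT = r"(?:day|week|month|year|hour|night|morning|evening)s?"
_DASH = r"[-–—]"

# longest-first alternation of seizure-event surfaces
DEFAULT_EVENT_LEXICON: tuple[str, ...] = (
    r"right arm clonic",
    r"tonic[ -–]clonic seizures?",
    r"complex partial seizures?",
    r"grand mal seizures?",
    r"generalized tonic[ -–]clonic seizures?",
    r"aphasic seizures?",
    r"automotor seizures?",
    r"automotor sz",
    r"focal seizures?",
    r"absence seizures?",
    r"myoclonic jerks?",
    r"gtc seizures?",
    r"gtc",
    r"auras?",
)

_MONTH = (
    r"(?:January|February|March|April|May|June|July|August|September"
    r"|October|November|December)"
)

# context that licenses a bare number (word) as a seizure Quantity
_QTY_CONTEXT = re.compile(
    r"^\s+(?:per|every|each|times?|seizures?|events?|episodes?"
    r"|daily|weekly|monthly|nightly)\b",
    re.IGNORECASE,
)

_NEGATION = re.compile(r"\bno (?:seizures?|szs?|events?|episodes?)\b", re.IGNORECASE)


@dataclass
class RuleExtractorConfig:
    event_lexicon: tuple[str, ...] = DEFAULT_EVENT_LEXICON
    max_phrase_gap: int = 30  # characters between attribute clusters
    phrase_break_pattern: str = r"[,;]|\band\b"  # gap text that splits phrases


class Extractor:
    """Contract for anything that produces span sets from segment text."""

    name: str = "extractor"

    def extract_phrases(self, text: str) -> PhraseSet:
        raise NotImplementedError

    def extract_attributes(self, text: str) -> AttributeSet:
        raise NotImplementedError


class RuleExtractor(Extractor):
    """Deterministic lexicon + pattern extractor.

    Patterns run in priority order over the whole text; each hit claims its
    character range, and later patterns skip anything overlapping a claimed
    range, so every attribute is emitted exactly once.  A negated mention
    ("no seizures ...") suppresses extraction for the whole segment, since
    such segments describe remission rather than a frequency.
    """

    name = "rules"

    def __init__(self, config: Optional[RuleExtractorConfig] = None):
        self.config = config or RuleExtractorConfig()
        event_alt = "|".join(self.config.event_lexicon)
        self._patterns: list[tuple[re.Pattern, tuple[AttributeType, ...]]] = [
            (
                re.compile(r"\bfrom (\d{4}) to (\d{4})\b"),
                (T.INTERVAL_START, T.INTERVAL_END),
            ),
            (re.compile(rf"\b({_MONTH},? \d{{4}})\b"), (T.TIME,)),
            (
                re.compile(rf"\b(\d+ (?:day|week|month|year)s? ago)\b", re.IGNORECASE),
                (T.RELATIVE_TIME,),
            ),
            (
                re.compile(
                    rf"\b((?:last|past) \d+ (?:day|week|month|year)s?)\b",
                    re.IGNORECASE,
                ),
                (T.RELATIVE_TIME_PERIOD,),
            ),
            (
                re.compile(r"\b(\d+ (?:month|year)s? of age)\b", re.IGNORECASE),
                (T.AGE,),
            ),
            (
                re.compile(r"(?<=started at )(\d+ ?y/o)\b", re.IGNORECASE),
                (T.AGE_START,),
            ),
            (
                re.compile(r"(?<=stopped around )(age \d+)\b", re.IGNORECASE),
                (T.AGE_END,),
            ),
            (
                re.compile(
                    r"\b(daily|weekly|monthly|yearly|nightly|annually)\b",
                    re.IGNORECASE,
                ),
                (T.PERIODIC,),
            ),
            (re.compile(rf"\b(?:{event_alt})\b", re.IGNORECASE), (T.EVENT,)),
            (
                re.compile(
                    rf"\bevery ({_X})\s*{_DASH}\s*({_X})\s+({_UNIT})\b", re.IGNORECASE
                ),
                (T.MIN_DURATION, T.MAX_DURATION, T.TEMPORAL_UNIT),
            ),
            (
                re.compile(rf"\bevery ({_X})\s+({_UNIT})\b", re.IGNORECASE),
                (T.DURATION, T.TEMPORAL_UNIT),
            ),
            (
                re.compile(rf"\b(?:per|every|each|a)\s+({_UNIT})\b", re.IGNORECASE),
                (T.TEMPORAL_UNIT,),
            ),
        ]
        self._range_qty = re.compile(
            rf"\b({_XQ})(?:\s*{_DASH}\s*|\s+to\s+)({_XQ})\b", re.IGNORECASE
        )
        self._qty = re.compile(rf"\b({_XQ})\b", re.IGNORECASE)

    def extract_attributes(self, text: str) -> AttributeSet:
        if not text or _NEGATION.search(text):
            return AttributeSet()
        claimed: list[tuple[int, int]] = []
        attrs: list[AttributeSpan] = []

        def free(start: int, end: int) -> bool:
            return all(end < s or start > e for s, e in claimed)

        def claim(start: int, end: int, attr_type: AttributeType) -> bool:
            if start > end or not free(start, end):
                return False
            claimed.append((start, end))
            attrs.append(
                AttributeSpan(Span(start, end), attr_type, text[start : end + 1])
            )
            return True

        for pattern, types in self._patterns:
            for m in pattern.finditer(text):
                # a pattern only fires if all its groups are unclaimed
                groups = range(1, len(types) + 1) if m.groups() else [0]
                bounds = [(m.start(g), m.end(g) - 1) for g in groups]
                if m.groups() == ():
                    bounds = [(m.start(), m.end() - 1)]
                if all(free(s, e) for s, e in bounds):
                    for (s, e), attr_type in zip(bounds, types):
                        claim(s, e, attr_type)

        event_starts = {
            a.span.start for a in attrs if a.attr_type is T.EVENT
        }

        def licensed(end_pos: int) -> bool:
            return bool(_QTY_CONTEXT.match(text[end_pos + 1 :])) or (
                end_pos + 2 in event_starts
            )

        for m in self._range_qty.finditer(text):
            s, e = m.start(), m.end() - 1
            if free(s, e) and licensed(e):
                claim(m.start(1), m.end(1) - 1, T.MIN_QUANTITY)
                claim(m.start(2), m.end(2) - 1, T.MAX_QUANTITY)

        for m in self._qty.finditer(text):
            s, e = m.start(), m.end() - 1
            if free(s, e) and licensed(e):
                claim(s, e, T.QUANTITY)

        return AttributeSet(tuple(attrs))

    def extract_phrases(
        self, text: str, attributes: Optional[AttributeSet] = None
    ) -> PhraseSet:
        """Cluster attribute hits into maximal phrase spans.

        A cluster breaks where the inter-attribute gap text contains a
        phrase separator (comma, semicolon, "and") or exceeds the
        configured maximum gap.
        """
        if attributes is None:
            attributes = self.extract_attributes(text)
        if len(attributes) == 0:
            return PhraseSet()
        breaker = re.compile(self.config.phrase_break_pattern, re.IGNORECASE)
        clusters: list[list[AttributeSpan]] = [[attributes[0]]]
        for attr in list(attributes)[1:]:
            prev = clusters[-1][-1]
            gap = text[prev.span.end + 1 : attr.span.start]
            if len(gap) > self.config.max_phrase_gap or breaker.search(gap):
                clusters.append([attr])
            else:
                clusters[-1].append(attr)
        return PhraseSet(
            tuple(Span(c[0].span.start, c[-1].span.end) for c in clusters)
        )


def rule_extract_attributes(text: str) -> AttributeSet:
    """Module-level convenience over a default-configured RuleExtractor."""
    return RuleExtractor().extract_attributes(text)


def rule_extract_phrases(text: str) -> PhraseSet:
    return RuleExtractor().extract_phrases(text)


class GoldReplayExtractor(Extractor):
    """Replays gold spans verbatim — the perfect oracle for pipeline tests."""

    name = "gold-replay"

    def extract(self, segment: AnnotatedSegment) -> tuple[PhraseSet, AttributeSet]:
        if segment.gold_phrases is None or segment.gold_attributes is None:
            raise SchemaError(f"segment {segment.id!r} has no gold layer")
        return segment.gold_phrases, segment.gold_attributes


def gold_replay_extractor(segment: AnnotatedSegment) -> tuple[PhraseSet, AttributeSet]:
    return GoldReplayExtractor().extract(segment)


def apply_extractor(
    segments: list[AnnotatedSegment], extractor: Extractor
) -> list[AnnotatedSegment]:
    """Fill the predicted layer of each segment from an extractor.

    Returns the same segment objects with ``predicted_phrases`` /
    ``predicted_attributes`` populated.
    """
    for seg in segments:
        if isinstance(extractor, GoldReplayExtractor):
            phrases, attrs = extractor.extract(seg)
        else:
            attrs = extractor.extract_attributes(seg.text)
            if isinstance(extractor, RuleExtractor):
                phrases = extractor.extract_phrases(seg.text, attrs)
            else:
                phrases = extractor.extract_phrases(seg.text)
        seg.predicted_phrases = phrases
        seg.predicted_attributes = attrs
    return segments
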