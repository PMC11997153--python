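"""Combining phrase spans and attribute spans into structured frequencies.

Given the phrase set P and the attribute set A extracted from one segment,
a structured seizure frequency is the subset of A whose spans all fall
inside one phrase of P (inclusive containment on both ends).  Because both
sets are ordered and non-overlapping, each attribute belongs to at most one
phrase and each phrase's subset is maximal by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

from .schema import (
    AttributeSet,
    AttributeSpan,
    PhraseSet,
    Span,
    StructuredFrequency,
)

logger = logging.getLogger(__name__)


@dataclass
class ComposeReport:
    """Leftovers from composition: phrases with no attributes inside, and
    attributes contained in no phrase (orphans)."""

    empty_phrases: list[Span] = field(default_factory=list)
    orphan_attributes: list[AttributeSpan] = field(default_factory=list)


def compose(
    phrases: PhraseSet, attributes: AttributeSet
) -> tuple[list[StructuredFrequency], ComposeReport]:
    """Group each attribute under the phrase that contains it.

    Returns the structured frequencies ordered by phrase start, plus a
    report of phrases left empty and orphaned attributes.  A phrase with no
    contained attribute yields no structured frequency.
    """
    report = ComposeReport()
    grouped: dict[Span, list[AttributeSpan]] = {p: [] for p in phrases}
    for attr in attributes:
        owner = next((p for p in phrases if p.contains(attr.span)), None)
        if owner is None:
            report.orphan_attributes.append(attr)
        else:
            grouped[owner].append(attr)

    result = []
    for phrase in phrases:
        attrs = grouped[phrase]
        if attrs:
            result.append(StructuredFrequency(phrase, tuple(attrs)))
        else:
            report.empty_phrases.append(phrase)
    return result, report


def compose_within_phrases(
    text: str,
    phrases: PhraseSet,
    attribute_extractor: Callable[[str], AttributeSet],
) -> list[StructuredFrequency]:
    """Alternative strategy: run attribute extraction on each phrase
    substring independently, map offsets back to the full text, and compose.

    Provided for head-to-head comparison with :func:`compose`, which runs
    attribute extraction on the whole text.  An extractor failure on one
    phrase contributes nothing for that phrase (logged).
    """
    all_attrs: list[AttributeSpan] = []
    for phrase in phrases:
        sub = phrase.text_of(text)
        try:
            attrs = attribute_extractor(sub)
        except Exception:  # extractor output is untrusted
            logger.warning(
                "attribute extractor failed on phrase (%d,%d); skipping",
                phrase.start,
                phrase.end,
                exc_info=True,
            )
            continue
        all_attrs.extend(a.shift(phrase.start) for a in attrs)
    structured, _ = compose(phrases, AttributeSet(tuple(all_attrs)))
    return structured
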