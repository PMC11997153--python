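import pytest

from szfreq import (
    AnnotatedSegment,
    AttributeSet,
    AttributeSpan,
    AttributeType,
    PhraseSet,
    Span,
)
from szfreq.synthetic import GeneratorConfig, generate

T = AttributeType

WORKED_TEXT = "Right arm clonic 1 every 2 weeks, GTC one every 2 months"


@pytest.fixture
def worked_text() -> str:
    return WORKED_TEXT


@pytest.fixture
def worked_phrases() -> PhraseSet:
    return PhraseSet((Span(0, 31), Span(34, 55)))


@pytest.fixture
def worked_attributes() -> AttributeSet:
    return AttributeSet(
        (
            AttributeSpan(Span(0, 15), T.EVENT, "Right arm clonic"),
            AttributeSpan(Span(17, 17), T.QUANTITY, "1"),
            AttributeSpan(Span(25, 25), T.DURATION, "2"),
            AttributeSpan(Span(27, 31), T.TEMPORAL_UNIT, "weeks"),
            AttributeSpan(Span(34, 36), T.EVENT, "GTC"),
            AttributeSpan(Span(38, 40), T.QUANTITY, "one"),
            AttributeSpan(Span(48, 48), T.DURATION, "2"),
            AttributeSpan(Span(50, 55), T.TEMPORAL_UNIT, "months"),
        )
    )


@pytest.fixture
def worked_segment(worked_text, worked_phrases, worked_attributes) -> AnnotatedSegment:
    seg = AnnotatedSegment(
        id="worked",
        text=worked_text,
        gold_phrases=worked_phrases,
        gold_attributes=worked_attributes,
    )
    seg.validate()
    return seg


@pytest.fixture(scope="session")
def small_corpus():
    """A deterministic 200-segment synthetic corpus."""
    return generate(GeneratorConfig(size=200, seed=11))


def make_structured(*parts):
    """Build a StructuredFrequency from (type, surface) pairs on a scratch
    text assembled by joining surfaces with single spaces."""
    from szfreq import StructuredFrequency

    attrs = []
    pos = 0
    for attr_type, surface in parts:
        attrs.append(AttributeSpan(Span(pos, pos + len(surface) - 1), attr_type, surface))
        pos += len(surface) + 1
    return StructuredFrequency(Span(0, pos - 2), tuple(attrs))
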