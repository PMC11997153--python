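"""Core data model for seizure-frequency annotation.

A clinical free-text *segment* carries zero or more seizure-frequency
*phrases* (contiguous spans such as ``"Aura- 1–2 per week"``) and typed
*attribute* spans (the pieces of information inside a phrase: the seizure
event, a quantity, a temporal unit, ...).  All offsets are 0-based character
indices with an INCLUSIVE end, in Unicode code points: the span ``(0, 15)``
on ``"Right arm clonic 1 every 2 weeks"`` addresses ``"Right arm clonic"``.

Seventeen attribute types are recognised; no other label is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence


class SchemaError(ValueError):
    """An object violates the annotation schema (unknown label, bad span...)."""


class SpanValidationError(SchemaError):
    """A span does not address a valid region of its owning text."""


class AttributeType(str, Enum):
    """The closed set of 17 seizure-frequency attribute types."""

    EVENT = "Event"
    QUANTITY = "Quantity"
    TEMPORAL_UNIT = "Temporal unit"
    MIN_QUANTITY = "Minimum quantity"
    MAX_QUANTITY = "Maximum quantity"
    INTERVAL_START = "Interval start"
    INTERVAL_END = "Interval end"
    TIME = "Time"
    RELATIVE_TIME = "Relative time"
    RELATIVE_TIME_PERIOD = "Relative time period"
    DURATION = "Duration"
    MIN_DURATION = "Minimum duration"
    MAX_DURATION = "Maximum duration"
    AGE = "Age"
    AGE_START = "Age start"
    AGE_END = "Age end"
    PERIODIC = "Periodic"

    @classmethod
    def from_label(cls, label: str) -> "AttributeType":
        try:
            return cls(label)
        except ValueError:
            raise SchemaError(
                f"unknown attribute type {label!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True, order=True)
class Span:
    """A character-offset interval, 0-based with inclusive end."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise SpanValidationError(
                f"invalid span ({self.start}, {self.end}): need 0 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def text_of(self, text: str) -> str:
        """The substring this span addresses in *text*."""
        if self.end >= len(text):
            raise SpanValidationError(
                f"span ({self.start}, {self.end}) out of range for text of "
                f"length {len(text)}"
            )
        return text[self.start : self.end + 1]

    def contains(self, other: "Span") -> bool:
        """Inclusive containment on both ends."""
        return self.start <= other.start and self.end >= other.end

    def overlaps(self, other: "Span") -> bool:
        return self.start <= other.end and other.start <= self.end

    def shift(self, offset: int) -> "Span":
        return Span(self.start + offset, self.end + offset)


@dataclass(frozen=True)
class AttributeSpan:
    """A typed span plus its surface string (kept redundantly for validation)."""

    span: Span
    attr_type: AttributeType
    surface: str

    def validate_against(self, text: str) -> None:
        actual = self.span.text_of(text)
        if actual != self.surface:
            raise SpanValidationError(
                f"surface mismatch at ({self.span.start}, {self.span.end}): "
                f"stored {self.surface!r} but text reads {actual!r}"
            )

    def shift(self, offset: int) -> "AttributeSpan":
        return AttributeSpan(self.span.shift(offset), self.attr_type, self.surface)


def _check_ordered_nonoverlapping(spans: Sequence[Span], what: str) -> None:
    for prev, cur in zip(spans, spans[1:]):
        if not prev.end < cur.start:
            raise SchemaError(
                f"{what} must be strictly ordered and non-overlapping: "
                f"({prev.start},{prev.end}) vs ({cur.start},{cur.end})"
            )


@dataclass(frozen=True)
class PhraseSet:
    """Ordered, non-overlapping phrase spans (end_i < start_{i+1})."""

    spans: tuple[Span, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.spans))
        object.__setattr__(self, "spans", ordered)
        _check_ordered_nonoverlapping(ordered, "phrase spans")

    def __iter__(self) -> Iterator[Span]:
        return iter(self.spans)

    def __len__(self) -> int:
        return len(self.spans)

    def __getitem__(self, i: int) -> Span:
        return self.spans[i]


@dataclass(frozen=True)
class AttributeSet:
    """Ordered, non-overlapping typed attribute spans."""

    spans: tuple[AttributeSpan, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.spans, key=lambda a: a.span))
        object.__setattr__(self, "spans", ordered)
        _check_ordered_nonoverlapping([a.span for a in ordered], "attribute spans")

    def __iter__(self) -> Iterator[AttributeSpan]:
        return iter(self.spans)

    def __len__(self) -> int:
        return len(self.spans)

    def __getitem__(self, i: int) -> AttributeSpan:
        return self.spans[i]


@dataclass(frozen=True)
class StructuredFrequency:
    """A non-empty bundle of attribute spans grouped under one phrase.

    This is the structured representation of one seizure frequency, e.g.
    [Event="GTC", Quantity="one", Duration="2", Temporal unit="months"].
    Attribute values are addressable by type via :meth:`get` / :meth:`surface`.
    """

    phrase: Span
    attributes: tuple[AttributeSpan, ...]

    def __post_init__(self) -> None:
        if not self.attributes:
            raise SchemaError("a structured frequency must hold >= 1 attribute")
        ordered = tuple(sorted(self.attributes, key=lambda a: a.span))
        object.__setattr__(self, "attributes", ordered)
        for attr in ordered:
            if not self.phrase.contains(attr.span):
                raise SchemaError(
                    f"attribute ({attr.span.start},{attr.span.end}) not contained "
                    f"in phrase ({self.phrase.start},{self.phrase.end})"
                )

    def get(self, attr_type: AttributeType) -> list[AttributeSpan]:
        return [a for a in self.attributes if a.attr_type is attr_type]

    def surface(self, attr_type: AttributeType) -> Optional[str]:
        """Surface of the first attribute of *attr_type*, or None."""
        hits = self.get(attr_type)
        return hits[0].surface if hits else None

    def attribute_key(self) -> frozenset[tuple[int, int, AttributeType]]:
        """Hashable identity of the attribute bundle (spans + types only)."""
        return frozenset(
            (a.span.start, a.span.end, a.attr_type) for a in self.attributes
        )


@dataclass
class AnnotatedSegment:
    """One free-text segment with gold and (optionally) predicted span layers.

    A segment whose ``gold_phrases`` is empty is an instance lacking explicitly
    defined seizure-frequency information (e.g. "Uncertain").
    """

    id: str
    text: str
    gold_phrases: PhraseSet = field(default_factory=PhraseSet)
    gold_attributes: AttributeSet = field(default_factory=AttributeSet)
    predicted_phrases: Optional[PhraseSet] = None
    predicted_attributes: Optional[AttributeSet] = None
    institution: Optional[str] = None

    def validate(self) -> None:
        """Raise :class:`SpanValidationError` on any out-of-range or stale span."""
        for layer in (self.gold_phrases, self.predicted_phrases):
            if layer is None:
                continue
            for span in layer:
                span.text_of(self.text)
        for layer in (self.gold_attributes, self.predicted_attributes):
            if layer is None:
                continue
            for attr in layer:
                attr.validate_against(self.text)

    def phrases(self, layer: str = "gold") -> PhraseSet:
        ps = self.gold_phrases if layer == "gold" else self.predicted_phrases
        if ps is None:
            raise SchemaError(f"segment {self.id!r} has no {layer} phrase layer")
        return ps

    def attributes(self, layer: str = "gold") -> AttributeSet:
        at = self.gold_attributes if layer == "gold" else self.predicted_attributes
        if at is None:
            raise SchemaError(f"segment {self.id!r} has no {layer} attribute layer")
        return at
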