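"""Reading, writing and summarising span-annotated corpora.

The on-disk format is line-delimited JSON in the common span-annotation
export shape: one record per segment with fields ``id``, ``text`` and
``labels`` — a list of ``[start, end, label]`` triples where the label is
either the phrase label (``"FREQ"`` by default) or one of the 17 attribute
types.  Offsets are 0-based Unicode code points; the end is inclusive by
default, with a per-file flag accepting half-open exports from annotation
tools that use that convention.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .schema import (
    AnnotatedSegment,
    AttributeSet,
    AttributeSpan,
    AttributeType,
    PhraseSet,
    SchemaError,
    Span,
)

PHRASE_LABEL = "FREQ"


class CorpusParseError(SchemaError):
    """A corpus record could not be parsed; carries the offending line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def _record_to_segment(
    record: dict,
    line_no: int,
    role: str,
    offsets: str,
    phrase_label: str,
) -> AnnotatedSegment:
    if not isinstance(record, dict) or "text" not in record:
        raise CorpusParseError(line_no, "record is not an object with a 'text' field")
    text = record["text"]
    if not isinstance(text, str):
        raise CorpusParseError(line_no, "'text' must be a string")
    seg_id = str(record.get("id", f"line-{line_no}"))
    labels = record.get("labels", [])
    if not isinstance(labels, list):
        raise CorpusParseError(line_no, "'labels' must be a list of triples")

    phrase_spans: list[Span] = []
    attr_spans: list[AttributeSpan] = []
    for triple in labels:
        try:
            start, end, label = triple
            start, end = int(start), int(end)
        except (TypeError, ValueError):
            raise CorpusParseError(
                line_no, f"malformed label triple {triple!r}"
            ) from None
        if offsets == "half_open":
            end -= 1
        try:
            span = Span(start, end)
            if span.end >= len(text):
                raise CorpusParseError(
                    line_no,
                    f"span ({start}, {end}) out of range for text of length {len(text)}",
                )
            if label == phrase_label:
                phrase_spans.append(span)
            else:
                attr_type = AttributeType.from_label(label)
                attr_spans.append(AttributeSpan(span, attr_type, span.text_of(text)))
        except CorpusParseError:
            raise
        except SchemaError as exc:
            raise CorpusParseError(line_no, str(exc)) from None

    try:
        phrases = PhraseSet(tuple(phrase_spans))
        attributes = AttributeSet(tuple(attr_spans))
    except SchemaError as exc:
        raise CorpusParseError(line_no, str(exc)) from None

    seg = AnnotatedSegment(id=seg_id, text=text, institution=record.get("institution"))
    if role == "gold":
        seg.gold_phrases = phrases
        seg.gold_attributes = attributes
    elif role == "predicted":
        seg.predicted_phrases = phrases
        seg.predicted_attributes = attributes
    else:
        raise ValueError(f"role must be 'gold' or 'predicted', got {role!r}")
    seg.validate()
    return seg


def load_corpus(
    path: Union[str, Path],
    role: str = "gold",
    *,
    offsets: str = "inclusive",
    phrase_label: str = PHRASE_LABEL,
) -> list[AnnotatedSegment]:
    """Load a line-delimited span-annotated corpus.

    Parameters
    ----------
    role:
        Which layer the file's spans populate: ``"gold"`` or ``"predicted"``.
    offsets:
        ``"inclusive"`` (default) or ``"half_open"`` for exports whose end
        offset points one past the last character.
    """
    if offsets not in ("inclusive", "half_open"):
        raise ValueError(f"offsets must be 'inclusive' or 'half_open', got {offsets!r}")
    segments = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(line_no, f"invalid JSON: {exc}") from None
            segments.append(
                _record_to_segment(record, line_no, role, offsets, phrase_label)
            )
    return segments


def segment_to_record(
    segment: AnnotatedSegment,
    *,
    layer: str = "gold",
    phrase_label: str = PHRASE_LABEL,
) -> dict:
    labels: list[list] = []
    for span in segment.phrases(layer):
        labels.append([span.start, span.end, phrase_label])
    for attr in segment.attributes(layer):
        labels.append([attr.span.start, attr.span.end, attr.attr_type.value])
    record = {"id": segment.id, "text": segment.text, "labels": labels}
    if segment.institution is not None:
        record["institution"] = segment.institution
    return record


def save_corpus(
    segments: Iterable[AnnotatedSegment],
    path: Union[str, Path],
    *,
    layer: str = "gold",
    phrase_label: str = PHRASE_LABEL,
) -> None:
    """Write segments as line-delimited JSON; inverse of :func:`load_corpus`."""
    with open(path, "w", encoding="utf-8") as fh:
        for seg in segments:
            record = segment_to_record(seg, layer=layer, phrase_label=phrase_label)
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


@dataclass
class CorpusSummary:
    """Descriptive statistics of an annotated corpus.

    ``frequency_buckets`` counts segments by their number of gold structured
    frequencies (phrases holding at least one attribute).  The median of the
    per-segment frequency counts is the *upper* median: with many
    zero-frequency segments the two central order statistics of an
    even-length corpus can differ, and the upper one is reported.
    """

    n_segments: int
    frequency_buckets: dict[int, int] = field(default_factory=dict)
    mean_frequencies: float = 0.0
    median_frequencies: float = 0.0
    min_frequencies: int = 0
    max_frequencies: int = 0
    mean_words: float = 0.0
    median_words: float = 0.0
    min_words: int = 0
    max_words: int = 0
    per_institution: dict[str, int] = field(default_factory=dict)


def corpus_summary(segments: list[AnnotatedSegment]) -> CorpusSummary:
    """Summarise frequency counts, word counts and institutions of a corpus."""
    # local import to avoid a cycle: compose groups attributes under phrases
    from .compose import compose

    if not segments:
        return CorpusSummary(n_segments=0)

    freq_counts = []
    word_counts = []
    per_inst: dict[str, int] = {}
    for seg in segments:
        structured, _ = compose(seg.gold_phrases, seg.gold_attributes)
        freq_counts.append(len(structured))
        word_counts.append(len(seg.text.split()))
        if seg.institution is not None:
            per_inst[seg.institution] = per_inst.get(seg.institution, 0) + 1

    buckets: dict[int, int] = {}
    for k in freq_counts:
        buckets[k] = buckets.get(k, 0) + 1

    return CorpusSummary(
        n_segments=len(segments),
        frequency_buckets=dict(sorted(buckets.items())),
        mean_frequencies=statistics.fmean(freq_counts),
        median_frequencies=statistics.median_high(freq_counts),
        min_frequencies=min(freq_counts),
        max_frequencies=max(freq_counts),
        mean_words=statistics.fmean(word_counts),
        median_words=statistics.median_high(word_counts),
        min_words=min(word_counts),
        max_words=max(word_counts),
        per_institution=per_inst,
    )
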