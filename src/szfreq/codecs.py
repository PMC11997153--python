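"""Lossless conversion between character spans and model-facing encodings.

Two encodings are supported:

* IOB2 token tags for encoder-style token classifiers — each token is tagged
  ``O``, ``B-<label>`` or ``I-<label>``;
* HTML-like inline tags for generative models — each entity is wrapped in an
  opening tag such as ``<FREQ>`` and a closing tag such as ``<\\FREQ>``
  (backslash form; the forward-slash form ``</FREQ>`` is also accepted when
  parsing).

Decoding from tagged model output cannot assume the model reproduced the
input verbatim: when the tag-stripped string differs from the original text,
offsets are recovered through character-level longest-common-subsequence
alignment and the result is flagged as approximate.
"""

from __future__ import annotations

import difflib
import re
import string
from dataclasses import dataclass, field
from typing import Optional, Union

from .schema import (
    AttributeSet,
    AttributeSpan,
    AttributeType,
    PhraseSet,
    SchemaError,
    Span,
)

PHRASE_LABEL = "FREQ"

_PUNCT = set(string.punctuation) | {"–", "—"}
# interior characters at which a whitespace chunk is further split, so that
# range annotations like "1–2" are token-aligned
_INTERIOR_SPLIT = {"-", "–", "—", "/"}


class AlignmentError(SchemaError):
    """A span does not line up with token boundaries."""


class TagError(SchemaError):
    """Invalid IOB2 tag sequence (strict mode only)."""


@dataclass(frozen=True)
class Token:
    surface: str
    span: Span


@dataclass(frozen=True)
class Iob2Sequence:
    tokens: tuple[Token, ...]
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise SchemaError("one tag per token required")
        for tag in self.tags:
            if tag != "O" and not (tag.startswith("B-") or tag.startswith("I-")):
                raise SchemaError(f"invalid IOB2 tag {tag!r}")


def tokenize(text: str) -> list[Token]:
    """Deterministic tokenization: whitespace split, punctuation peeling,
    and interior splitting at dash/slash characters.

    Every character of every token is addressable in the original text, so
    token spans can carry IOB2 tags back to exact character offsets.
    """
    if not text:
        raise ValueError("cannot tokenize empty text")
    tokens: list[Token] = []

    def emit(start: int, chunk: str) -> None:
        if chunk:
            tokens.append(Token(chunk, Span(start, start + len(chunk) - 1)))

    def split_interior(start: int, core: str) -> None:
        run_start = 0
        for i, ch in enumerate(core):
            if ch in _INTERIOR_SPLIT:
                emit(start + run_start, core[run_start:i])
                emit(start + i, ch)
                run_start = i + 1
        emit(start + run_start, core[run_start:])

    for m in re.finditer(r"\S+", text):
        chunk, base = m.group(), m.start()
        lo, hi = 0, len(chunk)
        leading: list[tuple[int, str]] = []
        trailing: list[tuple[int, str]] = []
        while lo < hi - 0 and chunk[lo] in _PUNCT and hi - lo > 1:
            leading.append((base + lo, chunk[lo]))
            lo += 1
        while hi > lo + 1 and chunk[hi - 1] in _PUNCT:
            trailing.append((base + hi - 1, chunk[hi - 1]))
            hi -= 1
        for pos, ch in leading:
            emit(pos, ch)
        split_interior(base + lo, chunk[lo:hi])
        for pos, ch in reversed(trailing):
            emit(pos, ch)
    return tokens


def _label_of(item: Union[Span, AttributeSpan], phrase_label: str) -> tuple[Span, str]:
    if isinstance(item, AttributeSpan):
        return item.span, item.attr_type.value
    return item, phrase_label


def spans_to_iob2(
    text: str,
    spans: Union[AttributeSet, PhraseSet],
    *,
    phrase_label: str = PHRASE_LABEL,
) -> Iob2Sequence:
    """Encode spans as token-level IOB2 tags.

    Every span boundary must coincide with token boundaries; a span that
    splits a token raises :class:`AlignmentError`.
    """
    tokens = tokenize(text)
    tags = ["O"] * len(tokens)
    for item in spans:
        span, label = _label_of(item, phrase_label)
        covered = [i for i, t in enumerate(tokens) if span.contains(t.span)]
        if (
            not covered
            or tokens[covered[0]].span.start != span.start
            or tokens[covered[-1]].span.end != span.end
        ):
            raise AlignmentError(
                f"span ({span.start},{span.end}) [{label}] does not align with "
                f"token boundaries"
            )
        tags[covered[0]] = f"B-{label}"
        for i in covered[1:]:
            tags[i] = f"I-{label}"
    return Iob2Sequence(tuple(tokens), tuple(tags))


def iob2_to_spans(
    seq: Iob2Sequence,
    *,
    kind: str = "auto",
    strict: bool = False,
    phrase_label: str = PHRASE_LABEL,
) -> Union[AttributeSet, PhraseSet]:
    """Decode an IOB2 sequence back to character spans.

    A span runs from its ``B-`` token's start to the end of the last
    contiguous ``I-`` token of the same label.  An orphan ``I-`` tag (at
    sequence start, after ``O``, or after a different label) is repaired by
    treating it as ``B-`` unless ``strict=True``, in which case it raises
    :class:`TagError`.
    """
    groups: list[tuple[str, Span]] = []
    cur_label: Optional[str] = None
    cur_start = cur_end = 0
    for token, tag in zip(seq.tokens, seq.tags):
        if tag == "O":
            if cur_label is not None:
                groups.append((cur_label, Span(cur_start, cur_end)))
                cur_label = None
            continue
        prefix, label = tag.split("-", 1)
        if prefix == "I" and cur_label == label:
            cur_end = token.span.end
            continue
        if prefix == "I":
            if strict:
                raise TagError(f"orphan tag {tag!r} at token {token.surface!r}")
            # lenient repair: treat as B-
        if cur_label is not None:
            groups.append((cur_label, Span(cur_start, cur_end)))
        cur_label = label
        cur_start, cur_end = token.span.start, token.span.end
    if cur_label is not None:
        groups.append((cur_label, Span(cur_start, cur_end)))

    labels = {label for label, _ in groups}
    if kind == "auto":
        kind = "phrase" if labels and labels <= {phrase_label} else "attribute"
    if kind == "phrase":
        return PhraseSet(tuple(span for _, span in groups))
    text = _reconstruct_text(seq)
    return AttributeSet(
        tuple(
            AttributeSpan(span, AttributeType.from_label(label), span.text_of(text))
            for label, span in groups
        )
    )


def _reconstruct_text(seq: Iob2Sequence) -> str:
    if not seq.tokens:
        return ""
    length = seq.tokens[-1].span.end + 1
    chars = [" "] * length
    for token in seq.tokens:
        for i, ch in enumerate(token.surface):
            chars[token.span.start + i] = ch
    return "".join(chars)


# ---------------------------------------------------------------------------
# HTML-like inline tagging


DEFAULT_CODES: dict[str, str] = {
    PHRASE_LABEL: "FREQ",
    AttributeType.EVENT.value: "EVNT",
    AttributeType.QUANTITY.value: "QNT",
    AttributeType.DURATION.value: "DUR",
    AttributeType.TEMPORAL_UNIT.value: "UNT",
    AttributeType.MIN_QUANTITY.value: "MINQ",
    AttributeType.MAX_QUANTITY.value: "MAXQ",
    AttributeType.INTERVAL_START.value: "INTS",
    AttributeType.INTERVAL_END.value: "INTE",
    AttributeType.TIME.value: "TIME",
    AttributeType.RELATIVE_TIME.value: "RELT",
    AttributeType.RELATIVE_TIME_PERIOD.value: "RELP",
    AttributeType.MIN_DURATION.value: "MIND",
    AttributeType.MAX_DURATION.value: "MAXD",
    AttributeType.AGE.value: "AGE",
    AttributeType.AGE_START.value: "AGES",
    AttributeType.AGE_END.value: "AGEE",
    AttributeType.PERIODIC.value: "PERD",
}


@dataclass(frozen=True)
class TagVocabulary:
    """Injective mapping from span labels to uppercase tag codes."""

    codes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CODES))
    closing_style: str = "backslash"  # "backslash" -> <\X>, "slash" -> </X>

    def __post_init__(self) -> None:
        values = list(self.codes.values())
        if len(set(values)) != len(values):
            raise SchemaError("tag codes must be injective")
        for code in values:
            if not code.isalpha() or not code.isupper():
                raise SchemaError(f"tag code {code!r} must be uppercase letters")

    def open_tag(self, label: str) -> str:
        return f"<{self.codes[label]}>"

    def close_tag(self, label: str) -> str:
        sep = "\\" if self.closing_style == "backslash" else "/"
        return f"<{sep}{self.codes[label]}>"

    def label_for(self, code: str) -> Optional[str]:
        for label, c in self.codes.items():
            if c == code:
                return label
        return None


DEFAULT_VOCAB = TagVocabulary()


def spans_to_tagged(
    text: str,
    spans: Union[AttributeSet, PhraseSet],
    vocab: TagVocabulary = DEFAULT_VOCAB,
    *,
    phrase_label: str = PHRASE_LABEL,
) -> str:
    """Wrap each span in opening/closing tags; stripping all tags reproduces
    *text* character-for-character."""
    items = sorted(
        (_label_of(item, phrase_label) for item in spans), key=lambda x: x[0]
    )
    for (a, _), (b, _) in zip(items, items[1:]):
        if a.overlaps(b):
            raise SchemaError("overlapping spans cannot be tagged")
    out: list[str] = []
    pos = 0
    for span, label in items:
        out.append(text[pos : span.start])
        out.append(vocab.open_tag(label))
        out.append(text[span.start : span.end + 1])
        out.append(vocab.close_tag(label))
        pos = span.end + 1
    out.append(text[pos:])
    return "".join(out)


@dataclass
class DecodeReport:
    """What happened while decoding one tagged string."""

    exact: bool = True
    approximately_aligned: bool = False
    dropped: list[str] = field(default_factory=list)


_TAG_RE = re.compile(r"<([\\/]?)([A-Z]+)>")


def tagged_to_spans(
    tagged: str,
    original: str,
    vocab: TagVocabulary = DEFAULT_VOCAB,
    *,
    phrase_label: str = PHRASE_LABEL,
) -> tuple[Union[AttributeSet, PhraseSet], DecodeReport]:
    """Recover character spans from tagged model output.

    Tags are stripped first; if the stripped string equals *original* the
    offsets are exact, otherwise they are mapped through an LCS alignment and
    the report flags the result as approximate.  Unknown, unclosed or
    unopened tags are dropped with a report entry — generative output is
    never trusted enough to raise.
    """
    report = DecodeReport()
    stripped_parts: list[str] = []
    stripped_len = 0
    open_label: Optional[str] = None
    open_start = 0
    raw: list[tuple[str, int, int]] = []  # (label, start, end) in stripped coords

    pos = 0
    for m in _TAG_RE.finditer(tagged):
        stripped_parts.append(tagged[pos : m.start()])
        stripped_len += m.start() - pos
        pos = m.end()
        closing = m.group(1) != ""
        label = vocab.label_for(m.group(2))
        if label is None:
            report.dropped.append(f"unknown tag {m.group(0)!r}")
            continue
        if not closing:
            if open_label is not None:
                report.dropped.append(f"unclosed tag <{vocab.codes[open_label]}>")
            open_label, open_start = label, stripped_len
        else:
            if open_label != label:
                report.dropped.append(f"unopened closing tag {m.group(0)!r}")
                continue
            if stripped_len > open_start:
                raw.append((label, open_start, stripped_len - 1))
            else:
                report.dropped.append(f"empty tag <{vocab.codes[label]}>")
            open_label = None
    if open_label is not None:
        report.dropped.append(f"unclosed tag <{vocab.codes[open_label]}>")
    stripped_parts.append(tagged[pos:])
    stripped = "".join(stripped_parts)

    if stripped == original:
        mapped = [(label, Span(s, e)) for label, s, e in raw]
    else:
        report.exact = False
        report.approximately_aligned = True
        index_map: list[Optional[int]] = [None] * len(stripped)
        matcher = difflib.SequenceMatcher(None, stripped, original, autojunk=False)
        for block in matcher.get_matching_blocks():
            for k in range(block.size):
                index_map[block.a + k] = block.b + k
        mapped = []
        for label, s, e in raw:
            starts = [index_map[i] for i in range(s, e + 1) if index_map[i] is not None]
            if not starts:
                report.dropped.append(f"unalignable span for label {label!r}")
                continue
            mapped.append((label, Span(starts[0], starts[-1])))

    # degrade gracefully on overlapping decoded spans: keep the earliest,
    # drop the rest with a report entry (model output is never trusted)
    mapped.sort(key=lambda x: x[1])
    filtered: list[tuple[str, Span]] = []
    for label, span in mapped:
        if filtered and span.start <= filtered[-1][1].end:
            report.dropped.append(
                f"overlapping decoded span ({span.start},{span.end}) [{label}]"
            )
            continue
        filtered.append((label, span))
    mapped = filtered

    labels = {label for label, _ in mapped}
    if labels and labels <= {phrase_label}:
        return PhraseSet(tuple(span for _, span in mapped)), report
    attrs = []
    for label, span in mapped:
        if label == phrase_label:
            report.dropped.append("phrase tag mixed into attribute output")
            continue
        attrs.append(
            AttributeSpan(span, AttributeType.from_label(label), span.text_of(original))
        )
    return AttributeSet(tuple(attrs)), report
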