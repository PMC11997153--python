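"""Exact-match evaluation, MAEs, and the paired-bootstrap protocol.

Span extractions are scored by exact match: a prediction is correct only if
its start and end character positions (and type, for typed comparisons)
equal a gold annotation.  A structured frequency is correct only if its full
attribute bundle (spans + types) equals a gold bundle; phrase-boundary
differences alone do not disqualify it, since a phrase extended by e.g. a
trailing period can still carry exactly the right attributes.

Uncertainty is quantified with a paired bootstrap: trials resample segments
with replacement from the test set, every competing system is evaluated on
the identical resamples (one seeded index stream), and system A is declared
significantly better than B when A's metric strictly exceeds B's in more
than 95% of trials.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .compose import compose
from .normalize import UnitTable, DEFAULT_UNITS, to_per_day
from .schema import AnnotatedSegment, AttributeSet, PhraseSet, StructuredFrequency
from .sudep7 import FactorDefinition, sudep7_score


@dataclass(frozen=True)
class MatchCounts:
    true_positive: int
    predicted_total: int
    gold_total: int

    def __post_init__(self) -> None:
        if self.true_positive > min(self.predicted_total, self.gold_total):
            raise ValueError("true positives cannot exceed either total")

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(
            self.true_positive + other.true_positive,
            self.predicted_total + other.predicted_total,
            self.gold_total + other.gold_total,
        )


def match_spans(
    pred: Union[AttributeSet, PhraseSet],
    gold: Union[AttributeSet, PhraseSet],
    typed: bool = True,
) -> MatchCounts:
    """Exact span matching; with ``typed`` the attribute type must agree too."""

    def keys(spans) -> set:
        out = set()
        for item in spans:
            if isinstance(spans, AttributeSet):
                key = (item.span.start, item.span.end, item.attr_type if typed else None)
            else:
                key = (item.start, item.end, None)
            out.add(key)
        return out

    p, g = keys(pred), keys(gold)
    return MatchCounts(len(p & g), len(p), len(g))


def prf(counts: MatchCounts) -> tuple[float, float, float]:
    """Precision, recall, F1 as percentages (2 d.p.).

    Zero-denominator convention: with nothing predicted and nothing gold the
    extraction is vacuously perfect (100); a zero denominator against a
    non-empty other side scores 0.
    """
    tp, pt, gt = counts.true_positive, counts.predicted_total, counts.gold_total
    if pt == 0 and gt == 0:
        return 100.0, 100.0, 100.0
    p = tp / pt if pt else 0.0
    r = tp / gt if gt else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return round(p * 100, 2), round(r * 100, 2), round(f * 100, 2)


def match_structured(
    pred: Sequence[StructuredFrequency],
    gold: Sequence[StructuredFrequency],
    *,
    strict_phrase: bool = False,
) -> MatchCounts:
    """Exact matching of structured frequencies by their attribute bundles.

    Each gold bundle matches at most one prediction.  With
    ``strict_phrase=True`` the phrase span must match as well.
    """

    def key(freq: StructuredFrequency):
        k = freq.attribute_key()
        return (freq.phrase, k) if strict_phrase else k

    pred_keys = Counter(key(f) for f in pred)
    gold_keys = Counter(key(f) for f in gold)
    tp = sum((pred_keys & gold_keys).values())
    return MatchCounts(tp, len(pred), len(gold))


def _check_aligned(
    pred_segments: Sequence[AnnotatedSegment], gold_segments: Sequence[AnnotatedSegment]
) -> None:
    if len(pred_segments) != len(gold_segments) or any(
        p.id != g.id for p, g in zip(pred_segments, gold_segments)
    ):
        raise ValueError("predicted and gold segment lists are not aligned")


def no_frequency_detection(
    pred_segments: Sequence[AnnotatedSegment],
    gold_segments: Sequence[AnnotatedSegment],
) -> MatchCounts:
    """Detection of segments lacking explicitly defined frequency information.

    A segment is a predicted positive when the model emitted zero phrases,
    and a gold positive when the gold annotation holds zero phrases.
    """
    _check_aligned(pred_segments, gold_segments)
    tp = pt = gt = 0
    for p, g in zip(pred_segments, gold_segments):
        pred_pos = len(p.phrases("predicted")) == 0
        gold_pos = len(g.gold_phrases) == 0
        pt += pred_pos
        gt += gold_pos
        tp += pred_pos and gold_pos
    return MatchCounts(tp, pt, gt)


def _segment_structured(seg: AnnotatedSegment, layer: str) -> list[StructuredFrequency]:
    structured, _ = compose(seg.phrases(layer), seg.attributes(layer))
    return structured


def segment_rate(
    seg: AnnotatedSegment,
    layer: str,
    placeholder: float,
    units: UnitTable = DEFAULT_UNITS,
) -> float:
    """Aggregate a segment to one seizures/day value: the sum of its
    structured frequencies' normalized rates (0 when it has none)."""
    return sum(
        to_per_day(f, placeholder, units=units).rate
        for f in _segment_structured(seg, layer)
    )


def mae_rates(
    pred_segments: Sequence[AnnotatedSegment],
    gold_segments: Sequence[AnnotatedSegment],
    placeholder: float,
    units: UnitTable = DEFAULT_UNITS,
) -> float:
    """Mean absolute error between predicted and gold per-day rates."""
    _check_aligned(pred_segments, gold_segments)
    errors = [
        abs(
            segment_rate(p, "predicted", placeholder, units)
            - segment_rate(g, "gold", placeholder, units)
        )
        for p, g in zip(pred_segments, gold_segments)
    ]
    return float(np.mean(errors)) if errors else 0.0


def mae_sudep7(
    pred_segments: Sequence[AnnotatedSegment],
    gold_segments: Sequence[AnnotatedSegment],
    placeholder: float,
    factors: Optional[Sequence[FactorDefinition]] = None,
    units: UnitTable = DEFAULT_UNITS,
) -> float:
    """Mean absolute error between predicted and gold SUDEP-7 scores."""
    _check_aligned(pred_segments, gold_segments)
    errors = []
    for p, g in zip(pred_segments, gold_segments):
        sp = sudep7_score(_segment_structured(p, "predicted"), placeholder, factors, units=units)
        sg = sudep7_score(_segment_structured(g, "gold"), placeholder, factors, units=units)
        errors.append(abs(sp.score - sg.score))
    return float(np.mean(errors)) if errors else 0.0


# ---------------------------------------------------------------------------
# Segment-level metrics and the paired bootstrap


class SegmentMetric:
    """A metric decomposable into per-segment statistics.

    ``per_segment`` maps one segment pair to a statistic tuple;
    ``aggregate`` maps the (trials, k) matrix of statistic sums (and the
    sample size) to one metric value per trial.  This decomposition lets
    10,000 bootstrap trials run as vectorized resummation instead of 10,000
    full evaluations.
    """

    k: int = 1

    def per_segment(self, seg: AnnotatedSegment) -> tuple[float, ...]:
        raise NotImplementedError

    def aggregate(self, sums: np.ndarray, sample_size: int) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, segments: Sequence[AnnotatedSegment]) -> float:
        stats = np.array([self.per_segment(s) for s in segments], dtype=float)
        sums = stats.sum(axis=0, keepdims=True)
        return float(self.aggregate(sums, len(segments))[0])


def _prf_from_sums(sums: np.ndarray, which: str) -> np.ndarray:
    tp, pt, gt = sums[:, 0], sums[:, 1], sums[:, 2]
    both_empty = (pt == 0) & (gt == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(pt > 0, tp / np.maximum(pt, 1), 0.0)
        r = np.where(gt > 0, tp / np.maximum(gt, 1), 0.0)
        f = np.where(p + r > 0, 2 * p * r / np.maximum(p + r, 1e-300), 0.0)
    out = {"precision": p, "recall": r, "f1": f}[which] * 100
    return np.where(both_empty, 100.0, out)


class SpanMatchMetric(SegmentMetric):
    """Precision/recall/F1 over spans or structured frequencies.

    ``task`` selects what is matched: ``"phrase"``, ``"attribute"`` (typed
    exact spans) or ``"structured"`` (full attribute bundles).
    """

    k = 3

    def __init__(self, task: str = "phrase", stat: str = "f1", typed: bool = True):
        if task not in ("phrase", "attribute", "structured"):
            raise ValueError(f"unknown task {task!r}")
        if stat not in ("precision", "recall", "f1"):
            raise ValueError(f"unknown stat {stat!r}")
        self.task = task
        self.stat = stat
        self.typed = typed

    def per_segment(self, seg: AnnotatedSegment) -> tuple[float, ...]:
        if self.task == "phrase":
            counts = match_spans(seg.phrases("predicted"), seg.gold_phrases, typed=False)
        elif self.task == "attribute":
            counts = match_spans(
                seg.attributes("predicted"), seg.gold_attributes, typed=self.typed
            )
        else:
            counts = match_structured(
                _segment_structured(seg, "predicted"),
                _segment_structured(seg, "gold"),
            )
        return (counts.true_positive, counts.predicted_total, counts.gold_total)

    def aggregate(self, sums: np.ndarray, sample_size: int) -> np.ndarray:
        return _prf_from_sums(sums, self.stat)


class RateMaeMetric(SegmentMetric):
    """MAE of per-segment per-day rates (predicted vs gold layers)."""

    k = 1

    def __init__(self, placeholder: float, units: UnitTable = DEFAULT_UNITS):
        self.placeholder = placeholder
        self.units = units

    def per_segment(self, seg: AnnotatedSegment) -> tuple[float, ...]:
        return (
            abs(
                segment_rate(seg, "predicted", self.placeholder, self.units)
                - segment_rate(seg, "gold", self.placeholder, self.units)
            ),
        )

    def aggregate(self, sums: np.ndarray, sample_size: int) -> np.ndarray:
        return sums[:, 0] / sample_size


class Sudep7MaeMetric(SegmentMetric):
    """MAE of per-segment SUDEP-7 scores (predicted vs gold layers)."""

    k = 1

    def __init__(
        self,
        placeholder: float,
        factors: Optional[Sequence[FactorDefinition]] = None,
        units: UnitTable = DEFAULT_UNITS,
    ):
        self.placeholder = placeholder
        self.factors = factors
        self.units = units

    def per_segment(self, seg: AnnotatedSegment) -> tuple[float, ...]:
        sp = sudep7_score(
            _segment_structured(seg, "predicted"), self.placeholder, self.factors,
            units=self.units,
        )
        sg = sudep7_score(
            _segment_structured(seg, "gold"), self.placeholder, self.factors,
            units=self.units,
        )
        return (abs(sp.score - sg.score),)

    def aggregate(self, sums: np.ndarray, sample_size: int) -> np.ndarray:
        return sums[:, 0] / sample_size


@dataclass
class BootstrapResult:
    """Per-trial metric values with their seeded resampling stream.

    ``indices`` holds the (n_trials, sample_size) matrix of resampled
    segment indices so paired comparisons and audits can replay the exact
    trials.
    """

    values: np.ndarray
    mean: float
    sd: float
    seed: int
    indices: np.ndarray = field(repr=False, default=None)


def bootstrap_indices(
    n_segments: int, n_trials: int, sample_size: int, seed: int
) -> np.ndarray:
    """The seeded index stream: same arguments → bit-identical matrix."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_segments, size=(n_trials, sample_size))


def bootstrap(
    metric: Union[SegmentMetric, Callable[[Sequence[AnnotatedSegment]], float]],
    segments: Sequence[AnnotatedSegment],
    n_trials: int = 10_000,
    sample_size: int = 200,
    seed: int = 0,
) -> BootstrapResult:
    """Evaluate *metric* on ``n_trials`` resamples of ``sample_size``
    segments drawn with replacement.

    Competing systems compared with the same ``seed`` (and corpus size) see
    identical resamples, as a paired comparison requires.  A
    :class:`SegmentMetric` runs vectorized; any plain callable on a segment
    list is accepted as a slow path.
    """
    if n_trials < 1 or sample_size < 1:
        raise ValueError("n_trials and sample_size must be >= 1")
    indices = bootstrap_indices(len(segments), n_trials, sample_size, seed)
    if isinstance(metric, SegmentMetric):
        stats = np.array([metric.per_segment(s) for s in segments], dtype=float)
        sums = stats[indices].sum(axis=1)
        values = metric.aggregate(sums, sample_size)
    else:
        values = np.array(
            [metric([segments[i] for i in row]) for row in indices], dtype=float
        )
    return BootstrapResult(
        values=values,
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        seed=seed,
        indices=indices,
    )


@dataclass(frozen=True)
class SignificanceResult:
    proportion: float
    significant: bool


def significance(
    scores_a: np.ndarray, scores_b: np.ndarray, level: float = 0.95
) -> SignificanceResult:
    """Paired significance rule: A beats B when A's per-trial score strictly
    exceeds B's in more than ``level`` of the trials."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired trial vectors must have equal length")
    proportion = float(np.mean(a > b))
    return SignificanceResult(proportion=proportion, significant=proportion > level)
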