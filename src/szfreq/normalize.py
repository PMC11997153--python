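"""Normalizing structured seizure frequencies to a seizures-per-day rate.

A structured frequency such as [Quantity="1", Duration="2", Temporal
unit="weeks"] converts to 1/14 seizures per day.  When a frequency lacks the
information needed for normalization (e.g. no temporal unit, or only a
relative-time context such as "2 years ago"), a caller-supplied placeholder
rate — conventionally the corpus mean over normalizable gold frequencies —
is imputed and flagged as such.

Unit lengths in days are fixed constants (day=1, week=7, month=30.44,
year=365.25, hour=1/24) but overridable through :class:`UnitTable`.  Ranges
(minimum/maximum quantity or duration) collapse to their midpoint by
default; ``range_mode`` selects ``"min"`` or ``"max"`` instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .schema import AnnotatedSegment, AttributeType, StructuredFrequency

T = AttributeType


@dataclass(frozen=True)
class UnitTable:
    """Length of each temporal unit in days."""

    day: float = 1.0
    week: float = 7.0
    month: float = 30.44
    year: float = 365.25
    hour: float = 1.0 / 24.0
    night: float = 1.0
    morning: float = 1.0
    evening: float = 1.0

    def lookup(self, surface: str) -> Optional[float]:
        word = surface.strip().lower().rstrip(".,;")
        word = re.sub(r"s$", "", word)
        aliases = {
            "day": "day", "week": "week", "wk": "week", "month": "month",
            "mo": "month", "year": "year", "yr": "year", "hour": "hour",
            "hr": "hour", "night": "night", "morning": "morning",
            "evening": "evening", "daily": "day", "weekly": "week",
            "monthly": "month", "yearly": "year", "annually": "year",
            "nightly": "night",
        }
        key = aliases.get(word)
        return getattr(self, key) if key else None


DEFAULT_UNITS = UnitTable()

NUMBER_WORDS: dict[str, float] = {
    "once": 1, "twice": 2, "thrice": 3,
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11, "twelve": 12,
}

# vague quantities are explicit, configurable conventions — never hidden
DEFAULT_VAGUE: dict[str, float] = {"few": 3, "couple": 2, "several": 4}


@dataclass(frozen=True)
class QuantityValue:
    """A parsed quantity: a point value and/or a min–max range."""

    point: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None
    vague: bool = False

    def __post_init__(self) -> None:
        if self.point is None and self.min is None and self.max is None:
            raise ValueError("quantity must set point or min/max")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError("quantity range must satisfy min <= max")

    def resolve(self, range_mode: str = "midpoint") -> float:
        if self.point is not None:
            return self.point
        lo = self.min if self.min is not None else self.max
        hi = self.max if self.max is not None else self.min
        assert lo is not None and hi is not None
        return {"midpoint": (lo + hi) / 2, "min": lo, "max": hi}[range_mode]


def parse_quantity(
    surface: str, vague_lexicon: Optional[dict[str, float]] = None
) -> Optional[QuantityValue]:
    """Parse a quantity surface: numerals, number words (once→1 ... twelve→12)
    and vague terms (few→3, couple→2, several→4 by default, flagged vague).

    Returns ``None`` for unparseable surfaces — the explicit "unparsed"
    result that triggers placeholder imputation downstream.
    """
    if vague_lexicon is None:
        vague_lexicon = DEFAULT_VAGUE
    word = surface.strip().lower().rstrip(".,;:")
    try:
        return QuantityValue(point=float(word.replace(",", "")))
    except ValueError:
        pass
    if word in NUMBER_WORDS:
        return QuantityValue(point=NUMBER_WORDS[word])
    if word in vague_lexicon:
        return QuantityValue(point=vague_lexicon[word], vague=True)
    return None


@dataclass(frozen=True)
class NormalizedRate:
    """A seizures-per-day value with provenance.

    ``imputed`` is set exactly when normalization was impossible and the
    placeholder was substituted; ``provenance`` lists the attribute types
    that fed the computation.
    """

    rate: float
    imputed: bool = False
    vague: bool = False
    provenance: tuple[AttributeType, ...] = ()

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")


_YEAR_RE = re.compile(r"^\s*(\d{4})\s*$")
_RELP_RE = re.compile(
    r"(?:last|past|previous)\s+(\d+|\w+)\s+(day|week|month|year|hour)s?",
    re.IGNORECASE,
)

# attribute types whose duplication within one frequency makes normalization
# ambiguous — the normalizer then refuses and imputes
_RATE_TYPES = (
    T.QUANTITY, T.MIN_QUANTITY, T.MAX_QUANTITY, T.DURATION, T.MIN_DURATION,
    T.MAX_DURATION, T.TEMPORAL_UNIT, T.INTERVAL_START, T.INTERVAL_END,
    T.PERIODIC, T.RELATIVE_TIME_PERIOD,
)


def _single_surface(freq: StructuredFrequency, attr_type: AttributeType) -> Optional[str]:
    hits = freq.get(attr_type)
    return hits[0].surface if len(hits) == 1 else None


def _has_duplicates(freq: StructuredFrequency) -> bool:
    return any(len(freq.get(t)) > 1 for t in _RATE_TYPES)


def period_in_days(
    freq: StructuredFrequency,
    units: UnitTable = DEFAULT_UNITS,
    range_mode: str = "midpoint",
) -> Optional[float]:
    """Resolve the temporal denominator of a frequency, in days.

    Resolution order: Duration × unit (or min/max duration midpoint × unit);
    Temporal unit alone; Interval start/end as years; Periodic word;
    Relative time period ("last 10 months").  Returns ``None`` when the
    denominator cannot be resolved (triggers imputation downstream).
    """
    if _has_duplicates(freq):
        return None
    unit_surface = _single_surface(freq, T.TEMPORAL_UNIT)
    unit_len = units.lookup(unit_surface) if unit_surface else None

    if unit_len is not None:
        dur = _single_surface(freq, T.DURATION)
        if dur is not None:
            q = parse_quantity(dur)
            return q.resolve(range_mode) * unit_len if q else None
        mind = _single_surface(freq, T.MIN_DURATION)
        maxd = _single_surface(freq, T.MAX_DURATION)
        if mind is not None or maxd is not None:
            lo = parse_quantity(mind) if mind else None
            hi = parse_quantity(maxd) if maxd else None
            if (mind and lo is None) or (maxd and hi is None):
                return None
            try:
                qv = QuantityValue(
                    min=lo.resolve() if lo else None,
                    max=hi.resolve() if hi else None,
                )
            except ValueError:
                return None
            return qv.resolve(range_mode) * unit_len
        return unit_len

    start = _single_surface(freq, T.INTERVAL_START)
    end = _single_surface(freq, T.INTERVAL_END)
    if start is not None and end is not None:
        ms, me = _YEAR_RE.match(start), _YEAR_RE.match(end)
        if ms and me and int(me.group(1)) > int(ms.group(1)):
            return (int(me.group(1)) - int(ms.group(1))) * units.year
        return None

    periodic = _single_surface(freq, T.PERIODIC)
    if periodic is not None:
        return units.lookup(periodic)

    relp = _single_surface(freq, T.RELATIVE_TIME_PERIOD)
    if relp is not None:
        m = _RELP_RE.search(relp)
        if m:
            n = parse_quantity(m.group(1))
            u = units.lookup(m.group(2))
            if n is not None and u is not None:
                return n.resolve(range_mode) * u
        return None

    return None


def _resolve_quantity(
    freq: StructuredFrequency,
    range_mode: str,
    vague_lexicon: Optional[dict[str, float]],
) -> tuple[Optional[float], bool, list[AttributeType]]:
    """Numerator of the rate: Quantity, min/max quantity range, or an implied
    1 when only a Periodic marker is present."""
    qs = _single_surface(freq, T.QUANTITY)
    if qs is not None:
        qv = parse_quantity(qs, vague_lexicon)
        if qv is None:
            return None, False, []
        return qv.resolve(range_mode), qv.vague, [T.QUANTITY]
    minq = _single_surface(freq, T.MIN_QUANTITY)
    maxq = _single_surface(freq, T.MAX_QUANTITY)
    if minq is not None or maxq is not None:
        lo = parse_quantity(minq, vague_lexicon) if minq else None
        hi = parse_quantity(maxq, vague_lexicon) if maxq else None
        if (minq and lo is None) or (maxq and hi is None):
            return None, False, []
        try:
            qv = QuantityValue(
                min=lo.resolve() if lo else None,
                max=hi.resolve() if hi else None,
                vague=(lo is not None and lo.vague) or (hi is not None and hi.vague),
            )
        except ValueError:
            return None, False, []
        used = [t for t, s in ((T.MIN_QUANTITY, minq), (T.MAX_QUANTITY, maxq)) if s]
        return qv.resolve(range_mode), qv.vague, used
    if freq.get(T.PERIODIC):
        return 1.0, False, [T.PERIODIC]
    return None, False, []


def try_per_day(
    freq: StructuredFrequency,
    *,
    units: UnitTable = DEFAULT_UNITS,
    range_mode: str = "midpoint",
    vague_lexicon: Optional[dict[str, float]] = None,
) -> Optional[NormalizedRate]:
    """Normalize to seizures/day, or ``None`` if the frequency cannot be
    normalized (missing/unparseable quantity or temporal information)."""
    if _has_duplicates(freq):
        return None
    quantity, vague, q_used = _resolve_quantity(freq, range_mode, vague_lexicon)
    period = period_in_days(freq, units, range_mode)
    if quantity is None or period is None or period <= 0:
        return None
    period_types = [
        t
        for t in (
            T.DURATION, T.MIN_DURATION, T.MAX_DURATION, T.TEMPORAL_UNIT,
            T.INTERVAL_START, T.INTERVAL_END, T.PERIODIC, T.RELATIVE_TIME_PERIOD,
        )
        if freq.get(t)
    ]
    return NormalizedRate(
        rate=quantity / period,
        imputed=False,
        vague=vague,
        provenance=tuple(dict.fromkeys(q_used + period_types)),
    )


def to_per_day(
    freq: StructuredFrequency,
    placeholder: float,
    *,
    units: UnitTable = DEFAULT_UNITS,
    range_mode: str = "midpoint",
    vague_lexicon: Optional[dict[str, float]] = None,
) -> NormalizedRate:
    """Normalize to seizures/day, imputing *placeholder* when impossible."""
    if placeholder < 0:
        raise ValueError("placeholder must be >= 0")
    rate = try_per_day(
        freq, units=units, range_mode=range_mode, vague_lexicon=vague_lexicon
    )
    if rate is None:
        return NormalizedRate(rate=placeholder, imputed=True)
    return rate


def corpus_mean_rate(
    segments: list[AnnotatedSegment],
    *,
    layer: str = "gold",
    units: UnitTable = DEFAULT_UNITS,
    range_mode: str = "midpoint",
) -> float:
    """Mean seizures/day over all normalizable structured frequencies of a
    corpus layer — the conventional placeholder value.

    Imputed (non-normalizable) frequencies are excluded to avoid
    circularity.  Raises ``ValueError`` when nothing is normalizable, in
    which case an explicit placeholder must be supplied instead.
    """
    from .compose import compose

    rates = []
    for seg in segments:
        structured, _ = compose(seg.phrases(layer), seg.attributes(layer))
        for freq in structured:
            nr = try_per_day(freq, units=units, range_mode=range_mode)
            if nr is not None:
                rates.append(nr.rate)
    if not rates:
        raise ValueError(
            "no normalizable structured frequency in corpus; "
            "supply an explicit placeholder rate"
        )
    return sum(rates) / len(rates)
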