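"""SUDEP-7 risk scoring from structured seizure frequencies.

The SUDEP-7 inventory is a seven-item checklist for Sudden Unexpected Death
in Epilepsy risk; its first four items concern seizure frequency and are the
ones computable from extracted frequencies:

* F1 — more than three tonic-clonic (GTC) seizures in the last year;
* F2 — one or more tonic-clonic seizures in the last year;
* F3 — one or more seizures of any type over the last 12 months;
* F4 — more than fifty seizures of any type per month.

Each structured frequency is normalized to seizures/day (with placeholder
imputation when impossible), then annualized or monthlyized for the factor
predicates.  Rates of the same event class are summed before predicates are
evaluated.  Factors carry unit weights by default — one satisfied factor
contributes one point — and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .normalize import DEFAULT_UNITS, UnitTable, to_per_day
from .schema import AttributeType, StructuredFrequency


class EventClass(Enum):
    GTC = "GTC"
    OTHER = "other"
    UNSPECIFIED = "unspecified"


# substrings identifying a generalized tonic-clonic (convulsive) event
DEFAULT_GTC_LEXICON: tuple[str, ...] = (
    "gtc",
    "tonic-clonic",
    "tonic clonic",
    "generalized tonic",
    "grand mal",
    "convuls",
)


def classify_event(
    surface: Optional[str], gtc_lexicon: Sequence[str] = DEFAULT_GTC_LEXICON
) -> EventClass:
    """Classify an Event surface as GTC, other, or unspecified (no surface)."""
    if surface is None:
        return EventClass.UNSPECIFIED
    lowered = surface.lower()
    if any(term in lowered for term in gtc_lexicon):
        return EventClass.GTC
    return EventClass.OTHER


@dataclass(frozen=True)
class FactorDefinition:
    """One frequency-based SUDEP-7 factor.

    The predicate reads: the summed rate of *event_class* seizures,
    expressed per *window*, ``comparison`` the *threshold*.
    """

    id: int
    event_class: str  # "GTC" | "any"
    threshold: float
    window: str  # "year" | "month"
    comparison: str  # "gt" | "ge"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.event_class not in ("GTC", "any"):
            raise ValueError("event_class must be 'GTC' or 'any'")
        if self.window not in ("year", "month"):
            raise ValueError("window must be 'year' or 'month'")
        if self.comparison not in ("gt", "ge"):
            raise ValueError("comparison must be 'gt' or 'ge'")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    def fires(self, value: float) -> bool:
        return value > self.threshold if self.comparison == "gt" else value >= self.threshold


def default_factors() -> list[FactorDefinition]:
    """The four frequency-related factors with unit weights."""
    return [
        FactorDefinition(1, "GTC", 3, "year", "gt"),
        FactorDefinition(2, "GTC", 1, "year", "ge"),
        FactorDefinition(3, "any", 1, "year", "ge"),
        FactorDefinition(4, "any", 50, "month", "gt"),
    ]


@dataclass
class Sudep7Result:
    score: float
    fired: list[int]
    gtc_rate_per_day: float
    any_rate_per_day: float
    factor_values: dict[int, float]


def sudep7_score(
    frequencies: Sequence[StructuredFrequency],
    placeholder: float,
    factors: Optional[Sequence[FactorDefinition]] = None,
    *,
    units: UnitTable = DEFAULT_UNITS,
) -> Sudep7Result:
    """Score a segment's structured frequencies against the factor set.

    GTC-class rates feed the GTC factors; all rates feed the any-type
    factors.  An imputed rate has an unknown event class and therefore
    counts toward the any-type factors only.  No frequencies → score 0.
    """
    if factors is None:
        factors = default_factors()
    gtc_rate = 0.0
    any_rate = 0.0
    for freq in frequencies:
        nr = to_per_day(freq, placeholder, units=units)
        any_rate += nr.rate
        if nr.imputed:
            continue
        surfaces = [a.surface for a in freq.get(AttributeType.EVENT)]
        classes = [classify_event(s) for s in surfaces] or [EventClass.UNSPECIFIED]
        if EventClass.GTC in classes:
            gtc_rate += nr.rate

    fired: list[int] = []
    values: dict[int, float] = {}
    score = 0.0
    for factor in factors:
        base = gtc_rate if factor.event_class == "GTC" else any_rate
        scale = units.year if factor.window == "year" else units.month
        value = base * scale
        values[factor.id] = value
        if factor.fires(value):
            fired.append(factor.id)
            score += factor.weight
    return Sudep7Result(
        score=score,
        fired=fired,
        gtc_rate_per_day=gtc_rate,
        any_rate_per_day=any_rate,
        factor_values=values,
    )
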