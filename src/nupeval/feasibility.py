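"""Feasibility-for-sustainable-exploitation scoring and readiness banding.

Twelve attributes — spanning cultivation history, conservation status,
distribution, commercial products, propagation and cultivation knowledge,
and water demand — are each scored on an attribute-specific admissible set
of integers with maximum 6.  The sum (out of 72) expressed as a percentage
is the species' exploitation feasibility, which in turn determines a
readiness timescale: above 70% exploitation is already achievable, above
55% up to 70% it is achievable in the short term, and at or below 55% the
framework assigns no band.

The semantic mapping from species facts (IUCN category, occurrence range,
marketed products, ...) onto these integers is the evaluator's judgement and
arrives here as input; this module enforces the admissible score sets,
aggregates, and classifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .rounding import percent_of_max

__all__ = [
    "FeasibilityAttribute",
    "FeasibilityAttributeSpec",
    "FeasibilityScoreCard",
    "ReadinessBand",
    "BandRule",
    "ReadinessAssessment",
    "MAX_FEASIBILITY_TOTAL",
    "default_attribute_specs",
    "default_band_table",
    "validate_scorecard",
    "feasibility_percentage",
    "classify_readiness",
    "readiness_report",
]

MAX_FEASIBILITY_TOTAL = 72  # 12 attributes x 6


class FeasibilityAttribute(str, Enum):
    EXISTING_CULTIVATIONS = "existing_cultivations"
    THREAT_CATEGORY = "threat_category"
    PROTECTION_STATUS = "protection_status"
    EX_SITU_CONSERVATION = "ex_situ_conservation"
    DISTRIBUTION = "distribution"
    COMMERCIAL_PRODUCTS = "commercial_products"
    KNOWN_PROPAGATION = "known_propagation"
    VEGETATIVE_PROPAGATION_SUCCESS = "vegetative_propagation_success"
    SEED_GERMINATION_SUCCESS = "seed_germination_success"
    CULTIVATION_NEEDS = "cultivation_needs"
    EXISTING_CULTIVATION_PROTOCOLS = "existing_cultivation_protocols"
    WATER_DEMAND = "water_demand"


@dataclass(frozen=True)
class FeasibilityAttributeSpec:
    """Admissible integer scores for one attribute (maximum always 6)."""

    attribute_id: FeasibilityAttribute
    allowed_scores: frozenset[int]
    max_score: int = 6

    def __post_init__(self) -> None:
        if not self.allowed_scores <= set(range(7)):
            raise ValidationError(
                f"{self.attribute_id.value}: allowed scores must lie in 0..6"
            )
        if max(self.allowed_scores) != self.max_score:
            raise ValidationError(
                f"{self.attribute_id.value}: max allowed score must be "
                f"{self.max_score}"
            )


_FULL = frozenset(range(7))

_DEFAULT_ALLOWED: dict[FeasibilityAttribute, frozenset[int]] = {
    FeasibilityAttribute.EXISTING_CULTIVATIONS: frozenset({0, 6}),
    FeasibilityAttribute.THREAT_CATEGORY: _FULL,
    FeasibilityAttribute.PROTECTION_STATUS: frozenset({0, 4, 5, 6}),
    FeasibilityAttribute.EX_SITU_CONSERVATION: _FULL,
    FeasibilityAttribute.DISTRIBUTION: _FULL,
    FeasibilityAttribute.COMMERCIAL_PRODUCTS: _FULL,
    FeasibilityAttribute.KNOWN_PROPAGATION: frozenset({0, 3, 5, 6}),
    FeasibilityAttribute.VEGETATIVE_PROPAGATION_SUCCESS: _FULL,
    FeasibilityAttribute.SEED_GERMINATION_SUCCESS: _FULL,
    FeasibilityAttribute.CULTIVATION_NEEDS: frozenset({0, 3, 5, 6}),
    FeasibilityAttribute.EXISTING_CULTIVATION_PROTOCOLS: _FULL,
    FeasibilityAttribute.WATER_DEMAND: frozenset({0, 1, 3, 6}),
}


def default_attribute_specs() -> list[FeasibilityAttributeSpec]:
    """Specs for all 12 attributes with their printed admissible score sets."""
    return [FeasibilityAttributeSpec(attr, allowed)
            for attr, allowed in _DEFAULT_ALLOWED.items()]


@dataclass(frozen=True)
class FeasibilityScoreCard:
    species_name: str
    scores: Mapping[FeasibilityAttribute, int]
    total: int
    max_total: int
    percentage: float
    sources: Mapping[FeasibilityAttribute, str] = field(default_factory=dict)


class ReadinessBand(str, Enum):
    ALREADY_ACHIEVED = "already_achieved"
    ACHIEVABLE_SHORT_TERM = "achievable_short_term"
    UNCLASSIFIED_BELOW_55 = "unclassified_below_55"


@dataclass(frozen=True)
class BandRule:
    """percentage in (lower, upper] selects this band; None = unbounded."""

    band: ReadinessBand
    label: str
    lower_exclusive: Optional[float]
    upper_inclusive: Optional[float]

    def contains(self, pct: float) -> bool:
        if self.lower_exclusive is not None and pct <= self.lower_exclusive:
            return False
        if self.upper_inclusive is not None and pct > self.upper_inclusive:
            return False
        return True


def default_band_table() -> list[BandRule]:
    """The two published readiness bands plus a catch-all for lower scores.

    Thresholds are strict lower bounds, so exactly 70% is still short-term
    and exactly 55% is unclassified.
    """
    return [
        BandRule(ReadinessBand.ALREADY_ACHIEVED,
                 "Already achieved (>70%)", 70.0, None),
        BandRule(ReadinessBand.ACHIEVABLE_SHORT_TERM,
                 "Achievable in short-term (>55-70%)", 55.0, 70.0),
        BandRule(ReadinessBand.UNCLASSIFIED_BELOW_55,
                 "Unclassified by this framework (<=55%)", None, 55.0),
    ]


@dataclass(frozen=True)
class ReadinessAssessment:
    species_name: str
    percentage: float
    band: ReadinessBand
    band_label: str


def validate_scorecard(
    species_name: str,
    scores: Mapping[FeasibilityAttribute | str, int],
    specs: Optional[Sequence[FeasibilityAttributeSpec]] = None,
    sources: Optional[Mapping[FeasibilityAttribute | str, str]] = None,
) -> FeasibilityScoreCard:
    """Check a 12-score vector against the admissible sets and aggregate it.

    Raises :class:`ValidationError` naming the attribute when a score is
    missing or outside its admissible set.
    """
    if specs is None:
        specs = default_attribute_specs()
    by_attr = {s.attribute_id: s for s in specs}
    norm = {FeasibilityAttribute(k): int(v) for k, v in scores.items()}
    missing = set(by_attr) - set(norm)
    if missing:
        raise ValidationError(
            f"{species_name}: missing attribute(s) "
            f"{sorted(a.value for a in missing)}"
        )
    extra = set(norm) - set(by_attr)
    if extra:
        raise ValidationError(
            f"{species_name}: unknown attribute(s) "
            f"{sorted(a.value for a in extra)}"
        )
    for attr, value in norm.items():
        allowed = by_attr[attr].allowed_scores
        if value not in allowed:
            raise ValidationError(
                f"{species_name}: {attr.value}={value} not in admissible set "
                f"{sorted(allowed)}"
            )
    total = sum(norm.values())
    max_total = sum(s.max_score for s in specs)
    src = {FeasibilityAttribute(k): str(v) for k, v in (sources or {}).items()}
    return FeasibilityScoreCard(
        species_name=species_name, scores=norm, total=total,
        max_total=max_total, percentage=percent_of_max(total, max_total),
        sources=src,
    )


def feasibility_percentage(total: int, max_total: int = MAX_FEASIBILITY_TOTAL) -> float:
    """Total score as a percentage of the maximum, one decimal,
    ties rounded away from zero (e.g. 40/72 -> 55.6)."""
    if not 0 <= total <= max_total:
        raise ValidationError(f"total {total} outside [0, {max_total}]")
    return percent_of_max(total, max_total)


def classify_readiness(
    percentage: float,
    species_name: str = "",
    bands: Optional[Sequence[BandRule]] = None,
) -> ReadinessAssessment:
    """Assign the readiness-timescale band for a feasibility percentage."""
    if not 0 <= percentage <= 100:
        raise ValidationError(f"percentage {percentage} outside [0, 100]")
    if bands is None:
        bands = default_band_table()
    for rule in bands:
        if rule.contains(percentage):
            return ReadinessAssessment(
                species_name=species_name, percentage=percentage,
                band=rule.band, band_label=rule.label,
            )
    raise ValidationError(
        f"band table does not cover percentage {percentage}"
    )


def readiness_report(
    cards: Sequence[FeasibilityScoreCard],
    bands: Optional[Sequence[BandRule]] = None,
) -> pd.DataFrame:
    """Per-species summary: attribute scores, total, percentage and readiness
    band, sorted by percentage descending (ties alphabetical)."""
    if not cards:
        raise ValidationError("readiness_report needs at least one score card")
    rows = []
    for card in cards:
        assessment = classify_readiness(card.percentage, card.species_name, bands)
        row = {"species": card.species_name}
        row.update({a.value: card.scores[a] for a in FeasibilityAttribute})
        row["total"] = card.total
        row["max_total"] = card.max_total
        row["percentage"] = card.percentage
        row["band"] = assessment.band.value
        row["band_label"] = assessment.band_label
        row["sources"] = "; ".join(
            f"{a.value}: {card.sources[a]}" for a in FeasibilityAttribute
            if a in card.sources
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["percentage", "species"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
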