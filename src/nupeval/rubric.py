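"""Ordinal rubric scoring of raw germplasm measurements.

Seven attributes spanning four evaluation axes — molecular authentication,
phytochemistry (antioxidant activity as % radical scavenging, total phenolic
content in mg GAE/100 g), asexual propagation (% rooting of cuttings), and ex
situ cultivation (juvenile tree height at 18 months, % height increase from
6-18 months, onset of fruit production) — are each mapped onto an ordinal
0-5 score through fixed threshold bands.  The seven scores sum to a total out
of 35, reported as a percentage of the maximum: the species' multifaceted
potential.

Band boundary convention: a band printed as "5-20" is closed at both ends,
while a ">"-prefixed lower end is open, so consecutive bands tile the axis as
[5, 20], (20, 30], (30, 50], ...  The top band of every quantitative scale is
open-ended above, which also clamps out-of-range highs (e.g. a total phenolic
content above 200 mg GAE/100 g still scores 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ScaleTypeError, ValidationError
from .rounding import percent_of_max

__all__ = [
    "RubricAttribute",
    "ScaleKind",
    "Band",
    "AttributeScale",
    "GenotypeMeasurements",
    "SpeciesRawProfile",
    "MultifacetedScoreCard",
    "MAX_ATTRIBUTE_SCORE",
    "MAX_TOTAL",
    "default_scales",
    "score_value",
    "score_species",
    "compare_species",
]

MAX_ATTRIBUTE_SCORE = 5
MAX_TOTAL = 35  # 7 attributes x 5


class RubricAttribute(str, Enum):
    """The seven rubric attributes, keyed by what they measure."""

    MOLECULAR_AUTH = "molecular_auth"
    ROOTING_PCT = "rooting_pct"
    ANTIOXIDANT_AA_PCT = "antioxidant_aa_pct"
    TPC_MG_GAE_100G = "tpc_mgGAE_100g"
    TREE_HEIGHT_18M_M = "tree_height_18m_m"
    GROWTH_RATE_PCT = "growth_rate_pct"
    FRUIT_ONSET = "fruit_onset"


class ScaleKind(str, Enum):
    NUMERIC = "numeric"      # non-negative real, score ascending in value
    BOOLEAN = "boolean"      # authenticated / not
    SEASON = "season"        # positive integer season index, score descending


@dataclass(frozen=True)
class Band:
    """One score band: ``lower``/``upper`` of None mean unbounded on that end."""

    score: int
    lower: Optional[float] = None
    upper: Optional[float] = None
    lower_closed: bool = True
    upper_closed: bool = True

    def contains(self, x: float) -> bool:
        if self.lower is not None:
            if self.lower_closed:
                if x < self.lower:
                    return False
            elif x <= self.lower:
                return False
        if self.upper is not None:
            if self.upper_closed:
                if x > self.upper:
                    return False
            elif x >= self.upper:
                return False
        return True


@dataclass(frozen=True)
class AttributeScale:
    """Ordered score bands for one rubric attribute.

    For NUMERIC scales the bands must tile [0, inf) without overlap so every
    admissible raw value maps to exactly one score.  A missing raw value
    always scores 0 ("no data / not evaluated") regardless of the bands.
    """

    attribute_id: RubricAttribute
    kind: ScaleKind
    bands: tuple[Band, ...] = ()
    max_score: int = MAX_ATTRIBUTE_SCORE

    def __post_init__(self) -> None:
        if self.kind is ScaleKind.BOOLEAN:
            return
        scores = [b.score for b in self.bands]
        if len(set(scores)) != len(scores):
            raise ValidationError(
                f"{self.attribute_id.value}: duplicate band scores {scores}"
            )
        if any(not (0 <= b.score <= self.max_score) for b in self.bands):
            raise ValidationError(
                f"{self.attribute_id.value}: band score outside 0..{self.max_score}"
            )

    def band_for(self, x: float) -> Band:
        hits = [b for b in self.bands if b.contains(x)]
        if len(hits) != 1:
            raise ValidationError(
                f"{self.attribute_id.value}: value {x!r} matched "
                f"{len(hits)} bands (expected exactly 1)"
            )
        return hits[0]

    def band_for_score(self, score: int) -> Band:
        for b in self.bands:
            if b.score == score:
                return b
        raise ValidationError(
            f"{self.attribute_id.value}: no band with score {score}"
        )


def _ascending_bands(edges: Sequence[float], first_lower_closed: bool = True) -> tuple[Band, ...]:
    """Bands for thresholds printed as ``<e0, e0-e1, >e1-e2, ...``: score 0
    below the first edge, then closed-closed, then open-closed intervals, with
    the top band open-ended."""
    bands = [Band(0, lower=None, upper=edges[0], upper_closed=False)]
    lower = edges[0]
    lower_closed = first_lower_closed
    for score, upper in enumerate(edges[1:], start=1):
        bands.append(Band(score, lower=lower, upper=upper,
                          lower_closed=lower_closed, upper_closed=True))
        lower, lower_closed = upper, False
    bands.append(Band(len(edges), lower=lower, upper=None, lower_closed=False))
    return tuple(bands)


def default_scales() -> list[AttributeScale]:
    """The default threshold rubric for all seven attributes.

    Quantitative scales (edges delimit scores 0..5):

    ========================  =============================
    attribute                 band edges
    ========================  =============================
    rooting %                 5, 20, 30, 50, 70
    antioxidant activity %    5, 20, 40, 65, 85
    TPC mg GAE/100 g          20, 50, 80, 100, 150  (>150 scores 5)
    height at 18 months (m)   0.5, 1, 1.5, 2  (score 0 = not grown)
    growth rate 6-18 mo (%)   5, 10, 15, 20   (score 0 = not grown)
    ========================  =============================

    Fruit onset scores descend with the first fruiting season: season 2 (or
    earlier) -> 5, season 3 -> 4, season 4 -> 3, season 5 -> 2, season 6 or
    later -> 1, never fruited -> 0.  Molecular authentication is two-valued:
    a confirmed distinct genetic identity scores 5, otherwise 0.
    """
    scales = [
        AttributeScale(RubricAttribute.MOLECULAR_AUTH, ScaleKind.BOOLEAN),
        AttributeScale(
            RubricAttribute.ROOTING_PCT, ScaleKind.NUMERIC,
            _ascending_bands([5, 20, 30, 50, 70]),
        ),
        AttributeScale(
            RubricAttribute.ANTIOXIDANT_AA_PCT, ScaleKind.NUMERIC,
            _ascending_bands([5, 20, 40, 65, 85]),
        ),
        AttributeScale(
            RubricAttribute.TPC_MG_GAE_100G, ScaleKind.NUMERIC,
            _ascending_bands([20, 50, 80, 100, 150]),
        ),
        AttributeScale(
            RubricAttribute.TREE_HEIGHT_18M_M, ScaleKind.NUMERIC,
            # score 0 is reserved for "not established"; any measured height
            # below 0.5 m scores 1
            (Band(1, lower=None, upper=0.5, upper_closed=False),
             Band(2, lower=0.5, upper=1.0),
             Band(3, lower=1.0, upper=1.5, lower_closed=False),
             Band(4, lower=1.5, upper=2.0, lower_closed=False),
             Band(5, lower=2.0, upper=None, lower_closed=False)),
        ),
        AttributeScale(
            RubricAttribute.GROWTH_RATE_PCT, ScaleKind.NUMERIC,
            (Band(1, lower=None, upper=5, upper_closed=False),
             Band(2, lower=5, upper=10),
             Band(3, lower=10, upper=15, lower_closed=False),
             Band(4, lower=15, upper=20, lower_closed=False),
             Band(5, lower=20, upper=None, lower_closed=False)),
        ),
        AttributeScale(
            RubricAttribute.FRUIT_ONSET, ScaleKind.SEASON,
            (Band(5, lower=None, upper=2),
             Band(4, lower=3, upper=3),
             Band(3, lower=4, upper=4),
             Band(2, lower=5, upper=5),
             Band(1, lower=6, upper=None)),
        ),
    ]
    return scales


def score_value(scale: AttributeScale, raw) -> int:
    """Score one raw value against one scale.

    ``None`` scores 0 (no data).  Booleans are admissible only on the
    molecular-authentication scale and numbers only on the others; negative
    numbers are rejected.
    """
    if raw is None:
        return 0
    if scale.kind is ScaleKind.BOOLEAN:
        if not isinstance(raw, bool):
            raise ScaleTypeError(
                f"{scale.attribute_id.value} expects a boolean, got {type(raw).__name__}"
            )
        return scale.max_score if raw else 0
    if isinstance(raw, bool):
        raise ScaleTypeError(
            f"{scale.attribute_id.value} expects a number, got a boolean"
        )
    try:
        x = float(raw)
    except (TypeError, ValueError):
        raise ScaleTypeError(
            f"{scale.attribute_id.value} expects a number, got {type(raw).__name__}"
        ) from None
    if math.isnan(x):
        return 0
    if x < 0:
        raise ValidationError(
            f"{scale.attribute_id.value}: negative value {x} is not scorable"
        )
    if scale.kind is ScaleKind.SEASON:
        if x != int(x) or x < 1:
            raise ValidationError(
                f"{scale.attribute_id.value}: season index must be a positive "
                f"integer, got {raw!r}"
            )
        x = int(x)
    return scale.band_for(x).score


@dataclass
class GenotypeMeasurements:
    """Raw measurements for one wild-collected genotype (accession).

    Accessions follow the International Plant Exchange Network style and may
    contain commas (e.g. ``GR-1-BBGK-19,191``); they are stored verbatim.
    Any field may be None when the genotype was not assessed for it.
    """

    accession: str
    rooting_pct: Optional[float] = None
    aa_rsa_pct: Optional[float] = None
    tpc: Optional[float] = None                # mg GAE / 100 g
    height_18m: Optional[float] = None         # metres
    growth_rate_6_18: Optional[float] = None   # % height increase, may exceed 100
    fruit_onset_season: Optional[int] = None   # growing season index, >= 1
    genetically_distinct: Optional[bool] = None

    def __post_init__(self) -> None:
        self.accession = str(self.accession).strip()
        if not self.accession:
            raise ValidationError("accession must be a non-empty string")
        for name in ("rooting_pct", "aa_rsa_pct"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValidationError(
                    f"{self.accession}: {name}={v} outside [0, 100]"
                )
        if self.tpc is not None and self.tpc < 0:
            raise ValidationError(f"{self.accession}: tpc={self.tpc} negative")
        if self.height_18m is not None and self.height_18m < 0:
            raise ValidationError(
                f"{self.accession}: height_18m={self.height_18m} negative"
            )
        if self.fruit_onset_season is not None:
            s = self.fruit_onset_season
            if int(s) != s or s < 1:
                raise ValidationError(
                    f"{self.accession}: fruit_onset_season={s} must be a "
                    "positive integer"
                )
            self.fruit_onset_season = int(s)


@dataclass
class SpeciesRawProfile:
    """All evaluated genotypes of one species plus the aggregation rule."""

    species_name: str
    genotypes: list[GenotypeMeasurements] = field(default_factory=list)
    aggregation: str = "mean_across_genotypes"

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValidationError(
                f"{self.species_name}: profile needs at least one genotype"
            )
        if self.aggregation != "mean_across_genotypes":
            raise ValidationError(
                f"unknown aggregation {self.aggregation!r}"
            )


@dataclass(frozen=True)
class MultifacetedScoreCard:
    """Per-species result: seven 0-5 scores, total out of 35, percentage."""

    species_name: str
    scores: Mapping[RubricAttribute, int]
    total: int
    max_total: int
    percentage: float

    @classmethod
    def from_scores(cls, species_name: str,
                    scores: Mapping[RubricAttribute, int]) -> "MultifacetedScoreCard":
        if len(scores) != len(RubricAttribute):
            missing = set(RubricAttribute) - set(scores)
            raise ValidationError(
                f"{species_name}: missing scores for "
                f"{sorted(a.value for a in missing)}"
            )
        total = int(sum(scores.values()))
        return cls(species_name=species_name, scores=dict(scores), total=total,
                   max_total=MAX_TOTAL,
                   percentage=percent_of_max(total, MAX_TOTAL))


# measurement field backing each rubric attribute
_ATTRIBUTE_FIELDS = {
    RubricAttribute.MOLECULAR_AUTH: "genetically_distinct",
    RubricAttribute.ROOTING_PCT: "rooting_pct",
    RubricAttribute.ANTIOXIDANT_AA_PCT: "aa_rsa_pct",
    RubricAttribute.TPC_MG_GAE_100G: "tpc",
    RubricAttribute.TREE_HEIGHT_18M_M: "height_18m",
    RubricAttribute.GROWTH_RATE_PCT: "growth_rate_6_18",
    RubricAttribute.FRUIT_ONSET: "fruit_onset_season",
}


def aggregate_profile(profile: SpeciesRawProfile) -> dict[RubricAttribute, object]:
    """Collapse a profile's genotypes to one raw value per attribute.

    Quantitative measurements are averaged over the genotypes that have data;
    fruit onset takes the earliest observed season; molecular authentication
    is true only if every assessed genotype proved genetically distinct.
    Attributes with no data at all aggregate to None.
    """
    out: dict[RubricAttribute, object] = {}
    for attr, fname in _ATTRIBUTE_FIELDS.items():
        values = [getattr(g, fname) for g in profile.genotypes
                  if getattr(g, fname) is not None]
        if not values:
            out[attr] = None
        elif attr is RubricAttribute.MOLECULAR_AUTH:
            out[attr] = all(values)
        elif attr is RubricAttribute.FRUIT_ONSET:
            out[attr] = min(values)
        else:
            out[attr] = float(sum(values)) / len(values)
    return out


def score_species(profile: SpeciesRawProfile,
                  scales: Optional[Iterable[AttributeScale]] = None) -> MultifacetedScoreCard:
    """Aggregate a species profile across genotypes and score every attribute."""
    if scales is None:
        scales = default_scales()
    by_attr = {s.attribute_id: s for s in scales}
    missing = set(RubricAttribute) - set(by_attr)
    if missing:
        raise ValidationError(
            f"scales incomplete, missing {sorted(a.value for a in missing)}"
        )
    raw = aggregate_profile(profile)
    scores = {attr: score_value(by_attr[attr], raw[attr]) for attr in RubricAttribute}
    return MultifacetedScoreCard.from_scores(profile.species_name, scores)


def compare_species(cards: Sequence[MultifacetedScoreCard]) -> pd.DataFrame:
    """Ranked comparison table: one row per species, highest percentage first,
    ties broken alphabetically by species name."""
    if not cards:
        raise ValidationError("compare_species needs at least one score card")
    names = [c.species_name for c in cards]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate species names: {dupes}")
    rows = []
    for c in cards:
        row = {"species": c.species_name}
        row.update({a.value: c.scores[a] for a in RubricAttribute})
        row["total"] = c.total
        row["max_total"] = c.max_total
        row["percentage"] = c.percentage
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["percentage", "species"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df
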