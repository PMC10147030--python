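"""Seeded generators for trial datasets and species measurement profiles.

The trial generator emulates the orchard pilot design the analysis expects:
replicate young trees per genotype x fertilization treatment measured at
fixed months after planting.  Heights follow a two-level Gaussian model,

    height(rep, t) = baseline + b_rep + slope[treatment] * t + e(rep, t),

with a per-replicate random intercept b_rep ~ N(0, replicate_sd), i.i.d.
measurement error e ~ N(0, measurement_sd), and truncation at zero.
Fruiting events are drawn per replicate and growing season from a
per-treatment hazard; once a replicate fruits it stays fruiting.

Random streams are split per genotype via ``numpy.random.SeedSequence``
spawning, so enlarging ``n_genotypes`` never perturbs the trajectories of
the genotypes already generated.

The profile generator draws raw rubric measurements (rooting %, antioxidant
activity, total phenolic content, height, growth rate, fruit onset) from
truncated normal distributions; given target scores it centres each
distribution inside the corresponding rubric band, so the noise-free limit
recovers the targets exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .rubric import (
    AttributeScale,
    GenotypeMeasurements,
    RubricAttribute,
    SpeciesRawProfile,
    default_scales,
)
from .trial import DEFAULT_TREATMENTS, TrialDataset, season_of_month

__all__ = [
    "TrialSimConfig",
    "ProfileSimConfig",
    "simulate_trial",
    "simulate_profiles",
    "trial_preset",
    "TRIAL_PRESETS",
    "case_study_fixtures",
]


@dataclass(frozen=True)
class TrialSimConfig:
    """Parameters of the synthetic orchard trial.

    Defaults mirror the design the analysis modules expect: three
    fertilization regimes, five replicate plants per treatment, and
    measurements every three months over the first 18 months.
    ``treatment_effect_cm_per_month`` is added to the growth slope of every
    non-control treatment on top of ``monthly_growth_cm``.
    """

    species: str = "Synthetic species"
    n_genotypes: int = 1
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    n_replicates: int = 5
    timepoints_months: tuple[float, ...] = (3.0, 6.0, 9.0, 12.0, 15.0, 18.0)
    baseline_height_cm: float = 50.0
    monthly_growth_cm: Mapping[str, float] = field(
        default_factory=lambda: {t: 8.0 for t in DEFAULT_TREATMENTS})
    treatment_effect_cm_per_month: float = 0.0
    replicate_sd_cm: float = 5.0
    measurement_sd_cm: float = 5.0
    fruit_onset_hazard: Mapping[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in DEFAULT_TREATMENTS})
    first_fruiting_season: int = 2  # juvenile plants cannot fruit earlier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 1 or self.n_replicates < 1:
            raise ValidationError("n_genotypes and n_replicates must be >= 1")
        if len(self.treatments) < 1:
            raise ValidationError("at least one treatment required")
        tp = tuple(float(t) for t in self.timepoints_months)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValidationError("timepoints_months must be strictly increasing")
        if any(t < 0 for t in tp):
            raise ValidationError("timepoints_months must be >= 0")
        if self.replicate_sd_cm < 0 or self.measurement_sd_cm < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.baseline_height_cm < 0:
            raise ValidationError("baseline_height_cm must be >= 0")
        if self.first_fruiting_season < 1:
            raise ValidationError("first_fruiting_season must be >= 1")
        for t in self.treatments:
            if t not in self.monthly_growth_cm:
                raise ValidationError(f"monthly_growth_cm missing treatment {t!r}")
            h = self.fruit_onset_hazard.get(t, 0.0)
            if not 0.0 <= h <= 1.0:
                raise ValidationError(
                    f"fruit_onset_hazard[{t!r}]={h} outside [0, 1]")


def _slope(config: TrialSimConfig, treatment: str) -> float:
    s = float(config.monthly_growth_cm[treatment])
    if treatment != "control":
        s += config.treatment_effect_cm_per_month
    return s


def simulate_trial(config: TrialSimConfig) -> TrialDataset:
    """Draw one trial dataset; byte-identical for identical (config, seed)."""
    root = np.random.SeedSequence(int(config.seed))
    children = root.spawn(config.n_genotypes)
    timepoints = tuple(float(t) for t in config.timepoints_months)
    seasons = sorted({s for s in (season_of_month(t) for t in timepoints)
                      if s >= config.first_fruiting_season})
    records = []
    for g, child in enumerate(children):
        rng = np.random.default_rng(child)
        accession = f"SYN-{g + 1:03d}"
        for treatment in config.treatments:
            slope = _slope(config, treatment)
            hazard = float(config.fruit_onset_hazard.get(treatment, 0.0))
            for rep in range(1, config.n_replicates + 1):
                intercept = rng.normal(0.0, config.replicate_sd_cm)
                noise = rng.normal(0.0, config.measurement_sd_cm,
                                   size=len(timepoints))
                onset = None
                for s in seasons:
                    if rng.random() < hazard:
                        onset = s
                        break
                for t, eps in zip(timepoints, noise):
                    h = config.baseline_height_cm + intercept + slope * t + eps
                    records.append({
                        "species": config.species,
                        "accession": accession,
                        "treatment": treatment,
                        "replicate": rep,
                        "months_after_planting": t,
                        "height_cm": max(h, 0.0),
                        "fruiting": (onset is not None
                                     and season_of_month(t) >= onset),
                    })
    return TrialDataset.from_records(records)


# Presets anchored to published juvenile growth of the corresponding genera
# under Greek orchard conditions: dogrose reaching 2.3-3.6 m by 18 months
# with ~20-45% height increase from 6-18 months and fruit from season 2;
# cornelian cherry 0.8-1.25 m with no fruit within the trial; elder up to
# ~2.45 m.  Baselines are high because cutting-raised plants put on most of
# their height in the establishment season before the 6-month mark.
TRIAL_PRESETS: dict[str, TrialSimConfig] = {
    "rosa-like": TrialSimConfig(
        species="Rosa-like shrub", n_genotypes=4,
        baseline_height_cm=170.0,
        monthly_growth_cm={"control": 5.5, "conventional": 6.5, "organic": 7.5},
        replicate_sd_cm=12.0, measurement_sd_cm=6.0,
        fruit_onset_hazard={t: 0.7 for t in DEFAULT_TREATMENTS},
    ),
    "cornus-like": TrialSimConfig(
        species="Cornus-like tree", n_genotypes=1,
        baseline_height_cm=65.0,
        monthly_growth_cm={"control": 1.4, "conventional": 3.3, "organic": 2.4},
        replicate_sd_cm=6.0, measurement_sd_cm=4.0,
        fruit_onset_hazard={t: 0.0 for t in DEFAULT_TREATMENTS},
    ),
    "sambucus-like": TrialSimConfig(
        species="Sambucus-like shrub", n_genotypes=9,
        baseline_height_cm=125.0,
        monthly_growth_cm={"control": 4.5, "conventional": 6.8, "organic": 5.8},
        replicate_sd_cm=10.0, measurement_sd_cm=6.0,
        fruit_onset_hazard={t: 0.7 for t in DEFAULT_TREATMENTS},
    ),
}


def trial_preset(name: str, seed: Optional[int] = None) -> TrialSimConfig:
    try:
        config = TRIAL_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(TRIAL_PRESETS)}"
        ) from None
    return replace(config, seed=seed) if seed is not None else config


# ---------------------------------------------------------------------------
# species profile generation

# sampling domain per numeric attribute: (hard lower, hard upper, band cap)
# — the cap bounds the centre of an open-ended top band
_DOMAINS: dict[RubricAttribute, tuple[float, float, float]] = {
    RubricAttribute.ROOTING_PCT: (0.0, 100.0, 100.0),
    RubricAttribute.ANTIOXIDANT_AA_PCT: (0.0, 100.0, 100.0),
    RubricAttribute.TPC_MG_GAE_100G: (0.0, np.inf, 200.0),
    RubricAttribute.TREE_HEIGHT_18M_M: (0.0, np.inf, 3.0),
    RubricAttribute.GROWTH_RATE_PCT: (0.0, np.inf, 30.0),
}

_ONSET_FOR_SCORE = {5: 2, 4: 3, 3: 4, 2: 5, 1: 6}


def band_center(scale: AttributeScale, score: int) -> float:
    """Midpoint of the band carrying ``score``, with open ends capped at the
    attribute's plausible-range limit."""
    _, _, cap = _DOMAINS[scale.attribute_id]
    band = scale.band_for_score(score)
    lo = 0.0 if band.lower is None else float(band.lower)
    hi = cap if band.upper is None else float(band.upper)
    if hi < lo:
        raise ValidationError(
            f"{scale.attribute_id.value}: band for score {score} is empty "
            "after capping"
        )
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class ProfileSimConfig:
    """Parameters of the synthetic species-profile generator.

    ``attribute_means``/``attribute_sds`` give the sampling distribution per
    numeric attribute; ``target_scores`` (per attribute, 0-5) overrides the
    means with rubric band centres.  ``fruit_onset_season`` and
    ``genetically_distinct`` set the categorical attributes directly unless
    targeted.  ``missing`` lists attributes to leave unmeasured.
    """

    species: str = "Synthetic species"
    n_genotypes: int = 3
    attribute_means: Mapping[RubricAttribute, float] = field(
        default_factory=lambda: {
            RubricAttribute.ROOTING_PCT: 60.0,
            RubricAttribute.ANTIOXIDANT_AA_PCT: 75.0,
            RubricAttribute.TPC_MG_GAE_100G: 120.0,
            RubricAttribute.TREE_HEIGHT_18M_M: 1.8,
            RubricAttribute.GROWTH_RATE_PCT: 18.0,
        })
    attribute_sds: Mapping[RubricAttribute, float] = field(
        default_factory=lambda: {
            RubricAttribute.ROOTING_PCT: 5.0,
            RubricAttribute.ANTIOXIDANT_AA_PCT: 5.0,
            RubricAttribute.TPC_MG_GAE_100G: 10.0,
            RubricAttribute.TREE_HEIGHT_18M_M: 0.1,
            RubricAttribute.GROWTH_RATE_PCT: 1.0,
        })
    fruit_onset_season: Optional[int] = 2
    genetically_distinct: Optional[bool] = True
    target_scores: Optional[Mapping[RubricAttribute, int]] = None
    missing: tuple[RubricAttribute, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 1:
            raise ValidationError("n_genotypes must be >= 1")
        for attr, sd in self.attribute_sds.items():
            if sd < 0:
                raise ValidationError(f"{attr.value}: sd must be >= 0")


def _resolve_targets(config: ProfileSimConfig,
                     scales: Sequence[AttributeScale]):
    """Means / categorical values after applying any target scores."""
    means = dict(config.attribute_means)
    onset = config.fruit_onset_season
    distinct = config.genetically_distinct
    if config.target_scores:
        by_attr = {s.attribute_id: s for s in scales}
        for attr, score in config.target_scores.items():
            attr = RubricAttribute(attr)
            score = int(score)
            if attr in _DOMAINS:
                means[attr] = band_center(by_attr[attr], score)
            elif attr is RubricAttribute.FRUIT_ONSET:
                if score == 0:
                    onset = None
                elif score in _ONSET_FOR_SCORE:
                    onset = _ONSET_FOR_SCORE[score]
                else:
                    raise ValidationError(
                        f"fruit_onset target score {score} not attainable")
            elif attr is RubricAttribute.MOLECULAR_AUTH:
                if score not in (0, 5):
                    raise ValidationError(
                        f"molecular_auth target score must be 0 or 5, got {score}")
                distinct = score == 5
    return means, onset, distinct


def simulate_profiles(config: ProfileSimConfig,
                      scales: Optional[Sequence[AttributeScale]] = None
                      ) -> SpeciesRawProfile:
    """Draw one species profile with ``n_genotypes`` genotypes."""
    if scales is None:
        scales = default_scales()
    means, onset, distinct = _resolve_targets(config, scales)
    root = np.random.SeedSequence(int(config.seed))
    children = root.spawn(config.n_genotypes)
    field_of = {
        RubricAttribute.ROOTING_PCT: "rooting_pct",
        RubricAttribute.ANTIOXIDANT_AA_PCT: "aa_rsa_pct",
        RubricAttribute.TPC_MG_GAE_100G: "tpc",
        RubricAttribute.TREE_HEIGHT_18M_M: "height_18m",
        RubricAttribute.GROWTH_RATE_PCT: "growth_rate_6_18",
    }
    genotypes = []
    for g, child in enumerate(children):
        rng = np.random.default_rng(child)
        kwargs: dict = {"accession": f"SYN-{config.species[:3].upper()}-{g + 1:03d}"}
        for attr, fname in field_of.items():
            if attr in config.missing:
                kwargs[fname] = None
                continue
            lo, hi, _ = _DOMAINS[attr]
            sd = float(config.attribute_sds.get(attr, 0.0))
            value = float(rng.normal(float(means[attr]), sd)) if sd > 0 \
                else float(means[attr])
            kwargs[fname] = float(np.clip(value, lo, hi))
        kwargs["fruit_onset_season"] = (
            None if RubricAttribute.FRUIT_ONSET in config.missing else onset)
        kwargs["genetically_distinct"] = (
            None if RubricAttribute.MOLECULAR_AUTH in config.missing else distinct)
        genotypes.append(GenotypeMeasurements(**kwargs))
    return SpeciesRawProfile(species_name=config.species, genotypes=genotypes)


def case_study_fixtures() -> dict:
    """Machine-readable inputs from the published four-species case study
    (dogrose, elder, cornelian cherry, serviceberry): the 12-attribute
    feasibility score vectors, their totals, and the multifaceted-potential
    totals out of 35.  Used by the test and acceptance suites as known
    worked examples.
    """
    feasibility_scores = {
        "Rosa canina": {
            "existing_cultivations": 6, "threat_category": 1,
            "protection_status": 0, "ex_situ_conservation": 6,
            "distribution": 0, "commercial_products": 6,
            "known_propagation": 6, "vegetative_propagation_success": 6,
            "seed_germination_success": 6, "cultivation_needs": 6,
            "existing_cultivation_protocols": 6, "water_demand": 3,
        },
        "Sambucus nigra": {
            "existing_cultivations": 6, "threat_category": 1,
            "protection_status": 0, "ex_situ_conservation": 6,
            "distribution": 0, "commercial_products": 6,
            "known_propagation": 6, "vegetative_propagation_success": 6,
            "seed_germination_success": 5, "cultivation_needs": 6,
            "existing_cultivation_protocols": 6, "water_demand": 3,
        },
        "Cornus mas": {
            "existing_cultivations": 6, "threat_category": 1,
            "protection_status": 0, "ex_situ_conservation": 6,
            "distribution": 0, "commercial_products": 5,
            "known_propagation": 6, "vegetative_propagation_success": 6,
            "seed_germination_success": 0, "cultivation_needs": 6,
            "existing_cultivation_protocols": 6, "water_demand": 3,
        },
        "Amelanchier ovalis": {
            "existing_cultivations": 6, "threat_category": 0,
            "protection_status": 0, "ex_situ_conservation": 6,
            "distribution": 1, "commercial_products": 1,
            "known_propagation": 6, "vegetative_propagation_success": 6,
            "seed_germination_success": 0, "cultivation_needs": 6,
            "existing_cultivation_protocols": 5, "water_demand": 3,
        },
    }
    return {
        "feasibility_scores": feasibility_scores,
        "feasibility_totals": {
            "Rosa canina": 52, "Sambucus nigra": 51,
            "Cornus mas": 45, "Amelanchier ovalis": 40,
        },
        "multifaceted_totals": {
            "Amelanchier ovalis": 34, "Rosa canina": 33,
            "Sambucus nigra": 32, "Cornus mas": 26,
        },
        "scales": default_scales(),
    }
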