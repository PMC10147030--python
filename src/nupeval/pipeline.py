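"""End-to-end evaluation: raw measurements -> rubric score cards,
feasibility vectors -> readiness bands, trial data -> growth statistics,
combined into one versioned JSON report."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import io as nio
from .errors import ValidationError
from .feasibility import readiness_report, validate_scorecard
from .rubric import compare_species, score_species
from .trial import (
    TrialDataset,
    oneway_anova,
    summarize_trial,
    tukey_hsd,
)

logger = logging.getLogger("nupeval")


@dataclass
class RunConfig:
    alpha: float = 0.05
    rounding_decimals: int = 1
    rubric_path: Optional[str] = None
    band_table_path: Optional[str] = None
    planting_date: Optional[str] = None  # ISO-8601; month 0 of the trial
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha={self.alpha} outside (0, 1)")
        if self.rounding_decimals < 0:
            raise ValidationError("rounding decimals must be >= 0")


def run_full_evaluation(
    config: RunConfig,
    measurements_path: Optional[str] = None,
    feasibility_path: Optional[str] = None,
    trial_path: Optional[str] = None,
) -> dict:
    """Run every stage for which an input was given and write the combined
    report (JSON plus CSV summaries) under ``config.output_dir``.

    At least one input is required.  The report embeds checksums of the
    rubric and band table actually applied, and whether they were defaults.
    """
    if not any([measurements_path, feasibility_path, trial_path]):
        raise ValidationError(
            "no inputs: provide measurements, feasibility scores and/or "
            "trial data"
        )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    scales, rubric_default = nio.load_rubric(config.rubric_path)
    bands, bands_default = nio.load_band_table(config.band_table_path)
    if not rubric_default:
        logger.info("non-default rubric loaded from %s", config.rubric_path)
    if not bands_default:
        logger.info("non-default band table loaded from %s",
                    config.band_table_path)

    report: dict = {
        "schema": nio.REPORT_SCHEMA,
        "alpha": config.alpha,
        "rubric_checksum": nio.config_checksum(nio.scales_to_dict(scales)),
        "rubric_default": rubric_default,
        "band_table_checksum": nio.config_checksum(list(bands)),
        "band_table_default": bands_default,
    }

    if measurements_path:
        profiles = nio.read_measurements(measurements_path)
        cards = [score_species(p, scales) for p in profiles]
        table = compare_species(cards)
        table.to_csv(outdir / "multifaceted_scores.csv", index=False)
        report["multifaceted"] = table.to_dict(orient="records")
        logger.info("scored %d species profiles", len(cards))

    if feasibility_path:
        vectors = nio.read_feasibility_scores(feasibility_path)
        cards = [validate_scorecard(sp, scores) for sp, scores in vectors.items()]
        table = readiness_report(cards, bands)
        table.to_csv(outdir / "feasibility_readiness.csv", index=False)
        report["feasibility"] = table.to_dict(orient="records")
        logger.info("assessed feasibility for %d species", len(cards))

    if trial_path:
        dataset = nio.read_trial_csv(trial_path)
        report["trial"] = analyze_trial(dataset, alpha=config.alpha,
                                        outdir=outdir)

    nio.write_report(report, outdir / "report.json")
    return report


def analyze_trial(dataset: TrialDataset, alpha: float = 0.05,
                  outdir: Optional[Path] = None) -> dict:
    """Per-genotype trial statistics: growth summaries plus, for each
    measurement date with enough data, the treatment ANOVA and Tukey pairs.
    Dates where the design is too sparse for a test are skipped."""
    summaries = summarize_trial(dataset)
    result: dict = {"growth_summaries": [dataclasses.asdict(s)
                                         for s in summaries]}
    per_date = []
    for accession in dataset.accessions:
        sub = dataset.subset(accession)
        for month in sorted(sub["months_after_planting"].unique()):
            try:
                anova = oneway_anova(dataset, accession, month, alpha=alpha)
                tukey = tukey_hsd(dataset, accession, month, alpha=alpha)
            except ValidationError:
                continue
            per_date.append({
                "accession": accession,
                "months_after_planting": month,
                "F": anova.F,
                "df_between": anova.df_between,
                "df_within": anova.df_within,
                "p_value": anova.p_value,
                "degenerate": anova.degenerate,
                "any_pair_significant": tukey.any_significant,
                "tukey_pairs": [dataclasses.asdict(p) for p in tukey.pairs],
            })
    result["per_date_anova"] = per_date
    if outdir is not None:
        import pandas as pd

        pd.DataFrame(result["growth_summaries"]).to_csv(
            outdir / "growth_summaries.csv", index=False)
    return result
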