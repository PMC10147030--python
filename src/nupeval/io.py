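"""Reading and writing the package's file formats.

All tabular inputs are UTF-8 CSV with a mandatory header row, comma field
separator and "." decimal separator; accession identifiers may themselves
contain commas (IPEN style), so writers always quote and readers rely on
standard CSV quoting.  Rubric scales and readiness band tables can be
overridden from YAML.  Reports are JSON with an explicit schema tag and a
checksum of the rubric / band table actually used, so every reported number
is traceable to its configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .errors import ValidationError
from .feasibility import (
    BandRule,
    ReadinessBand,
    default_band_table,
)
from .rubric import (
    AttributeScale,
    Band,
    GenotypeMeasurements,
    RubricAttribute,
    ScaleKind,
    SpeciesRawProfile,
    default_scales,
)
from .trial import TrialDataset

REPORT_SCHEMA = "nupeval-report/1"

_MEASUREMENT_COLUMNS = {
    "species": None,
    "accession": None,
    "rooting_pct": "rooting_pct",
    "aa_rsa_pct": "aa_rsa_pct",
    "tpc_mgGAE_100g": "tpc",
    "height_18m_m": "height_18m",
    "growth_rate_pct": "growth_rate_6_18",
    "fruit_onset_season": "fruit_onset_season",
    "genetically_distinct": "genetically_distinct",
}


def _parse_bool(cell: str, where: str) -> Optional[bool]:
    s = str(cell).strip().lower()
    if s in ("", "nan", "none"):
        return None
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"{where}: cannot parse boolean {cell!r}")


def _parse_float(cell, where: str) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    s = str(cell).strip()
    if s == "" or s.lower() in ("nan", "none"):
        return None
    try:
        return float(s)
    except ValueError:
        raise ValidationError(f"{where}: non-numeric cell {cell!r}") from None


def read_measurements(path) -> list[SpeciesRawProfile]:
    """Parse a per-genotype measurement CSV into species profiles.

    Empty cells mean "not measured".  Validation failures name the file line
    (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")
    by_species: dict[str, list[GenotypeMeasurements]] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        where = f"{path.name}:{line}"
        species = row["species"].strip()
        if not species:
            raise ValidationError(f"{where}: empty species name")
        try:
            onset = _parse_float(row["fruit_onset_season"], where)
            g = GenotypeMeasurements(
                accession=row["accession"],
                rooting_pct=_parse_float(row["rooting_pct"], where),
                aa_rsa_pct=_parse_float(row["aa_rsa_pct"], where),
                tpc=_parse_float(row["tpc_mgGAE_100g"], where),
                height_18m=_parse_float(row["height_18m_m"], where),
                growth_rate_6_18=_parse_float(row["growth_rate_pct"], where),
                fruit_onset_season=None if onset is None else int(onset),
                genetically_distinct=_parse_bool(row["genetically_distinct"],
                                                 where),
            )
        except ValidationError as err:
            raise ValidationError(f"{where}: {err}") from None
        by_species.setdefault(species, []).append(g)
    return [SpeciesRawProfile(species_name=s, genotypes=gs)
            for s, gs in by_species.items()]


def write_measurements(profiles: Sequence[SpeciesRawProfile], path) -> None:
    rows = []
    for p in profiles:
        for g in p.genotypes:
            rows.append({
                "species": p.species_name,
                "accession": g.accession,
                "rooting_pct": g.rooting_pct,
                "aa_rsa_pct": g.aa_rsa_pct,
                "tpc_mgGAE_100g": g.tpc,
                "height_18m_m": g.height_18m,
                "growth_rate_pct": g.growth_rate_6_18,
                "fruit_onset_season": g.fruit_onset_season,
                "genetically_distinct": g.genetically_distinct,
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_trial_csv(path) -> TrialDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    try:
        return TrialDataset(df)
    except ValidationError as err:
        raise ValidationError(f"{Path(path).name}: {err}") from None


def write_trial_csv(dataset: TrialDataset, path) -> None:
    # %.17g keeps heights exactly round-trippable through text
    dataset.frame.to_csv(path, index=False, float_format="%.17g")


def read_feasibility_scores(path) -> dict[str, dict[str, int]]:
    """Feasibility score vectors from CSV (rows = attributes, columns =
    species) or from YAML mapping species -> attribute -> score."""
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        data = yaml.safe_load(path.read_text())
        out = {}
        for species, scores in data.items():
            out[species] = {
                k: (int(v["score"]) if isinstance(v, dict) else int(v))
                for k, v in scores.items()
            }
        return out
    df = pd.read_csv(path)
    first = df.columns[0]
    out = {}
    for species in df.columns[1:]:
        vec = {}
        for _, row in df.iterrows():
            attr = str(row[first]).strip()
            try:
                vec[attr] = int(row[species])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path.name}: non-integer score for {attr!r} / "
                    f"{species!r}: {row[species]!r}"
                ) from None
        out[str(species)] = vec
    return out


# ---------------------------------------------------------------------------
# rubric / band-table YAML


def scales_to_dict(scales: Sequence[AttributeScale]) -> dict:
    return {
        "scales": [
            {
                "attribute": s.attribute_id.value,
                "kind": s.kind.value,
                "max_score": s.max_score,
                "bands": [
                    {"score": b.score, "lower": b.lower, "upper": b.upper,
                     "lower_closed": b.lower_closed,
                     "upper_closed": b.upper_closed}
                    for b in s.bands
                ],
            }
            for s in scales
        ]
    }


def scales_from_dict(data: dict) -> list[AttributeScale]:
    scales = []
    for entry in data["scales"]:
        bands = tuple(
            Band(score=int(b["score"]),
                 lower=b.get("lower"), upper=b.get("upper"),
                 lower_closed=bool(b.get("lower_closed", True)),
                 upper_closed=bool(b.get("upper_closed", True)))
            for b in entry.get("bands", ())
        )
        scales.append(AttributeScale(
            attribute_id=RubricAttribute(entry["attribute"]),
            kind=ScaleKind(entry.get("kind", "numeric")),
            bands=bands,
            max_score=int(entry.get("max_score", 5)),
        ))
    return scales


def load_rubric(path=None) -> tuple[list[AttributeScale], bool]:
    """Rubric scales from YAML, or the defaults.  Returns (scales,
    is_default)."""
    if path is None:
        return default_scales(), True
    data = yaml.safe_load(Path(path).read_text())
    return scales_from_dict(data), False


def load_band_table(path=None) -> tuple[list[BandRule], bool]:
    if path is None:
        return default_band_table(), True
    data = yaml.safe_load(Path(path).read_text())
    rules = [
        BandRule(band=ReadinessBand(e["band"]), label=str(e["label"]),
                 lower_exclusive=e.get("lower_exclusive"),
                 upper_inclusive=e.get("upper_inclusive"))
        for e in data["bands"]
    ]
    return rules, False


def config_checksum(obj) -> str:
    """Stable sha256 of a JSON-serializable configuration object."""
    if obj and isinstance(obj, (list, tuple)) and dataclasses.is_dataclass(obj[0]):
        obj = [dataclasses.asdict(o) for o in obj]
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
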