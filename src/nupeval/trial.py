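"""Field-trial growth statistics for a completely randomized orchard design.

The design: wild-collected genotypes planted as replicate young trees under
several fertilization treatments (typically an unfertilized control, a
conventional N-rich regime, and an organic regime), with plant height (cm)
measured at intervals over the first growing seasons.  Analyses mirror
standard practice for such trials:

* per measurement date, a one-way (completely randomized) ANOVA of height by
  treatment, followed by Tukey's HSD pairwise comparison (Tukey-Kramer
  standard error when replicate counts are unequal);
* per growing season, a univariate mixed-design ("split-plot") repeated
  measures ANOVA with treatment as the between-subjects factor, measurement
  time as the within-subjects factor, and replicate plants as the subjects
  nested in treatment; no sphericity correction is applied;
* a juvenile growth summary per genotype x treatment: mean height at 6 and
  18 months after planting and the percent height increase between them,
  plus the first growing season with observed fruiting.

Heights are carried in centimetres throughout; conversion to metres happens
only when a summary feeds the potential-scoring rubric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "DEFAULT_TREATMENTS",
    "TrialDataset",
    "AnovaResult",
    "TukeyPair",
    "TukeyResult",
    "GrowthSummary",
    "growth_rate",
    "oneway_anova",
    "oneway_anova_groups",
    "tukey_hsd",
    "repeated_measures_anova",
    "summarize_trial",
    "season_of_month",
    "to_genotype_measurements",
]

DEFAULT_TREATMENTS = ("control", "conventional", "organic")

_COLUMNS = ["species", "accession", "treatment", "replicate",
            "months_after_planting", "height_cm", "fruiting"]


def season_of_month(months_after_planting: float) -> int:
    """Growing season index for a time point: months [0, 12) fall in season 1,
    [12, 24) in season 2, and so on."""
    if months_after_planting < 0:
        raise ValidationError("months_after_planting must be >= 0")
    return int(months_after_planting // 12) + 1


class TrialDataset:
    """Long-format trial measurements with one row per
    (accession, treatment, replicate, months_after_planting)."""

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        if "fruiting" not in df.columns:
            df["fruiting"] = False
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"trial table missing column(s) {missing}")
        df = df[_COLUMNS]
        df["replicate"] = df["replicate"].astype(int)
        df["months_after_planting"] = df["months_after_planting"].astype(float)
        df["height_cm"] = df["height_cm"].astype(float)
        df["fruiting"] = df["fruiting"].fillna(False).astype(bool)
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        if (df["months_after_planting"] < 0).any():
            raise ValidationError("months_after_planting must be >= 0")
        if (df["height_cm"] < 0).any():
            raise ValidationError("height_cm must be >= 0")
        key = ["accession", "treatment", "replicate", "months_after_planting"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup, key].iloc[0].tolist()
            raise ValidationError(
                f"duplicate measurement for (accession, treatment, replicate, "
                f"month) = {tuple(first)}"
            )
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "TrialDataset":
        return cls(pd.DataFrame(list(records)))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def accessions(self) -> list[str]:
        return sorted(self.frame["accession"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.frame["treatment"].unique())

    @property
    def months(self) -> list[float]:
        return sorted(self.frame["months_after_planting"].unique())

    def subset(self, accession: str,
               months_after_planting: Optional[float] = None) -> pd.DataFrame:
        df = self.frame[self.frame["accession"] == accession]
        if df.empty:
            raise ValidationError(f"no measurements for accession {accession!r}")
        if months_after_planting is not None:
            df = df[df["months_after_planting"] == float(months_after_planting)]
            if df.empty:
                raise ValidationError(
                    f"accession {accession!r}: no measurements at "
                    f"{months_after_planting} months"
                )
        return df


@dataclass(frozen=True)
class AnovaResult:
    """One F test from a sums-of-squares decomposition.

    ``degenerate`` marks a date where the within-group variance is zero, so
    the F ratio is undefined (F and p are NaN) rather than an exception.
    """

    factor: str
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    F: float
    p_value: float
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < self.alpha


@dataclass(frozen=True)
class TukeyPair:
    treatment_a: str
    treatment_b: str
    mean_diff: float          # mean(a) - mean(b), cm
    p_adjusted: float         # studentized-range adjusted p
    significant: bool


@dataclass(frozen=True)
class TukeyResult:
    accession: str
    months_after_planting: float
    alpha: float
    pairs: tuple[TukeyPair, ...]
    degenerate: bool = False

    @property
    def any_significant(self) -> bool:
        return any(p.significant for p in self.pairs)


def growth_rate(height_6m: float, height_18m: float) -> float:
    """Percent height increase from 6 to 18 months after planting.

    Negative rates (shrinkage/dieback) are passed through with their sign.
    """
    if height_6m <= 0:
        raise ValidationError(
            f"height at 6 months must be positive, got {height_6m}"
        )
    if height_18m < 0:
        raise ValidationError(
            f"height at 18 months must be >= 0, got {height_18m}"
        )
    return 100.0 * (height_18m - height_6m) / height_6m


def oneway_anova_groups(groups: Sequence[Sequence[float]],
                        factor: str = "treatment",
                        alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA decomposition on raw groups of observations."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("one-way ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValidationError("every group needs at least 2 observations")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_between = len(arrays) - 1
    df_within = len(all_values) - len(arrays)
    if ss_within <= 0.0:
        return AnovaResult(factor, df_between, df_within, ss_between,
                           ss_within, math.nan, math.nan, alpha,
                           degenerate=True)
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(factor, df_between, df_within, ss_between, ss_within,
                       float(f_stat), p, alpha)


def _groups_at_date(dataset: TrialDataset, accession: str,
                    months_after_planting: float) -> tuple[list[str], list[np.ndarray]]:
    df = dataset.subset(accession, months_after_planting)
    labels = sorted(df["treatment"].unique())
    if len(labels) < 2:
        raise ValidationError(
            f"accession {accession!r} at {months_after_planting} months: "
            "need >= 2 treatments"
        )
    groups = [df.loc[df["treatment"] == t, "height_cm"].to_numpy()
              for t in labels]
    if any(len(g) < 2 for g in groups):
        raise ValidationError(
            f"accession {accession!r} at {months_after_planting} months: "
            "every treatment needs >= 2 replicates"
        )
    return labels, groups


def oneway_anova(dataset: TrialDataset, accession: str,
                 months_after_planting: float,
                 alpha: float = 0.05) -> AnovaResult:
    """Height-by-treatment ANOVA for one genotype at one measurement date."""
    _, groups = _groups_at_date(dataset, accession, months_after_planting)
    return oneway_anova_groups(groups, factor="treatment", alpha=alpha)


def tukey_hsd(dataset: TrialDataset, accession: str,
              months_after_planting: float,
              alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD comparison of all treatment pairs at one date.

    Uses the studentized-range distribution with the Tukey-Kramer standard
    error, so unequal replicate counts (plant death) are handled.
    """
    labels, groups = _groups_at_date(dataset, accession, months_after_planting)
    pooled_var = oneway_anova_groups(groups, alpha=alpha)
    if pooled_var.degenerate:
        pairs = tuple(
            TukeyPair(labels[i], labels[j],
                      float(np.mean(groups[i]) - np.mean(groups[j])),
                      math.nan, False)
            for i in range(len(labels)) for j in range(i + 1, len(labels))
        )
        return TukeyResult(accession, months_after_planting, alpha, pairs,
                           degenerate=True)
    res = stats.tukey_hsd(*groups)
    pairs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p_adj = float(res.pvalue[i, j])
            pairs.append(TukeyPair(
                treatment_a=labels[i], treatment_b=labels[j],
                mean_diff=float(np.mean(groups[i]) - np.mean(groups[j])),
                p_adjusted=p_adj, significant=p_adj < alpha,
            ))
    return TukeyResult(accession, months_after_planting, alpha, tuple(pairs))


def repeated_measures_anova(dataset: TrialDataset, accession: str,
                            season: int, alpha: float = 0.05,
                            drop_incomplete: bool = False
                            ) -> dict[str, AnovaResult]:
    """Mixed-design repeated measures ANOVA for one genotype and season.

    Between-subjects factor: treatment.  Within-subjects factor: measurement
    time within the season.  Subjects: replicate plants nested in treatment.
    Returns the three univariate F tests keyed ``"treatment"``, ``"time"``
    and ``"interaction"``; each effect is tested against its own error
    stratum (subjects-within-treatment for the between factor, the residual
    for the within factor and the interaction).

    Requires a balanced replicate x time grid per treatment; with
    ``drop_incomplete=True`` replicates missing any time point are excluded
    listwise first.
    """
    df = dataset.subset(accession)
    df = df[df["months_after_planting"].map(season_of_month) == int(season)]
    if df.empty:
        raise ValidationError(
            f"accession {accession!r}: no measurements in season {season}"
        )
    times = sorted(df["months_after_planting"].unique())
    if len(times) < 2:
        raise ValidationError(
            f"accession {accession!r} season {season}: need >= 2 time points"
        )
    if drop_incomplete:
        counts = df.groupby(["treatment", "replicate"])["months_after_planting"].nunique()
        complete = counts[counts == len(times)].index
        df = df.set_index(["treatment", "replicate"]).loc[complete].reset_index()
    cube = df.pivot_table(index=["treatment", "replicate"],
                          columns="months_after_planting",
                          values="height_cm", aggfunc="first")
    if cube.isna().any().any():
        raise ValidationError(
            f"accession {accession!r} season {season}: unbalanced replicate x "
            "time grid; exclude incomplete replicates listwise "
            "(drop_incomplete=True)"
        )
    n_per = cube.groupby(level="treatment").size()
    if n_per.nunique() != 1 or (n_per < 2).any():
        raise ValidationError(
            f"accession {accession!r} season {season}: treatments must have "
            f"equal replicate counts >= 2, got {n_per.to_dict()}"
        )
    treatments = list(n_per.index)
    a, n, t = len(treatments), int(n_per.iloc[0]), len(times)
    if a < 2:
        raise ValidationError("repeated measures ANOVA needs >= 2 treatments")

    y = cube.to_numpy().reshape(a, n, t)           # treatment x subject x time
    grand = y.mean()
    subj_means = y.mean(axis=2)                    # a x n
    treat_means = y.mean(axis=(1, 2))              # a
    time_means = y.mean(axis=(0, 1))               # t
    cell_means = y.mean(axis=1)                    # a x t

    ss_total = float(((y - grand) ** 2).sum())
    ss_treat = float(n * t * ((treat_means - grand) ** 2).sum())
    ss_subj_within = float(t * ((subj_means - treat_means[:, None]) ** 2).sum())
    ss_time = float(a * n * ((time_means - grand) ** 2).sum())
    ss_inter = float(n * ((cell_means - treat_means[:, None]
                           - time_means[None, :] + grand) ** 2).sum())
    ss_resid = ss_total - ss_treat - ss_subj_within - ss_time - ss_inter
    ss_resid = max(ss_resid, 0.0)

    df_treat, df_subj = a - 1, a * (n - 1)
    df_time, df_inter = t - 1, (a - 1) * (t - 1)
    df_resid = a * (n - 1) * (t - 1)

    def _f(factor, ss_effect, df_effect, ss_err, df_err):
        if ss_err <= 0.0:
            return AnovaResult(factor, df_effect, df_err, ss_effect, ss_err,
                               math.nan, math.nan, alpha, degenerate=True)
        f_stat = (ss_effect / df_effect) / (ss_err / df_err)
        p = float(stats.f.sf(f_stat, df_effect, df_err))
        return AnovaResult(factor, df_effect, df_err, ss_effect, ss_err,
                           float(f_stat), p, alpha)

    return {
        "treatment": _f("treatment", ss_treat, df_treat, ss_subj_within, df_subj),
        "time": _f("time", ss_time, df_time, ss_resid, df_resid),
        "interaction": _f("interaction", ss_inter, df_inter, ss_resid, df_resid),
    }


@dataclass(frozen=True)
class GrowthSummary:
    """Juvenile growth of one genotype under one treatment."""

    species: str
    accession: str
    treatment: str
    height_6m_cm: Optional[float]
    height_18m_cm: Optional[float]
    growth_rate_pct: Optional[float]
    fruit_onset_season: Optional[int]
    month_6_used: Optional[float] = None   # actual months matched to 6 / 18
    month_18_used: Optional[float] = None


def _nearest(available: Sequence[float], target: float,
             tolerance: float) -> Optional[float]:
    best = None
    for m in available:
        if abs(m - target) <= tolerance:
            if best is None or abs(m - target) < abs(best - target):
                best = m
    return best


def summarize_trial(dataset: TrialDataset,
                    target_months: tuple[float, float] = (6.0, 18.0),
                    tolerance: float = 1.0) -> list[GrowthSummary]:
    """Growth summaries per (accession, treatment).

    Heights at 6 and 18 months are treatment-level means across replicates at
    the measurement nearest each target (within ``tolerance`` months); the
    growth rate is computed on those means.  The actual months matched are
    recorded.  A missing time point yields None for the affected fields.
    """
    out: list[GrowthSummary] = []
    t6, t18 = target_months
    for (accession, treatment), grp in dataset.frame.groupby(
            ["accession", "treatment"], sort=True):
        months = [float(m) for m in sorted(grp["months_after_planting"].unique())]
        m6 = _nearest(months, t6, tolerance)
        m18 = _nearest(months, t18, tolerance)
        h6 = (float(grp.loc[grp["months_after_planting"] == m6, "height_cm"].mean())
              if m6 is not None else None)
        h18 = (float(grp.loc[grp["months_after_planting"] == m18, "height_cm"].mean())
               if m18 is not None else None)
        rate = None
        if h6 is not None and h18 is not None and h6 > 0:
            rate = growth_rate(h6, h18)
        fruited = grp[grp["fruiting"]]
        onset = (int(fruited["months_after_planting"].map(season_of_month).min())
                 if not fruited.empty else None)
        out.append(GrowthSummary(
            species=str(grp["species"].iloc[0]), accession=accession,
            treatment=treatment, height_6m_cm=h6, height_18m_cm=h18,
            growth_rate_pct=rate, fruit_onset_season=onset,
            month_6_used=m6, month_18_used=m18,
        ))
    return out


def best_treatment_table(summaries: Sequence[GrowthSummary]) -> pd.DataFrame:
    """Per genotype, the treatment with the greatest 18-month height."""
    rows = [s.__dict__ for s in summaries if s.height_18m_cm is not None]
    if not rows:
        raise ValidationError("no summaries with an 18-month height")
    df = pd.DataFrame(rows)
    idx = df.groupby("accession")["height_18m_cm"].idxmax()
    return df.loc[idx].reset_index(drop=True)


def to_genotype_measurements(summaries: Sequence[GrowthSummary]):
    """Rubric inputs per genotype: 18-month height (m), growth rate (%), and
    fruit-onset season from the best-performing treatment (greatest 18-month
    height; earliest onset across treatments)."""
    from .rubric import GenotypeMeasurements

    best = best_treatment_table(summaries)
    by_acc = {}
    for s in summaries:
        if s.fruit_onset_season is not None:
            prev = by_acc.get(s.accession)
            by_acc[s.accession] = (s.fruit_onset_season if prev is None
                                   else min(prev, s.fruit_onset_season))
    out = []
    for _, row in best.iterrows():
        out.append(GenotypeMeasurements(
            accession=row["accession"],
            height_18m=row["height_18m_cm"] / 100.0,
            growth_rate_6_18=row["growth_rate_pct"],
            fruit_onset_season=by_acc.get(row["accession"]),
        ))
    return out
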