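"""Trial statistics: growth rate, one-way ANOVA, Tukey HSD, repeated
measures decomposition, growth summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nupeval import (
    TrialDataset,
    ValidationError,
    growth_rate,
    oneway_anova,
    oneway_anova_groups,
    repeated_measures_anova,
    summarize_trial,
    tukey_hsd,
)
from nupeval.trial import season_of_month, to_genotype_measurements


def _dataset(groups: dict[str, list[float]], month: float = 18.0,
             accession: str = "G-1") -> TrialDataset:
    records = []
    for treatment, heights in groups.items():
        for rep, h in enumerate(heights, start=1):
            records.append(dict(species="sp", accession=accession,
                                treatment=treatment, replicate=rep,
                                months_after_planting=month, height_cm=h))
    return TrialDataset.from_records(records)


class TestGrowthRate:
    @pytest.mark.parametrize("h6,h18,expected", [
        (100, 120, 20.0), (150, 150, 0.0), (80, 60, -25.0), (200, 290, 45.0),
    ])
    def test_examples(self, h6, h18, expected):
        assert growth_rate(h6, h18) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            growth_rate(0.0, 50.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=st.floats(min_value=0.1, max_value=1e4),
           r=st.floats(min_value=-100, max_value=500))
    def test_rate_recovers_relative_change(self, a, r):
        assert growth_rate(a, a * (1 + r / 100)) == pytest.approx(r, abs=1e-6)


class TestOnewayAnova:
    def test_hand_computed_instance(self):
        # SSB = 6, SSW = 6, df = (2, 6) -> F = (6/2)/(6/6) = 3
        res = oneway_anova_groups([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.ss_between == pytest.approx(6.0)
        assert res.ss_within == pytest.approx(6.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.F == pytest.approx(3.0)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(0, 5), 1, size=rng.integers(2, 8))
                      for _ in range(3)]
            res = oneway_anova_groups(groups)
            ref = stats.f_oneway(*groups)
            assert res.F == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ss_additivity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            groups = [rng.normal(0, 1, size=rng.integers(2, 9))
                      for _ in range(rng.integers(2, 5))]
            res = oneway_anova_groups(groups)
            allv = np.concatenate(groups)
            ss_total = ((allv - allv.mean()) ** 2).sum()
            assert res.ss_between + res.ss_within == pytest.approx(
                ss_total, rel=1e-9)

    def test_location_and_scale_invariance_of_f(self):
        groups = [[1.0, 2, 3], [2, 3, 4], [3, 4, 5]]
        base = oneway_anova_groups(groups)
        shifted = oneway_anova_groups([[v + 50 for v in g] for g in groups])
        scaled = oneway_anova_groups([[v * 3.5 for v in g] for g in groups])
        assert shifted.F == pytest.approx(base.F)
        assert shifted.p_value == pytest.approx(base.p_value)
        assert scaled.F == pytest.approx(base.F)

    def test_all_equal_is_degenerate_not_an_exception(self):
        res = oneway_anova_groups([[2.0, 2], [2, 2], [2, 2]])
        assert res.degenerate and math.isnan(res.F)

    def test_dataset_interface_filters_by_date(self):
        ds = _dataset({"control": [1, 2, 3], "conventional": [2, 3, 4],
                       "organic": [3, 4, 5]})
        res = oneway_anova(ds, "G-1", 18.0)
        assert res.F == pytest.approx(3.0)
        with pytest.raises(ValidationError):
            oneway_anova(ds, "G-1", 6.0)


class TestTukey:
    def test_identical_groups_nothing_significant(self):
        ds = _dataset({"control": [5, 6, 7, 6, 5],
                       "conventional": [6, 5, 7, 5, 6],
                       "organic": [5, 7, 6, 6, 5]})
        assert not tukey_hsd(ds, "G-1", 18.0).any_significant

    def test_far_group_flags_exactly_its_two_pairs(self):
        rng = np.random.default_rng(5)
        # two near-identical groups and one far group (shifted so all
        # heights are admissible; the F and Tukey tests are shift-invariant)
        ds = _dataset({
            "control": list(rng.normal(100.0, 0.1, 5)),
            "conventional": list(rng.normal(100.1, 0.1, 5)),
            "organic": list(rng.normal(110.0, 0.1, 5)),
        })
        res = tukey_hsd(ds, "G-1", 18.0)
        sig = {frozenset((p.treatment_a, p.treatment_b))
               for p in res.pairs if p.significant}
        assert sig == {frozenset(("control", "organic")),
                       frozenset(("conventional", "organic"))}

    def test_mean_diff_antisymmetric_significance_symmetric(self):
        ds = _dataset({"control": [1.0, 2, 3], "conventional": [4.0, 5, 6]})
        res = tukey_hsd(ds, "G-1", 18.0)
        (pair,) = res.pairs
        assert pair.mean_diff == pytest.approx(-3.0)
        # recompute with reversed labels via renaming
        ds2 = _dataset({"conventional": [1.0, 2, 3], "control": [4.0, 5, 6]})
        (pair2,) = tukey_hsd(ds2, "G-1", 18.0).pairs
        assert pair2.mean_diff == pytest.approx(3.0)
        assert pair.significant == pair2.significant

    def test_degenerate_groups_flagged(self):
        ds = _dataset({"control": [2.0, 2], "conventional": [2.0, 2]})
        res = tukey_hsd(ds, "G-1", 18.0)
        assert res.degenerate and not res.any_significant

    def test_against_statsmodels_on_random_instances(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(21)
        for trial in range(15):
            ns = rng.integers(3, 6, size=3)  # unequal n exercises Tukey-Kramer
            groups = {
                t: list(rng.normal(rng.uniform(50, 54), 1.0, n))
                for t, n in zip(("control", "conventional", "organic"), ns)
            }
            ds = _dataset(groups)
            res = tukey_hsd(ds, "G-1", 18.0)
            values = np.concatenate([groups[t] for t in sorted(groups)])
            labels = np.concatenate([[t] * len(groups[t])
                                     for t in sorted(groups)])
            ref = pairwise_tukeyhsd(values, labels, alpha=0.05)
            ref_pairs = {
                frozenset((row[0], row[1])): (float(row[2]), bool(row[-1]))
                for row in ref.summary().data[1:]
            }
            for p in res.pairs:
                diff_ref, sig_ref = ref_pairs[
                    frozenset((p.treatment_a, p.treatment_b))]
                # statsmodels' summary table rounds mean diffs to 4 decimals
                assert abs(abs(p.mean_diff) - abs(diff_ref)) < 1e-3
                assert p.significant == sig_ref


def _rm_dataset(rng, slopes, n=5, times=(3.0, 6.0, 9.0),
                rep_sd=3.0, meas_sd=2.0):
    records = []
    for treatment, slope in slopes.items():
        for rep in range(1, n + 1):
            b = rng.normal(0, rep_sd)
            for t in times:
                records.append(dict(
                    species="sp", accession="G-1", treatment=treatment,
                    replicate=rep, months_after_planting=t,
                    height_cm=max(0.0, 50 + b + slope * t + rng.normal(0, meas_sd)),
                ))
    return TrialDataset.from_records(records)


def _brute_force_split_plot(data):
    """Independent split-plot SS oracle using plain Python loops over a
    nested dict data[treatment][replicate][time] = value."""
    treatments = sorted(data)
    reps = sorted(next(iter(data.values())))
    times = sorted(next(iter(next(iter(data.values())).values())))
    values = [data[a][s][t] for a in treatments for s in reps for t in times]
    grand = sum(values) / len(values)
    a, n, t = len(treatments), len(reps), len(times)

    def mean(vs):
        return sum(vs) / len(vs)

    treat_mean = {x: mean([data[x][s][u] for s in reps for u in times])
                  for x in treatments}
    time_mean = {u: mean([data[x][s][u] for x in treatments for s in reps])
                 for u in times}
    subj_mean = {(x, s): mean([data[x][s][u] for u in times])
                 for x in treatments for s in reps}
    cell_mean = {(x, u): mean([data[x][s][u] for s in reps])
                 for x in treatments for u in times}

    ss_treat = n * t * sum((treat_mean[x] - grand) ** 2 for x in treatments)
    ss_subj = t * sum((subj_mean[(x, s)] - treat_mean[x]) ** 2
                      for x in treatments for s in reps)
    ss_time = a * n * sum((time_mean[u] - grand) ** 2 for u in times)
    ss_inter = n * sum(
        (cell_mean[(x, u)] - treat_mean[x] - time_mean[u] + grand) ** 2
        for x in treatments for u in times)
    ss_total = sum((v - grand) ** 2 for v in values)
    ss_resid = ss_total - ss_treat - ss_subj - ss_time - ss_inter
    return ss_treat, ss_subj, ss_time, ss_inter, ss_resid


class TestRepeatedMeasures:
    def test_toy_grid_matches_brute_force_oracle(self):
        data = {
            "control": {1: {3.0: 10.0, 6.0: 14.0}, 2: {3.0: 12.0, 6.0: 17.0}},
            "organic": {1: {3.0: 11.0, 6.0: 19.0}, 2: {3.0: 13.0, 6.0: 22.0}},
        }
        records = [dict(species="sp", accession="G-1", treatment=a,
                        replicate=s, months_after_planting=t, height_cm=v)
                   for a, subs in data.items()
                   for s, obs in subs.items() for t, v in obs.items()]
        res = repeated_measures_anova(TrialDataset.from_records(records),
                                      "G-1", season=1)
        ss_treat, ss_subj, ss_time, ss_inter, ss_resid = \
            _brute_force_split_plot(data)
        assert res["treatment"].ss_between == pytest.approx(ss_treat)
        assert res["treatment"].ss_within == pytest.approx(ss_subj)
        assert res["time"].ss_between == pytest.approx(ss_time)
        assert res["interaction"].ss_between == pytest.approx(ss_inter)
        assert res["time"].ss_within == pytest.approx(ss_resid)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(17)
        ds = _rm_dataset(rng, {"control": 6.0, "conventional": 9.0,
                               "organic": 7.0})
        res = repeated_measures_anova(ds, "G-1", season=1)
        df = ds.frame.copy()
        df["subject"] = df["treatment"] + ":" + df["replicate"].astype(str)
        ref = pg.mixed_anova(data=df, dv="height_cm",
                             within="months_after_planting",
                             subject="subject", between="treatment")
        ref = ref.set_index("Source")
        assert res["treatment"].F == pytest.approx(
            float(ref.loc["treatment", "F"]), rel=1e-6)
        assert res["time"].F == pytest.approx(
            float(ref.loc["months_after_planting", "F"]), rel=1e-6)
        assert res["interaction"].F == pytest.approx(
            float(ref.loc["Interaction", "F"]), rel=1e-6)

    def test_duplicating_every_replicate_doubles_each_ss_stratum(self):
        # cloning every replicate leaves all means unchanged, so every sum
        # of squares doubles exactly (F itself shifts with the error df)
        rng = np.random.default_rng(23)
        ds = _rm_dataset(rng, {"control": 6.0, "organic": 8.0}, n=3)
        base = repeated_measures_anova(ds, "G-1", season=1)
        dup = ds.frame.copy()
        clone = dup.copy()
        clone["replicate"] = clone["replicate"] + clone["replicate"].max()
        doubled = TrialDataset(pd.concat([dup, clone], ignore_index=True))
        res = repeated_measures_anova(doubled, "G-1", season=1)
        for factor in ("treatment", "time", "interaction"):
            assert res[factor].ss_between == pytest.approx(
                2 * base[factor].ss_between)
            assert res[factor].ss_within == pytest.approx(
                2 * base[factor].ss_within)

    def test_location_and_scale_invariance(self):
        rng = np.random.default_rng(37)
        ds = _rm_dataset(rng, {"control": 6.0, "organic": 8.0}, n=4)
        base = repeated_measures_anova(ds, "G-1", season=1)
        shifted = ds.frame.copy()
        shifted["height_cm"] = shifted["height_cm"] * 2.5 + 40
        res = repeated_measures_anova(TrialDataset(shifted), "G-1", season=1)
        for factor in ("treatment", "time", "interaction"):
            assert res[factor].F == pytest.approx(base[factor].F)
            assert res[factor].p_value == pytest.approx(base[factor].p_value)

    def test_unbalanced_grid_instructs_listwise_exclusion(self):
        rng = np.random.default_rng(29)
        ds = _rm_dataset(rng, {"control": 6.0, "organic": 8.0}, n=3)
        frame = ds.frame.drop(index=0)  # remove one measurement
        broken = TrialDataset(frame)
        with pytest.raises(ValidationError, match="listwise"):
            repeated_measures_anova(broken, "G-1", season=1)

    def test_null_treatment_strong_time_trend(self):
        # no treatment effect + shared time trend: time F far above 1,
        # treatment F near its null expectation (median over replications)
        f_time, f_treat = [], []
        rng = np.random.default_rng(31)
        for _ in range(60):
            ds = _rm_dataset(rng, {"control": 8.0, "conventional": 8.0,
                                   "organic": 8.0})
            res = repeated_measures_anova(ds, "G-1", season=1)
            f_time.append(res["time"].F)
            f_treat.append(res["treatment"].F)
        assert np.median(f_time) > 50
        assert abs(np.median(f_treat) - 1) < 0.5


class TestSummaries:
    def test_growth_summary_on_treatment_means(self):
        records = []
        for rep, (h6, h18) in enumerate([(195, 285), (205, 295)], start=1):
            for m, h in ((6.0, h6), (18.0, h18)):
                records.append(dict(species="sp", accession="G-1",
                                    treatment="control", replicate=rep,
                                    months_after_planting=m, height_cm=h,
                                    fruiting=m == 18.0))
        (summary,) = summarize_trial(TrialDataset.from_records(records))
        assert summary.height_6m_cm == pytest.approx(200.0)
        assert summary.height_18m_cm == pytest.approx(290.0)
        assert summary.growth_rate_pct == pytest.approx(45.0)
        assert summary.fruit_onset_season == 2

    def test_nearest_month_within_tolerance_recorded(self):
        records = [dict(species="sp", accession="G-1", treatment="control",
                        replicate=1, months_after_planting=m, height_cm=h)
                   for m, h in ((6.5, 100.0), (18.0, 200.0))]
        (summary,) = summarize_trial(TrialDataset.from_records(records))
        assert summary.month_6_used == 6.5
        assert summary.growth_rate_pct == pytest.approx(100.0)

    def test_missing_timepoint_gives_missing_cells(self):
        records = [dict(species="sp", accession="G-1", treatment="control",
                        replicate=1, months_after_planting=m, height_cm=100.0)
                   for m in (3.0, 18.0)]
        (summary,) = summarize_trial(TrialDataset.from_records(records))
        assert summary.height_6m_cm is None
        assert summary.growth_rate_pct is None

    def test_never_fruiting_has_no_onset(self):
        records = [dict(species="sp", accession="G-1", treatment="control",
                        replicate=1, months_after_planting=m, height_cm=100.0)
                   for m in (6.0, 18.0)]
        (summary,) = summarize_trial(TrialDataset.from_records(records))
        assert summary.fruit_onset_season is None

    def test_rubric_handoff_converts_units_and_picks_best_treatment(self):
        records = []
        for treatment, h18 in (("control", 150.0), ("organic", 210.0)):
            for m, h in ((6.0, 100.0), (18.0, h18)):
                records.append(dict(species="sp", accession="G-1",
                                    treatment=treatment, replicate=1,
                                    months_after_planting=m, height_cm=h))
        summaries = summarize_trial(TrialDataset.from_records(records))
        (g,) = to_genotype_measurements(summaries)
        assert g.height_18m == pytest.approx(2.1)  # organic wins, in metres
        assert g.growth_rate_6_18 == pytest.approx(110.0)

    def test_season_indexing(self):
        assert season_of_month(0.0) == 1
        assert season_of_month(11.9) == 1
        assert season_of_month(12.0) == 2
        assert season_of_month(18.0) == 2
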