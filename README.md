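# nupeval

Evaluation toolkit for wild fruit-tree and shrub germplasm — the neglected
and underutilized plant species (NUPs) that ethnobotany uses but commercial
agriculture ignores.  `nupeval` turns the raw measurements collected while
domesticating such germplasm (rooting trials, fruit phytochemistry, orchard
pilot trials) into the two standard prioritization indices used in
germplasm-evaluation studies, and provides the field-trial statistics that
feed them.

It is aimed at researchers running ex situ domestication trials of
wild-collected genotypes who need reproducible, auditable scoring rather
than spreadsheet arithmetic.

## What it computes

**Multifaceted potential** (`nupeval.rubric`).  Seven attributes across four
evaluation axes, each scored 0–5 on a fixed ordinal threshold rubric:

| attribute | raw measurement | band edges (score 1 … 5) |
|---|---|---|
| molecular authentication | genetic identity established | 0 or 5 only |
| asexual propagation | % rooting of cuttings | 5, 20, 30, 50, 70 |
| antioxidant activity | % radical scavenging (%RSA) | 5, 20, 40, 65, 85 |
| total phenolic content | mg GAE/100 g | 20, 50, 80, 100, 150 |
| tree establishment | height (m) at 18 months | 0.5, 1, 1.5, 2 |
| juvenile growth rate | % height increase, 6–18 months | 5, 10, 15, 20 |
| fruit-production onset | first fruiting season | season 2 → 5 … season ≥ 6 → 1 |

A band printed "5–20" is closed at both ends; a ">"-prefixed bound is open,
so the bands tile the axis as [5, 20], (20, 30], (30, 50], …  Raw values are
averaged across a species' genotypes (earliest season for fruit onset; all
assessed genotypes must be distinct for authentication), scored, summed to a
total T out of 35 and reported as 100·T/35 %, rounded to one decimal with
ties away from zero.

**Feasibility for sustainable exploitation** (`nupeval.feasibility`).
Twelve attributes (existing cultivations, threat category, protection
status, ex situ conservation, distribution, commercial products, propagation
and cultivation knowledge, germination and rooting success, water demand),
each restricted to a printed admissible score set with maximum 6.  The sum
out of 72, as a percentage, maps onto a readiness timescale: > 70 % "already
achieved", > 55–70 % "achievable in short-term", ≤ 55 % unclassified by the
framework.  Score semantics are the evaluator's input; the package enforces
the admissible sets, aggregates, and classifies.

**Trial statistics** (`nupeval.trial`).  For a completely randomized
orchard design (genotypes × fertilization treatments × replicate plants,
height measured over time): per-date one-way ANOVA across treatments with
Tukey HSD (Tukey–Kramer for unequal replicate counts), per-season
mixed-design repeated measures ANOVA (treatment between subjects, time
within), and growth summaries — treatment-mean heights at 6 and 18 months
and the juvenile growth rate 100·(h₁₈ − h₆)/h₆.

**Synthetic trials** (`nupeval.simulate`).  A seeded two-level Gaussian
generator (per-replicate random intercept + measurement error around a
per-treatment linear growth trend, per-season fruiting hazards) stands in
for unpublished replicate-level data, so every stage is testable end to end.

## Worked example

Simulate a dogrose-like trial, analyze it, and score species profiles:

```
$ nupeval simulate --preset rosa-like --seed 42 --out trial.csv
wrote 360 measurements to trial.csv
$ nupeval trial-analyze --data trial.csv --out results
analyzed 4 genotypes -> results
```

`results/growth_summaries.csv` then holds rows such as (genotype SYN-001):

```
treatment     height_6m_cm  height_18m_cm  growth_rate_pct  fruit_onset_season
control       207.2         273.6          32.0             2
conventional  204.1         289.0          41.5             2
organic       210.2         300.5          43.0             2
```

i.e. plants around 2.7–3.0 m at 18 months with a 32–43 % height increase
from month 6 and first fruit in the second season.  The per-date ANOVA at
18 months for this genotype gives F = 4.48 (df 2, 12), p = 0.035, with at
least one Tukey pair significant at α = 0.05.

Scoring a measurement table (`score-potential`):

```
$ nupeval score-potential --measurements measurements.csv --out potential.json
```

yields, for a Rosa canina profile with two genotypes (mean rooting 57.5 %,
%RSA 91, TPC 165 mg GAE/100 g, height 2.9 m, growth 33.6 %, onset season 2,
both genetically distinct):

```
molecular_auth 5, rooting 4, antioxidant 5, tpc 5, height 5, growth 5, onset 5
total 34 / 35  ->  97.1 %
```

Feasibility and readiness work the same way from a scores CSV
(`nupeval feasibility --scores scores.csv --out report.json`); a species
whose 12 scores sum to 52 reports 72.2 % and the "Already achieved (>70%)"
readiness band.

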