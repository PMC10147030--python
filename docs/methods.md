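# Methods

This note documents the models and numerical conventions behind `nupeval`,
the choices made where the underlying evaluation scheme leaves room, and
what the synthetic generators do and do not emulate.

## Ordinal rubric scoring

Each of the seven multifaceted-potential attributes is a step function from
a raw measurement to a score in {0, …, 5}.  The threshold tables are encoded
as explicit interval bands with per-end open/closed flags rather than as
`numpy.digitize` bins, because the published convention mixes inclusive and
exclusive ends: a band printed "5–20" includes both endpoints, while a
">20–30" band excludes 20 and includes 30.  The scorer asserts at lookup
time that exactly one band contains the value, so a malformed override
rubric fails loudly instead of silently double- or zero-matching.

Conventions adopted where the scheme is silent:

- **Missing data score 0.**  Any unmeasured attribute takes the
  "no data / not evaluated" score.  This is also how "not established /
  failed to grow" is represented for the two cultivation attributes: their
  score-0 state is the *absence* of a measurement, so any measured height,
  however small, scores at least 1.
- **Open-ended top bands.**  The top band of each quantitative scale is
  unbounded above.  For total phenolic content the published top band is
  ">150–200" mg GAE/100 g; values above 200 are clamped to score 5, keeping
  the rubric monotone rather than leaving a hole.
- **Fruit onset** is stored as the growing-season index after planting
  (season 2 = second year).  The mapping is descending: season ≤ 2 → 5,
  3 → 4, 4 → 3, 5 → 2, ≥ 6 → 1, never fruited → 0.  Fruiting in the
  establishment season, not covered by the published rows, takes the top
  score by monotone extension.
- **Negative raw values are rejected**, including negative growth rates.  A
  genotype that shrank between months 6 and 18 is a data-quality question
  the rubric refuses to paper over; the trial module will still compute and
  report the negative rate.
- **Aggregation across genotypes** is the arithmetic mean over genotypes
  with data for each quantitative attribute, the earliest season for fruit
  onset, and a conjunction for molecular authentication (one ambiguous
  genotype blocks the species' authentication score).

Percentages everywhere are round-half-away-from-zero to one decimal
(`decimal.Decimal`, not the built-in banker's rounding): 40/72 → 55.6 %,
26/35 → 74.3 %.  This single rule reproduces every published percentage in
the case-study fixtures except one table cell that prints 55.5 for 40/72;
the package follows the arithmetic.

## Feasibility and readiness

The 12-attribute feasibility vectors arrive as already-assigned integers;
the semantic mapping from species facts (IUCN category, range size, market
presence, …) to scores belongs to the upstream scheme and is deliberately
out of scope.  The module enforces each attribute's admissible score set
(e.g. water demand ∈ {0, 1, 3, 6}; known propagation ∈ {0, 3, 5, 6}),
naming the attribute and the admissible set on failure.

The readiness band table contains exactly the two published bands plus an
explicit "unclassified" catch-all below 55 %.  Thresholds are strict lower
bounds: 70.0 % is still short-term, 55.0 % is unclassified.  No
medium-/long-term bands are invented; a custom band table can be supplied
as YAML.

## Trial statistics

- **One-way ANOVA** per genotype and measurement date is the classical
  between/within sums-of-squares decomposition with p from the F
  distribution.  Zero within-group variance returns a result flagged
  `degenerate` (F, p = NaN) rather than raising, since an all-equal date is
  a legitimate observation.
- **Tukey HSD** uses `scipy.stats.tukey_hsd`, which applies the
  Tukey–Kramer standard error when replicate counts are unequal (plant
  death).  The test suite cross-checks it against both
  `statsmodels.pairwise_tukeyhsd` and a direct studentized-range
  computation.
- **Repeated measures ANOVA** is the univariate split-plot decomposition:
  treatment tested against subjects-within-treatment, time and
  treatment × time against the residual.  No sphericity correction is
  applied.  The decomposition is implemented directly (the result objects
  expose every SS stratum, which off-the-shelf mixed-ANOVA routines do not
  return); `pingouin.mixed_anova` serves as an independent oracle in tests.
  The grid must be balanced; incomplete replicates are excluded listwise on
  request (`drop_incomplete=True`), and treatments must retain equal
  replicate counts.  Note that duplicating every replicate doubles each SS
  stratum exactly but *changes* the F ratios through the error degrees of
  freedom — the tests assert the SS identity, which is the true invariant.
- **Growth summaries** compute the 6→18-month rate on treatment-mean
  heights, not as a mean of per-plant rates, matching how per-treatment
  rates are reported alongside mean-height trajectories.  Target months are
  matched to the nearest measurement within ±1 month and the matched month
  is recorded in the output.  Heights are carried in cm; the handoff to the
  rubric converts to metres and picks the best-performing treatment
  (greatest 18-month height, earliest onset across treatments).

## Synthetic generators

The trial generator draws

    height(rep, t) = baseline + b_rep + slope[treatment]·t + ε(rep, t),

with b_rep ~ N(0, σ_rep), ε ~ N(0, σ_meas), truncated at zero.  Defaults:
three treatments (control/conventional/organic), 5 replicates,
measurements at months 3, 6, 9, 12, 15, 18, σ_rep = σ_meas = 5 cm.  A
two-level Gaussian is the minimal structure consistent with mean ± SE
trajectory plots; it deliberately omits autocorrelated growth shocks,
seasonal growth arrest, and climate covariates.  Passing tests on this
generator therefore demonstrate correctness of the statistical machinery
under its stated assumptions, not robustness to real orchard data.

Fruiting is drawn per replicate and season from a per-treatment hazard,
starting at `first_fruiting_season` (default 2: juvenile woody plants do
not fruit in the establishment season), and is persistent once begun.

Randomness: `numpy.random.SeedSequence` spawning gives each genotype its
own child stream, so enlarging a simulated trial never perturbs genotypes
already generated, and identical (config, seed) gives byte-identical
output.

Three presets anchor the height scale to published juvenile growth of the
corresponding genera (dogrose ≈ 2.3–3.6 m at 18 months, 20–45 % growth,
onset season 2; cornelian cherry ≈ 0.8–1.25 m, no onset within the trial;
elder up to ≈ 2.45 m).  They are scale-anchored, not fitted: the true
replicate-level variances of the source trials were never published.
Baselines are comparatively high because cutting-raised plants put on most
of their height before the 6-month mark, which is what reconciles metre-
scale final heights with sub-50 % 6→18-month growth rates.

The profile generator draws each quantitative rubric measurement from a
normal distribution clipped to the attribute's domain.  Given target
scores it centres each distribution at the midpoint of the corresponding
band (open-ended bands are capped at a plausible-range limit: 100 % for the
percentages, 200 mg GAE/100 g for phenolics, 3 m for height, 30 % for
growth rate), so zero-noise draws recover the targets exactly and
small-noise draws recover them with high probability.

## Statistical check sizes

The simulation-backed checks in the test and acceptance suites use: 1000
null trials for the type-I error of the per-date ANOVA (nominal 5 %,
asserted within ±2 points; at this size the binomial standard error is
≈ 0.7 points), 200 trials for power under a +8 cm/month fertilization
effect (asserted ≥ 95 %), and 200 seeded draws for rubric score recovery
under default noise (asserted ≥ 95 %).

## Known limitations

- The rubric refuses negative raw values, so a shrinking genotype must be
  handled (or excluded) by the analyst before scoring.
- Repeated measures analysis requires equal replicate counts per treatment
  after listwise exclusion; heavily unbalanced seasons need a mixed-effects
  model, which is out of scope.
- Feasibility score semantics are not computed — garbage scores that happen
  to lie in the admissible sets validate.
- The generator's linear-trend model cannot express within-season growth
  arrest; per-season piecewise configurations can approximate it by
  simulating seasons separately.
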