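# Methods

This note documents the models, estimators and numerical choices behind
`dietswap`, and what the synthetic-data generator does and does not
emulate.

## Data model

All tables are pandas DataFrames under the column contracts in
`src/dietswap/data/schema_reference.md`.  A *person-day* is one recall day
of one participant; food records carry grams, energy, a 13-nutrient
vector, an 11-field food-pattern-equivalents vector, a price per 100 g
and flags (beverage, beverage addition, ready-to-eat cereal, milk).  The
cereal flag is always recomputed from the food-code prefix (571–574);
the beverage flag is an input because beverage identification is
code-list based upstream and not derivable from the reduced schema.
Age groups (1–3, 4–8, 9–13, 14–19, 20–30, 31–50, 51–70, 71+) are derived
from integer age and are total and disjoint over ages ≥ 1.

## Composite profiles

Component weights are survey-weighted **energy shares** over both recall
days and all eating occasions.  Energy-share weighting was chosen over
occasion counts or gram shares because the substitution is energy-based:
with energy weights the composite's per-1000-kcal density equals the
stratum's realized mean cereal density, so the modeled cereal is exactly
"the cereal this stratum eats, per calorie".  An unweighted mode
(`survey_weighted=False`) is retained for sensitivity analysis.

Milk co-consumption uses a same-person, same-day, same-occasion rule — an
approximation to recipe-level combination linkage, which the schema does
not carry.  `p_milk` is the weighted share of cereal-containing
person-day-occasions that include milk; `milk_energy_share` is the
weighted mean of milk kcal over combined milk+cereal kcal **conditional
on milk being present** (paired with the explicit `p_milk`, this is
preferable to a per-capita mean because the two parameters then have
independent interpretations).  Composite price per 1000 kcal is the
energy-share-weighted mean of component prices.

Strata with no cereal records fall back deterministically:
stratum → same age group pooled across races → national pool, with the
level recorded on the profile and logged.

## Substitution

Eligibility per person-day, with precedence: no breakfast-class record →
skipped; any cereal at a breakfast-class occasion → cereal consumer
(untouched, matching the modeling convention that existing cereal
consumers' diets are not modified); only beverages/beverage additions →
beverage-only; otherwise eligible.  Eligibility is per recall day, not
per person: the two recalls are modeled as separate days, so a person can
be eligible on one day only.  When the beverage-addition flag is absent
in input data the record is treated as a replaceable solid (conservative;
logged by validation).

Model 2 allocates milk deterministically at the expected value
`p_milk × milk_energy_share` of replaced energy rather than by stochastic
per-day assignment.  Population means are identical under both schemes,
and the deterministic form makes every downstream table reproducible
without a seed.  With `p_milk = 0` Model 2 is bit-identical to Model 1
(no milk record is inserted at zero energy).

Synthetic records keep the arithmetic exact: energy is the replaced
energy, constituents are `density × E/1000`, grams are `E / energy
density`, and the stored price per 100 g is back-computed so that
`grams/100 × price` reproduces the composite's price per 1000 kcal.

## Person-day totals and empty calories

Totals are straight sums, so substitution and totalling commute exactly.
Empty calories (SoFAAS) use 9 kcal/g solid fat, 16.8 kcal/tsp added sugar
(4.2 g/tsp × 4 kcal/g) and 6.93 kcal/g alcohol counted only above an
allowance of 13 g per 1000 kcal; all four constants are configurable
(`EmptyCalorieConstants`).  Diet cost is `grams/100 × price per 100 g ×
inflation factor`, with multiplicative per-food-group factors keyed by
3-digit code prefix defaulting to 1 (identity when prices are
pre-adjusted).

## HEI-2010

The 12 component standards (density basis, zero/max thresholds, maximum
points summing to 100) ship as an editable YAML file; scores interpolate
linearly between thresholds and are clamped.  Population scoring is the
population ratio method: weighted constituent sums pooled across persons
first, densities and scores from the pooled ratios.  This is not the mean
of per-person scores, and a regression test pins a toy where the two
differ.  Conventions for degenerate inputs: zero-energy totals score 0 on
adequacy and full points on moderation components (with a logged
warning); a zero-SFA diet with unsaturated fat present maps the
fatty-acid ratio to the max-score threshold (ratio → +∞).

## Usual intake

A deliberately simplified two-part measurement-error model:

* **Ubiquitous** outcomes: day values are transformed (log default,
  Box-Cox optional; zeros offset by half the minimum positive value),
  regressed on weekend and recall-sequence indicators by survey-weighted
  least squares, and decomposed by moments: within-person variance is the
  weighted mean squared half-difference of the two recalls' residuals,
  between-person variance is total residual variance minus that, floored
  at zero.  No maximum likelihood, no random-effects covariance.
* **Episodic** outcomes: per-person consumption frequency shrunk toward
  the weighted population rate with strength from a beta-binomial moment
  fit (intra-person correlation clipped to [0.01, 0.99] so shrinkage is
  always proper), multiplied by an independent amount model fit on
  consumption days.

The usual-intake distribution is Monte Carlo: person effects drawn on the
transformed scale, back-transformed with a 30-node Gauss-Hermite integral
over the day-deviation distribution (exact for the lognormal case,
general for Box-Cox), episodic probabilities drawn from the fitted beta.
The population mean on the transformed scale averages the weekend effect
at 2/7 weekend days, at first-recall reference.  Percentiles 1–99 and
threshold proportions are read off the simulated draws; the default
20,000 draws put the Monte-Carlo error of a mid-distribution proportion
near 0.35 percentage points.

These simplifications mean the module targets *parameter recovery on data
generated under its own assumptions* (verified in the test suite), not
equivalence with the full mixed-model machinery used on real surveys.

## Survey inference

Balanced repeated replication for stratified two-PSU designs: half-sample
selection from the columns of a Sylvester Hadamard matrix (order 32 by
default; strata assigned to columns in sorted-key order for
determinism), Fay factor pairs (2−f, f) with f = 0.7, variance
`Σ_r (θ_r − θ_0)² / (R(1−f)²)`.  For linear estimators this reproduces
the closed-form stratified variance exactly (tested).  Weight
construction accepts the degenerate f = 1 (replicates equal base
weights); variance estimation rejects it.

T-tests on model-vs-observed contrasts use the paired per-person
difference and its BRR standard error, with degrees of freedom equal to
the number of strata by default (a normal-approximation policy is
available; the df convention for this design is not standardized).
Effect labels gate on p < 0.05 and read "between 5% and 10%" as
inclusive: exactly 5.0 and 10.0 are *modest*.

## Synthetic cohort generator

The generator's defaults are the study conditions for every simulation
test in the repository: 85% two-recall completion; per person-day
breakfast behavior {skip 0.17, beverage-only 0.25, cereal 0.16, eligible
solid food 0.42}, i.e. 83% breakfast consumption and ~42% substitution
eligibility; per-stratum cereal popularity drawn once from a Dirichlet;
milk with cereal at probability 0.6 and a 0.28 conditional energy share;
milk type mix shifting from whole milk in young children toward skim in
older adults; lognormal person and day effects with between/within CVs of
0.30/0.35 on portion sizes; a weekend amount multiplier of 1.05 (weekend
drawn Bernoulli(2/7)) and a second-recall (telephone-mode) multiplier of
0.97.  Breakfast-solid portions of 120–260 kcal with one to three items
put the mean replaceable breakfast near 380 kcal.  Cereal is configured
cheaper per calorie than the pastry-class foods it replaces, so cost
deltas have a known sign.  Intakes are generated on the log scale so the
usual-intake module's transformation assumptions are exercisable.

Because portions, behaviors and library densities have known
distributions, the expected per-capita change of every outcome has a
closed form,

```
E[Δ] = p_eligible × E[replaced kcal] × (composite density − replaced mean density) / 1000
```

with the composite mixed over strata by the age×race distribution and,
for Model 2, blended with milk at `p_milk × milk_energy_share`.
`E[replaced kcal]` includes the weekend and recall-mode multipliers.
Pipeline estimates are tested against these expectations within three
standard errors at n = 5000.

What the generator does **not** emulate: item-level missingness and
nonresponse, day-of-week sampling weights, recipe/combination food
linkage, supplement intake, seasonal or secular trends, and realistic
correlation between food choices within a day (items are drawn
independently given the behavior class).  Passing tests therefore show
the estimators are correct under the stated structure, not that real
survey data meet that structure.

## Problem sizes and runtime

Simulation tests use 1,200–5,000 participants and the acceptance script
uses 5,000 — large enough that estimator noise sits well inside the
tested tolerances (e.g. composite-weight recovery at 0.03 per component
needs several thousand cereal occasions per stratum, which the recovery
tests arrange by concentrating the cohort on one or two strata).  The
full suite runs in about a minute on one CPU.

## Known limitations

* The usual-intake variant ignores probability–amount correlation for
  episodic foods and uses moment estimators; percentile tails are less
  reliable than means.
* BRR standard errors treat the composite profiles as fixed when
  replicating downstream estimators; profile-estimation uncertainty is
  not propagated.
* Diet cost ignores price imputation for foods missing a price (zero
  cost, warned) and treats inflation as group-level multiplicative.
* The fallback chain for empty strata pools across races before pooling
  nationally; alternatives (e.g. nearest age group) are not implemented.
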