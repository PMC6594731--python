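# Methods

## Scope and data

The package estimates, for a regional 65+ population over a 10-year
horizon, the annual cost of assistive digital technologies that support
ageing in place. All demographic and epidemiological inputs are small
published tables bundled as CSV under `src/agetech/data/`: regional
census counts by five-year age band (2006/2011/2016), Queensland
age-specific death rates per 1,000 (2006–2026; the 2021/2026 columns are
published projections injected directly), national assistance-need and
residence shares by age band, national disease-count pools and the 8×8
pairwise comorbidity matrix for the eight most common chronic diseases,
and published regional cost aggregates used only as numerators of
per-capita ratios. Device prices are not bundled: the underlying market
price survey is not public, so the catalog module ships a synthetic
generator instead (see below).

## Progressive forecasting

Cohorts advance in five-year steps. A closed band at year *t + 5* is the
next-younger band at *t* advanced through five annual cycles of
survival, `x ← x·(1 − m/1000) + g`, where *m* is the death rate
(deaths per 1,000 per year, so compounding annually) and *g* the band's
annual net-migration allotment; results are clamped at zero. The open
terminal band (85+) retains its own survivors in addition to entrants
from 80–84.

Conventions the source data do not pin down, and the choices made:

* **Which band's rate governs a transition.** Default: the destination
  band's rate at the destination year; origin-band and mean-of-both are
  configurable (`rate_convention`). For the 85+ band's self-retention
  the "destination" is taken five years deeper (the 90–94 schedule
  band), since everyone retained was already 85+ and ages past 90 by the
  end of the step — without this the terminal band grows implausibly.
* **Migration.** Net overseas (−0.006%/yr) and interstate (+0.058%/yr)
  rates apply to the whole regional population; the resulting annual
  migrant count is apportioned to the 65+ bands in proportion to the
  cohorts feeding them. Regional totals come from the bundled table or a
  linear trend on available years.
* **Rate projection.** Death rates for years missing from the schedule
  are projected per band by ordinary least squares on year. The richer
  multivariate regression the source describes (population, year,
  chronic-disease counts) is under-determined by three observations, so
  the package fits year-only trends and also accepts an externally
  supplied projected schedule — the bundled 2021/2026 columns — which is
  what the default pipeline uses.

The published per-band forecast is **not** exactly recoverable (its
survivor-ratio and migration-timing conventions are unstated); with the
choices above the computed 2026 total 65+ lands within about 4% of the
published endpoint, and the pipeline can run from either the computed
forecast (`forecast_source="computed"`) or the published endpoints
(`"published"`, the default for table reproduction).

## Assistance need

Within each age band the share living at home *and* needing assistance
is the product of the two survey marginals. The pipeline applies the
overall published figure, 36.61%, kept as a configurable scalar rather
than recomputed from rounded marginals (0.386 × 0.948 = 36.59% — a
rounding artifact of the printed table; the published downstream counts
require 36.61% exactly). Per-band rates are available but unused by the
default pipeline, matching the published workflow.

## Comorbidity allocation

The assisted population is split by unrounded pool ratios into the
0/1/2/3+ disease categories. Two regimes:

* **`published` mode** (default) reproduces the published tables
  cell-for-cell, including their rounding conventions: category shares
  use the printed pool total (3,285.6 thousand) as denominator even
  though the pools sum to 3,286.5; one-disease shares are count /
  printed single-pool total (872.6) rounded to 0.1% before multiplying
  the whole-person pool. Because the source's single-disease column
  itself sums to 876.0, the eight one-disease cells overshoot their pool
  by 14 persons in 2016 — a source-data inconsistency preserved
  deliberately.
* **`strict` mode** renormalises all shares so every category's strata
  sum to its total and the whole allocation conserves the assisted
  population to ±1 person.

Two-disease strata take normalised shares of the 28 pairwise
co-occurrence cells. The matrix counts people with 2+ diseases in every
pair they exhibit, so applying its normalised ratios to the
exactly-two pool is an approximation — but it is the prescribed one.
Three-plus strata: each of the 56 triples is scored by the sum of its
three pairwise cells (min and product scoring available; only min and
product concentrate all mass on a triple that alone co-occurs); the
`top_k = 4` highest-scoring triples take mass proportional to score
over the total triple score mass, and the residual is spread over the
remaining 215 subsets weighted by the mean marginal prevalence of their
member diseases ("weighted average" residual). Under sum scoring the
top three triples match the published common-combination list;
the published fourth (CVD + mental + back) ranks fifth under every
scoring rule provided, so no rule here reproduces it and none is forced
to.

Rounding is half-up, applied only at display; all intermediates carry
full precision (the published per-capita figures are only recoverable
with unrounded divisors, e.g. 1,510.53 rather than 1,511).

## Cost engine

Per device and year: `price·(1 + installation)/lifespan +
maintenance·price`, i.e. purchase and installation amortised over the
lifespan with annual maintenance. Defaults — 5-year lifespan, 5%
installation, 15%/yr maintenance — are global assumptions, overridable
per item. A cash-flow mode books the full purchase in replacement years
instead; its 5-year average equals the amortised figure. No discounting:
all costs are constant base-year AUD. Prices quoted after the base year
are deflated by `(1 + r)^{-years}`; the deflation rate is a config value
(default 0.019/yr, approximately Australian CPI over 2016–2018) and no
reproduced figure depends on it. A person's kit is the union of the
basic bundle and their diseases' bundles, shared devices priced once, so
per-person cost is monotone under combination inclusion and under the
low → average scenario switch.

## Synthetic data

`synthetic.py` generates what cannot be shipped: individual disease sets
and a device catalog.

* Disease sets follow a log-linear pairwise model — independent
  per-disease prevalences tilted by pairwise odds multipliers. The
  2⁸-point outcome space is enumerated exactly, which yields closed-form
  pair probabilities; tests require sampled frequencies to match within
  3 binomial standard errors at n = 100,000. Default prevalences are
  shaped like national 65+ prevalence (arthritis and CVD near 0.5,
  cancer and COPD under 0.1).
* The catalog draws `price_low` uniformly per function category and
  `price_avg = price_low × U[1.2, 3]`; each disease gets 2–6 monitoring
  -leaning devices, the basic bundle draws from safety/mobility/fitness.
  Everything is reproducible bit-for-bit from the config seed.

What the generator does **not** emulate: age-dependence of prevalence,
higher-order (beyond pairwise) disease interactions, regional deviation
from national comorbidity structure, price correlation across devices,
and uptake behaviour. Passing tests therefore demonstrate internal
consistency of the pipeline and correct recovery of the generating
pairwise structure, not fidelity of any absolute cost to the real
device market.

## Problem sizes and determinism

The full published-input pipeline covers 3 years × 256 strata and runs
in well under a second; synthetic calibration checks use n = 100,000
individuals (a few seconds). All randomness flows from a single config
seed; two runs with identical config produce byte-identical reports.

## Known limitations

* The published per-band forecast and absolute cost totals are not
  reproducible (unstated survivor conventions; unpublished prices); the
  package reproduces every quantity that is, and checks the rest
  directionally or structurally.
* Pair-share allocation double-counts higher-order patients by
  construction of the source matrix (documented approximation).
* No benefit or cost-benefit analysis, no funding-source attribution,
  and no modelling of technology obsolescence beyond the fixed lifespan.
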