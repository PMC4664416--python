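# Methods

## Model and assumptions

The package treats a chronic, incurable disease in discrete annual time on
single-year age × sex cohorts (ages 20–100, with 100 meaning "100 and
above"). Within a cohort the state space is {disease-free, diseased, dead}
— an illness–death model without remission. The end-of-year prevalence
recurrence

p_y = [ (1−m1) p_{y−1} + ( (1−m) − (1−m1) p_{y−1} ) i_y ] / (1−m)

encodes a fixed within-year event order: mortality acts first (at risk m1
for prevalent cases, m0 for others), then incidence i_y among the year's
disease-free survivors. The denominator (1−m) renormalises to the surviving
cohort, so p is a proportion of survivors and the whole pipeline is
invariant to population scale. The same convention fixes the inversion used
for back-calculation and the event order of the microsimulation; keeping
the three aligned is what makes round-trip and oracle tests exact rather
than approximate.

Key assumptions: no remission; no disease-specific migration selectivity
(migrants adopt the prevalence of the cohort they join, configurable to
zero); incidence and prevalence refer to diagnosed/treated disease unless
the optional amplification and undiagnosed adjustments are applied; the
relative mortality of disease is exogenous (taken from published survival
studies, not estimated here).

## Indexing conventions

All per-step rates (m, rr, and the derived m1/m0) are indexed by the
cohort's *starting* age; the incidence surface is indexed by *attained*
age — the age a cohort reaches at the end of the year the incidence refers
to. This matches the cohort link p_{y−1}(a) → p_y(a+1) of the inversion.
The step into calendar year y uses the death risk of year y−1, following
the recurrence's subscripting. The trend exponent counts years since the
scenario base year (the first projected year has t = 1), both for the
incidence trend and for the relative-mortality decline.

## Mortality model

Published inputs give the total-population death risk m and a relative
mortality rr ≥ 1 of the diseased. The pair (m1, m0) is recovered from the
mixture identity p·m1 + (1−p)·m0 = m. Two reference conventions are
exposed: `vs_nondiabetic` (rr = m1/m0, the default — it conserves the
mortality budget exactly for any rr) and `vs_total` (rr = m1/m, which can
become inconsistent when p·rr·m > m and then raises). The denominator is
computed as 1 + p(rr−1) so that rr = 1 returns m1 = m0 = m to the last
bit, which the closed-cohort limit tests rely on.

The secular decline of rr (default 1.6 %/yr) supports two conventions,
because published phrasing is ambiguous between "relative excess mortality
declines" and "relative risk declines": `excess` applies the decay to
rr − 1 (so rr → 1 asymptotically, never below), `ratio` applies it to rr
with a floor at 1. `excess` is the default since it avoids the diseased
ever out-surviving the disease-free over long horizons.

## Back-calculation

For each sex and consecutive year pair the inversion is applied along
cohort diagonals. Attained age 20 has no predecessor cohort and the 100+
bin pools survivors of ages 99 and 100, so neither cell is invertible;
they are skipped and logged, leaving attained ages 21–99. Negative
back-calculated incidence (observed prevalence falling faster than
mortality explains) is *preserved* and flagged — clamping would hide data
inconsistencies — but projections clamp incidence at 0. Projections needing
a full age grid nearest-fill the two edge ages.

## Projection bookkeeping

Population advances by the cohort-component method: survivors age one
year, the 100+ bin absorbs (its prevalence is the survivor-weighted mean
of the two pooling cohorts), entrants refill age 20, and net migration
joins its cohort. When a full forecast count table is supplied, entrants
and migration are recovered as residuals of the advancement identity, so
re-advancing reproduces the table exactly. Entrant cohorts receive the
base-year age-20 prevalence scaled by the cumulative incidence-trend
factor; with the default trend of 0 this is simply the base value.

Scenario D freezes rr at its scenario-base-year value while the
general-population death risks continue to follow the supplied schedule,
so only the *relative* advantage of the diseased stops improving.

## Driver decomposition

There is no unique additive split of a case increase into population size,
age structure, and relative survival, because the drivers interact. The
default is sequential counterfactual substitution in the order (size,
structure, survival): rescale the horizon-year population total to the
base-year total; replace the horizon-year age/sex composition with the
base-year composition; re-run the projection with the rr trend frozen.
Each component is the drop in horizon-year cases its substitution causes;
the remainder over the base-year count is the residual, dominated by
falling general-population mortality, which no substitution touches.
Additivity is exact by construction (telescoping differences). The order
is recorded in the result, and a Shapley-style mode averages each factor's
marginal contribution over all six orders (the tiny averaging round-off is
folded into the largest component to preserve exact additivity).

## Flat-prevalence solver

The required annual incidence decline δ is found by bisection on
δ ∈ [0, 0.2], driving the horizon-year total adult prevalence (both sexes)
to the base-year value within 1e−6 on the proportion scale. Projected
horizon prevalence is monotone decreasing in δ, which validates the
bracket; the full convergence trace is returned for auditing. Bisection is
implemented directly (rather than through a library root-finder) because
the trace is part of the contract; an independent grid search at 1e−4
resolution confirms the solution in the test suite.

## Synthetic country

The generator emulates the statistical shape of national registry inputs,
not any particular country's data:

| parameter | default | meaning |
|---|---|---|
| entrant_size / entrant_growth | 60 000 per sex, +0.5 %/yr | age-20 cohort and its growth |
| mort_level, mort_slope | 4e−4 / 6e−4 at age 20, ×e^0.09 per year of age | Gompertz all-cause death risk, capped at 0.7 |
| mort_improvement | 1.0 %/yr | secular decline of all-cause mortality |
| inc_slope | 0.06 per year of age | log-linear incidence shape |
| rr_excess_at_20, rr_age_decay | 2.5, 0.03 | rr = 1 + 2.5·e^(−0.03·(age−20)), declining with age |
| rr_annual_decline | 1.6 %/yr | secular decline of excess mortality |
| nonpharm_share | 0.226 | share of disease not pharmacologically treated |

Two calibrations run at generation time and are deterministic: the
age-logistic prevalence curve per sex is least-squares fitted to published
three-band (20–44 / 45–64 / 65+) prevalence values at the start of the
baseline period, using the generator's own population weights; and the
incidence level per sex is solved in closed form so the
disease-free-weighted mean incidence matches published sex totals (3.3 and
5.5 per 1000). With the default incidence-age slope the generated 2013
banded prevalences sit within ±20 % of all nine published band values and
total incidence is 4.3 per 1000. The baseline prevalence series is
generated *forward* from the incidence surface through the projection
engine itself, so back-calculation faces a genuine inverse problem with
known truth.

What the generator does not emulate: registry undercount and coding noise,
cohort effects in incidence, migration selectivity, diagnostic drift, and
any real country's forecast vintage. Passing tests therefore demonstrate
the method's internal correctness and qualitative behaviour on realistic
structure — not agreement with any published national projection, whose
inputs (single-year-of-age registry baselines, official forecast files)
are not redistributable.

## Microsimulation oracle

Individuals are sampled from the base-year population with Bernoulli
disease status at cohort prevalence, then simulated annually with the
exact event order of the recurrence. The m1/m0 split uses the
*deterministic* cohort prevalence, which makes each cohort's overall death
risk exactly m and the recurrence the simulation's expectation; the
default comparison (closed cohort, 2×10⁵ individuals, 30 years) checks the
deterministic path stays within 3 Monte-Carlo standard errors at ≥95 % of
yearly checkpoints.

## Numerical choices and degenerate inputs

- m = 1 (cohort extinct within a year) raises rather than divides by zero;
  surviving prevalent mass exceeding total survivors raises a consistency
  error.
- Forward-step outputs are clipped to [0, 1] to absorb float dust at the
  boundaries; clipping never activates for interior values.
- Empty pooled top bins (zero survivor weight) fall back to the unweighted
  mean of the two pooling cohorts — only reachable in contrived fixtures.
- Table cells absent from input files are NaN internally; validators check
  role ranges on present cells and require a gap-free age axis per
  (year, sex). Operations that need full coverage raise naming the first
  missing (year, sex, age).
- All pipeline outputs are plain CSV/JSON with no timestamps, so identical
  configurations reproduce byte-identical artifacts.

## Problem sizes

Default runs use the full 81-age × 2-sex grid: a 7-year baseline
back-calculation, 37-year projections (2013–2050), a 2×10⁵-individual
30-year microsimulation, and solver verification on a 22-year horizon
with a two-stage (coarse 5e−3, fine 1e−4) grid search. These sizes keep
the complete suite under ten seconds on one CPU while exercising every
code path at the scale the method is meant for.

## Known limitations

- No remission and no disease subtypes; results pertain to the aggregate
  diagnosed disease.
- The undiagnosed-disease adjustment is a post-hoc multiplier with two
  explicit conventions (`of_total`, `of_diagnosed`); published composite
  figures that mix conventions cannot generally be reproduced exactly, so
  the convention used is always recorded in output metadata.
- The relative-mortality trend is an input, not estimated; if the true
  trend differs by age in ways the rr surface does not capture, projected
  survival effects inherit that bias.
- A uniform incidence trend across ages is the default scenario lever;
  age-specific trend vectors are accepted but published scenarios rarely
  constrain them.
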