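# prickle

Monitoring analytics for a small, closed population of European hedgehogs
(*Erinaceus europaeus*) surveyed twice a year — each spring and autumn, on
two consecutive nights — in an isolated urban park. The package is written
for the ecologists and volunteers who run such surveys: it turns a decade
of per-capture records (who was caught, when, where, at what weight) into
the quantities a population assessment needs, and ships an
individual-based simulator so that every stage of the pipeline can be
verified by parameter recovery without any field data.

## What it computes

**Abundance.** Each two-night survey is a two-sample capture–mark–recapture
experiment. With n₁ animals caught on night 1, n₂ on night 2 and m₂ on
both, Chapman's small-sample modification of the Lincoln–Petersen
estimator gives

    N̂ = (n₁+1)(n₂+1)/(m₂+1) − 1,
    var(N̂) = (n₁+1)(n₂+1)(n₁−m₂)(n₂−m₂) / [(m₂+1)²(m₂+2)],

with a 95% interval taken lognormal on the unseen fraction N̂ − M (M the
distinct animals handled), the standard interval for closed-population
estimators. Alongside it, the **minimum number alive** (MNA) at each
occasion counts every animal caught then, plus every animal caught both
before and after — a hard lower bound on abundance, broken down by
capture type and by adult-male / adult-female / juvenile composition.

**Demography.** Unmarked animals first caught in autumn under 700 g are
young-of-year (juveniles); everyone else is an adult. From that rule the
package derives autumn juveniles per adult female (recruitment), the
percentage of adults newly marked in each survey, overwinter and
over-summer loss rates by class, and pooled-cohort life tables
(lₓ, dₓ, Lₓ, Tₓ, eₓ with Lₓ = (lₓ + lₓ₊₁)/2 and eₓ = Tₓ/lₓ) for
autumn-caught juveniles. Adult weight summaries by sex and season and
tabulations of found deaths (cause × age class, month, percent
predation-related) round out the demographic picture.

**Space and habitat.** An animal's yearly range centre is the arithmetic
mean of its capture coordinates over the calendar year; centres are
assigned to survey zones by point-in-polygon. Consecutive-year centre
displacements give the movement summary — pooled median, upper quartile,
and "long movers" strictly above the upper quartile — plus per-year zone
distributions and the percent of captures in each of 11 habitat
categories.

**Simulation.** `prickle.simulate` builds the whole system forward:
stage-structured seasonal survival, Poisson litters with a deferred
late-birth fraction, two-night Bernoulli detection, lognormal yearly
range-centre drift inside a synthetic seven-zone 166-ha park, structured
weights and habitat, and cause-assigned deaths — emitting both the
capture CSV the analysis reads and the ground truth
(`SimTruth`) the recovery experiments compare against.

## Worked example

```python
from prickle import (SimConfig, simulate, build_histories,
                     survey_estimates, mna_series)

ds, truth = simulate(SimConfig(), seed=42)
histories = build_histories(ds)
for est, pt in zip(survey_estimates(histories), mna_series(histories)):
    print(f"{est.occasion.label:<12}{est.n1:>4}{est.n2:>4}{est.m2:>4}"
          f"{est.n_hat:>8.1f}   ({est.ci_low:5.1f}, {est.ci_high:5.1f})"
          f"{pt.mna_total:>5}{truth.alive_total(est.occasion.index):>6}")
```

prints (columns: occasion, n₁, n₂, m₂, N̂, 95% CI, MNA, true count):

```
spring2014     8  15   5    23.0   ( 19.2,  38.6)   18    25
autumn2014    10  11   3    32.0   ( 22.1,  65.3)   19    23
spring2015     7   5   3    11.0   (  9.4,  20.4)    9    12
autumn2015     8   5   4     9.8   (  9.1,  15.7)    9    10
spring2016     2   1   0     5.0   (  3.3,  16.1)    4     4
autumn2016     2   4   2     4.0   (  4.0,   4.0)    4     4
...
autumn2019     2   0   0     2.0   (  2.0,   2.0)    2     2
autumn2020     0   0   0     0.0   (  0.0,   0.0)    0     0
```

The Chapman estimate tracks the true count and the MNA floors it from
below; this replicate declines to extinction within seven years, which is
what the default demographic rates — seasonal "loss" rates read as
mortality — imply for a closed population of this size.

The same pipeline runs from the shell on any capture CSV in the documented
dialect (`individual_id, season, year, night, sex, weight_g, newly_marked,
easting_m, northing_m, zone, habitat`):

```sh
prickle simulate --seed 42 --out sim/
prickle analyse sim/captures.csv --deaths sim/deaths.csv --out report/
prickle recover --replicates 200 --seed 1 --out recovery/
```

`analyse` writes the full table set (abundance, recruitment, unmarked
adults, interval losses, life tables, weights, mortality, zone and habitat
distributions, movements) as CSV plus a provenance summary; `recover`
reports bias, RMSE, CI coverage and recovered-vs-true parameters over
replicate simulations.

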