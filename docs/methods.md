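# Methods

This note records the statistical model behind each stage of the pipeline,
the parameter choices and their defaults, what the simulator does and does
not emulate, and the numerical conventions that had to be pinned down for
reproducibility.

## Survey model and data contract

The design is a twice-yearly (spring and autumn) census of an isolated
park population, each survey consisting of two consecutive search nights.
Animals are individually marked at first capture. A survey that did not
happen is represented by the *absence* of its occasion from the
chronological sequence — never as an occasion with zero captures — and all
interval-based statistics work on adjacency in the realized sequence,
tagging intervals that span more than one season as `irregular`. One
consequence of the CSV contract is that occasions are inferred from the
(season, year) pairs present in the file: a survey that took place but
caught nothing is indistinguishable, in the capture file alone, from a
survey that never happened. The simulator preserves the full design in its
ground-truth output.

Capture coordinates are planar metres (national-grid-style easting /
northing); all distances are Euclidean. Latitude/longitude data must be
projected before ingestion.

## Abundance

Each survey yields the Chapman estimator N̂ = (n₁+1)(n₂+1)/(m₂+1) − 1 with
Seber's variance estimator. Closure over the two nights, equal
catchability and mark retention are assumed, as in the survey protocol the
package serves.

**Confidence intervals.** N̂ is right-skewed at these sample sizes, and
the symmetric normal interval demonstrably under-covers: exact multinomial
enumeration at N = 30 and per-night detection 0.5 puts the normal
interval's coverage at 0.870. We therefore default to the lognormal
interval on the unseen fraction f₀ = N̂ − M (M = n₁ + n₂ − m₂ distinct
animals), C = exp(1.96 √ln(1 + var/f₀²)), CI = [M + f₀/C, M + f₀·C] — the
interval conventional for closed-population abundance estimators — whose
exact coverage at the same design point is 0.920. The normal form remains
available (`ci_method="normal"`, lower bound truncated at M, flagged in
output metadata). Neither interval reaches nominal 95% at such small
samples; the coverage experiment in the test suite and acceptance script
measures this directly rather than assuming it.

**MNA.** An animal contributes to the minimum number alive at occasion t
if it was detected at t or detected at *any* earlier and *any* later
occasion (not just adjacent ones — the literal reading of "caught before
and after"). Animals found only on intervening tracking-week nights count
toward MNA and capture totals but are excluded from n₁/n₂/m₂, which are
defined by the two-night design.

## Age, recruitment, losses, life tables

**Age rule.** An unmarked animal first caught in an autumn at under 700 g
is a juvenile for that autumn only; from the following spring it is an
adult, so a class sequence is always juvenile\* then adult\*. The 700 g
cutoff is strict (`< 700`); an autumn first capture with no recorded
weight is conservatively classed adult, with a warning logged.

**Losses.** "Lost over interval (t, t+1)" means present at t and never
detected at any later occasion. Presence defaults to the MNA sense
(a `captured`-only denominator is a config switch, since the choice is a
genuine free parameter of such analyses). Loss confounds death with
permanent trap-avoidance; the simulator's recovery experiments quantify
exactly when the confound vanishes (detection probability 1). Losses out
of the final occasion are reported but flagged right-censored — survivors
of the study and final-interval deaths are indistinguishable. Juvenile
overwinter losses use autumn juveniles as the starting class even though
survivors are adults by spring.

**Life tables.** Cohorts pool all individuals classed juvenile at an
autumn within the configured cohort years. Age x counts autumn
anniversaries survived: a spring detection extends presence but ages
increment only at autumns (an animal last seen in spring of year y, first
caught in autumn of year y₀, attains age y − y₀ − 1). Columns follow the
standard convention lₓ (alive at x), dₓ = lₓ − lₓ₊₁, Lₓ = (lₓ + lₓ₊₁)/2,
Tₓ = Σ_{y≥x} L_y, eₓ = Tₓ/lₓ. Cohort years should stop two years before
the study end so that age-1 anniversaries are observable; the report
defaults to exactly that.

**Weights.** An animal weighed more than once within a survey contributes
its within-survey mean once. Summaries cover adults only, by sex × season
with pooled margins; all SDs use the n−1 denominator.

**Mortality.** Deaths are tabulated by cause × age class and by calendar
month. "Predation-related" = predation plus leg injuries (leg wounds are
attributed to predator bites). Percentages are computed over deaths with
known cause and age class, so the raw counts in the cause table always
allow re-derivation under other conventions.

## Space and habitat

Yearly range centres are coordinate-wise arithmetic means of all capture
locations in a calendar year (survey and tracking-week captures pooled).
Zone assignment is point-in-polygon, boundary-inclusive, with ties on
shared boundaries broken to the lexicographically first zone name — a
determinism rule, not an ecological claim. Movements pair consecutive-year
centres only; distances pooled across all years give the median and upper
quartile, and a long mover is strictly above the upper quartile.

**Quantile convention.** Quantiles interpolate linearly between order
statistics at (n+1)p plotting positions (type 6; the exclusive-quartile
convention of spreadsheet and Minitab-style toolchains, which such surveys
are typically analysed in). On distances {10, 20, 30, 40} this puts the
upper quartile at 37.5, flagging one long mover. With the strict
inequality, the long-mover fraction can never exceed 25% by more than one
animal's worth (≤ 0.25 + 1/n), a property the tests assert on random data.

The true park zone polygons are not available as data, so the package
ships a *synthetic* seven-zone rectangular stand-in (1660 m × 1000 m =
166 ha, zoo-grounds zone 15 ha) used by the simulator and tests; real
analyses should supply their own GeoJSON.

## The simulator

The annual cycle is: spring survey → over-summer adult mortality → births
→ autumn survey → class-specific overwinter mortality → juveniles age up.
Defaults encode the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_years`, `start_year` | 10, 2014 | twice-yearly design, 20 slots |
| `missing_occasions` | spring 2020 | one skipped survey |
| `initial_adults` | 25 | closed founding population |
| `initial_sex_ratio_male` | 0.45 | slight female excess, as observed |
| `adult_oversummer_survival` | 0.62 | complement of the 37.8% mean loss |
| `adult_overwinter_survival` | 0.69 | complement of the 31.1% mean loss |
| `juvenile_overwinter_survival` | 0.44 | complement of the 56.4% mean loss |
| `juveniles_per_female_mean` | 0.9 | autumn-observable Poisson litters |
| `deferred_birth_fraction` | 0.2 | late-born young missed in autumn |
| `per_night_capture_prob` | 0.5 | Bernoulli per night per animal |
| `centre_drift_median_m` | 142 | lognormal yearly drift, log-SD 0.9 |
| `within_year_scatter_sd_m` | 60 | isotropic capture scatter |
| weights | 843/158.2 (spring), 952/150.2 (autumn) | adult normal models, g |
| juvenile weights | mean 550, SD 120, truncated < 700 | autumn young-of-year |
| `habitat_mix` | short grass 0.59, tall grass 0.16, … | 11 categories |
| `predation_death_fraction` | 0.59 | remainder spread over four causes |

Total litters are Poisson(0.9/(1 − 0.2)) per autumn female with each pup
deferred with probability 0.2, so the *autumn-observable* litter stays
Poisson with mean exactly 0.9 — deferral models the late-season young that
autumn counts miss; survivors of their first winter surface the following
spring as previously unmarked adults. Deferred pups that die in their
first winter were never observable and generate no records.

Because the seasonal survival defaults are complements of *loss* rates —
which bundle permanent non-detection with death — the implied annual adult
survival (≈ 0.43) drives the simulated population to collapse within a
decade. That is a faithful rendering of what those rates mean for a closed
population, and it mirrors the decline of the population the design comes
from; recovery experiments therefore draw most of their information from
the early, well-populated years, and pooled cohorts exclude the final two
study years.

Randomness uses one seed split into per-purpose substreams (demography,
detection, movement, measurement, deaths). Detection compares shared
per-animal-per-night uniforms against the capture probability, so raising
the probability can only add detections — the monotone-detectability
property the tests assert pointwise. Identical config and seed give
byte-identical output files.

**Movement inside the park.** Drift steps draw a lognormal distance
(median 142 m) and a uniform direction, redrawing the *direction* (not the
distance) when the step would exit the park, so realized step lengths keep
the configured distribution except in the extreme tail (steps longer than
the largest in-park chord from the current centre, ~1.6% of draws).
Capture-based yearly centres add coordinate-scatter noise on top of the
true centres; with four captures a year the centre error is ~30 m per
axis, which inflates the *observed* median inter-year displacement by
roughly 8–10% over the true-centre median. The recovery report therefore
computes the movement median both ways: the true-centre route recovers the
configured 142 m, and the gap to the capture-based route measures the
scatter bias rather than hiding it.

**What the simulator does not emulate.** No immigration or emigration
(the population is closed by construction); no tracking-week captures; no
habitat- or zone-dependent survival; no spatially explicit predation; no
fox–hedgehog behavioural dynamics; weights are independent across
captures rather than tracking individual condition. Passing recovery
tests therefore demonstrate that the pipeline measures what the generating
process encodes — not that real field data satisfy these assumptions.

## Recovery experiments and their reference points

`recovery_experiment` runs the full pipeline over replicate simulations
and summarises, per replicate: mean Chapman bias and RMSE against true
alive counts, 95% CI coverage, mean MNA/truth ratio, mean observed
juveniles per adult female, first-year juvenile survival l₁/l₀ from the
pooled life table, and the median inter-year drift (both routes). The
natural reference for l₁/l₀ is the product of juvenile overwinter and
adult over-summer survival (0.44 × 0.62 = 0.27), because the
autumn-to-autumn first year spans one winter as a juvenile and one summer
as an adult. These comparisons are exact identities at detection
probability 1 and degrade gracefully as detection drops — at the default
0.5 per night, loss-based survival under-estimates true survival and the
coverage of per-survey CIs falls, both of which the experiments report
rather than correct.

## Numerical conventions

- Quantiles: type-6 ((n+1)p) linear interpolation throughout movements.
- SDs: n−1 denominator everywhere.
- Sex conflicts across a marked animal's records resolve by majority,
  ties to unknown, with a validation issue logged.
- A survey-night detection outranks a tracking-week one at the same
  occasion when computing per-occasion status.
- Chapman with m₂ > min(n₁, n₂) is a domain error; n₁ = n₂ = m₂ gives
  N̂ equal to the count with zero variance; empty surveys give N̂ = 0.
- Zone maps are validated as simple polygons with pairwise interior
  overlap below 10⁻⁶ m²; point-in-zone is boundary-inclusive with
  lexicographic tie-break.
- Report CSVs are written with deterministic row ordering; provenance
  (input SHA-256, config echo, package version) goes in `summary.txt`.

## Problem sizes used by the shipped experiments

The test suite and acceptance script size their simulations to the study's
own scale: 10-year horizons with ~25 founders; 200 replicates for recovery
experiments (Monte-Carlo SEs of ~0.01–2 in the reported units); 1000
simulated surveys for CI coverage; 500 random histories for the MNA
oracle cross-check; the full 0 ≤ m₂ ≤ min(n₁, n₂) ≤ 50 grid for the
Chapman algebra. These sizes give comfortable statistical resolution for
every assertion made.

## Known limitations

- Apparent survival only: the design cannot separate death from permanent
  non-detection; all "survival" outputs inherit this.
- The Chapman CI is approximate at very small n₁, n₂; the lognormal form
  mitigates but does not eliminate under-coverage.
- Recruitment from autumn counts under-represents late-season breeding by
  construction (the deferred fraction makes this explicit in simulation).
- The synthetic park geometry is a stand-in; zone-level conclusions from
  simulated data say nothing about the real park's zones.
- Capture-based range centres are noisy at few captures per year; the
  movement median carries the documented upward scatter bias.
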