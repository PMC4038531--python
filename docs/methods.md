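# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, the assumptions of the synthetic-data generator, and
the known limitations.

## Count-to-concentration conversion

Airborne concentration is reported as grains per cubic metre of air,
averaged over a 24-hour day:

    C = (n / f) / V

with raw count `n`, counted fraction `f ∈ (0, 1]` (transects examined /
total transects; unknown protocols default to 1.0 with a logged warning),
and daily sampled volume `V`.

* **Hirst-type traps**: `V = q · 1440 / 1000` m³ for pump flow `q` L/min.
  The nominal 10 L/min gives 14.4 m³/day. Hirst instruments are known to
  disagree with one another by roughly 25%; no inter-instrument correction
  is attempted — downstream stages work on within-site percentages, which
  are invariant to a constant per-station factor.
* **Rotorod samplers**: a swept-volume model,
  `V = n_rods · w · l · 2πr · rpm · duty_min · 24`, for rod width `w`,
  length `l`, rotation radius `r` and duty minutes per hour. The rotation
  radius is instrument-specific and rarely published; the default
  (27.9 mm) makes the standard configuration — two 1.59 × 32 mm rods at
  2400 rev/min, 6 min/hour — sample ≈42.8 L/min while spinning
  (≈6.17 m³/day), the nominal behaviour of intermittent-cycling Rotorods.
  Any analysis that depends on absolute Rotorod concentrations should set
  the radius explicitly.
* Collection efficiency is fixed at 1.0: no particle-size or wind-speed
  correction is modelled.
* Days with no record are gaps. Gaps contribute nothing to any sum and
  are never imputed; a record's date is the start of its counting period
  and its count the period aggregate (relevant for weekly-step records).

## Composition and ranking

Percentages are of the *pollen sum*: the taxon's total over the whole
record divided by all-taxa total, per site. This is the standard device
for comparing sites with different instruments and record lengths; it
deliberately discards absolute flux. A site × taxon cell with no records
at all is absent (NaN), which is distinct from an observed zero — absence
propagates through averaging and ranking, where means are taken over
occurring sites only. Ranking excludes taxa occurring at fewer than
`min_sites = 2` sites (a single-city taxon, however abundant there, says
nothing regional); ties in the average break alphabetically. Reported
values are rounded to one decimal; internal arithmetic is full precision.
When reading published percentage tables, trace cells printed as `<x` are
taken at the censoring midpoint `x/2` (so `<0.1` → 0.05); this choice
reproduces the packaged table's own printed cross-city averages at every
row.

## Pollen season and calendars

The season is the central 90% of the pollen year's total: start = first
day the running sum reaches 5% of the annual total, end = first day it
reaches 95%, both with the closed "reaches" convention (cumulative ≥
threshold), which makes the rule deterministic and scale-invariant.
Pollen years run July 1 – June 30 for temperate/subtropical Southern-
Hemisphere sites (labelled "2009/2010") and over the calendar year at
tropical sites, so austral spring seasons are never split across a year
boundary. Pollen years with fewer than 60 observed days are flagged
low-coverage and excluded from calendars by default — a few-week
deployment cannot anchor annual percentages. Calendar cells mark every
month containing at least `min_days_per_month = 1` day of any of the
cell's season windows, unioned across pollen years; a stricter occupancy
(e.g. ≥15 days) is available via the option.

## Ordination

Cities are compared with Bray–Curtis dissimilarity on their percentage
composition restricted to the union of each city's top-8 taxa (values are
not renormalised after selection; renormalisation and the full matrix are
available). Percentages are square-root transformed before the
dissimilarity by default. The transform is the conventional
community-ecology damping of dominant taxa, and on the packaged city
table it is what reproduces the published ordination of these cities
(stress 0.111 and the temperature-led envfit ordering, versus stress
0.070 and a land-cover-led ordering untransformed); `transform="none"`
and `"wisconsin"`, and Euclidean/Jaccard metrics, are one flag away.

Non-metric MDS is authored in-package: Kruskal stress-1

    stress = sqrt( Σ (d_ij − δ̂_ij)² / Σ d_ij² )

where `d` are configuration distances and `δ̂` the isotonic (monotone
non-decreasing in the input dissimilarities) regression of `d`, minimised
by SMACOF iterations (Guttman transform) with the disparities refreshed
each step. Ties in the input dissimilarities use the primary approach:
pairs are ordered by (dissimilarity, current distance) each iteration, so
tied inputs may take different disparities. The optimiser runs from one
classical-scaling (Torgerson) start plus `n_restarts = 50` seeded random
starts and keeps the lowest stress; convergence is a relative stress drop
below 1e-7 (max 500 iterations). Configurations are mean-centred; rotation
and reflection remain unidentified, so only stress and envfit r² are
comparable across runs, never axis signs. Stress ≲ 0.2 is the
conventional "good 2-D picture" threshold.

## Environmental vectors

Each covariate is regressed on the centred ordination coordinates.
`r²` is the squared multiple correlation of that two-regressor fit —
invariant under any orthogonal transform of the configuration — and the
plotted/reported direction is the unit coefficient vector (vector length
in a biplot is conventionally √r²). Significance is one-sided by
permutation of the covariate's site labels:
`p = (1 + #{r²_perm ≥ r²_obs}) / (1 + B)` with `B = 999` by default; the
+1 correction keeps `p ≥ 1/(B+1)`. Constant covariates are rejected.

## Synthetic data generator

The generator emulates a multi-city compilation with planted,
closed-form truth:

* **Sites**: `n_sites = 11` spanning 12.4–45.9°S. MinT falls ~0.48 °C per
  degree of latitude (Gaussian noise, sd 0.8 °C), MaxT sits ~11 °C above
  MinT, MAP falls ~30 mm per degree (sd 90 mm). The noise decorrelates
  MinT from MAP enough that an envfit can tell them apart. Sites north of
  17°S are tropical (calendar pollen year).
* **Taxa**: Gaussian flowering pulses on the pollen-year clock,
  `λ(u) = A · N(u; μ, σ)` in grains/m³ at day `u` after the year start.
  The default community of six taxa (grasses, native myrtles, cypress and
  introduced northern trees) spans warm affinity (`β > 0`: load scales as
  `exp(β·(MinT − mean MinT))`) and cool affinity (`β < 0`), planting a
  MinT gradient in composition; Poaceae's σ additionally widens by
  2 days/°C above the average MinT, mimicking long warm-site grass
  seasons. Loads are hundreds to thousands of grains·day/m³, typical of
  dominant urban taxa.
* **Noise**: raw counts are negative-binomial around `λ·V·f` with
  dispersion `k = 5` (variance `m + m²/k`), reflecting the strong
  overdispersion of daily pollen counts; `"poisson"` and `"none"`
  (rounded expectation) limits are available, and days can be dropped at
  a configurable gap rate.
* **Truth**: because the kernel is Gaussian, the true season bounds are
  `μ ∓ 1.645σ` days after the year start, and loads/covariate effects are
  direct functions of the parameters. `truth_report` computes these
  analytically, never from samples.

What passing the recovery tests shows — and does not. Noise-free season
recovery within ±1 day and a ≥95%-of-seeds win rate for MinT in the
envfit ranking demonstrate that the pipeline's statistics recover planted
structure of realistic shape and size. Real records differ in ways the
generator does not model: skewed and multi-modal flowering curves,
meteorology-driven day-to-day autocorrelation, mid-season instrument
outages, and taxa whose abundance responds to more than one covariate.
Under negative-binomial noise at dispersion 5, individual season
boundaries jitter by up to ~3–4 days even at loads ≥ 10³ (the crossing
day of a 5% cumulative threshold is intrinsically noisy); the tests
therefore hold the noise-free limit to ±1 day and the overdispersed case
to a ≤2-day mean absolute error, which is what the rule can deliver at
those noise levels.

## Numerical and degenerate-input choices

* Season rule on an all-zero year: no window, logged, not an error; a
  single nonzero day yields a one-day season.
* A site with zero total pollen cannot be expressed in percentages and is
  a named validation error, as is an all-zero row in a Bray–Curtis input.
* `select_top_taxa` with `k` ≥ the taxon count returns the matrix
  unchanged (warning if strictly greater).
* nMDS requires ≥3 sites and `n_dims < n_sites`; results are exactly
  reproducible given (seed, n_restarts).
* Floating-point: row sums of a full composition matrix are 100 within
  1e-6; taxon aggregation conserves site×date totals within 1e-9.

## Problem sizes

The packaged city analysis is 11 sites × 20 taxa; nMDS with 50 restarts
and a 999-permutation envfit completes in seconds. The synthetic
end-to-end checks use 11 sites × 6 taxa × 365 days per seed across 20
seeds (ordination restarts reduced to 10 there), chosen to give stable
pass/fail behaviour at interactive runtimes.

## Limitations

* Absolute concentrations from Rotorod records inherit the swept-volume
  model's configured radius; only within-site percentages are robust to
  this choice.
* The ~25% inter-instrument variation of Hirst traps is documented, not
  modelled.
* Published percentage tables carry 1-decimal rounding; analyses built on
  them (ordination, envfit) reproduce the qualitative structure and
  headline statistics but not arbitrarily fine effect sizes.
* The calendar's month-overlap rule (any day in the month) is the most
  permissive reading of "to the nearest month"; stricter occupancy is an
  option, not the default.
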