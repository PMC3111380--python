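# Methods

This note documents the model implemented by `injury_aaf`, the choices
made where the published method left the design open, and what the
synthetic-data validation does and does not demonstrate.

## Exposure model

The population in each age × sex stratum is partitioned into lifetime
abstainers + former drinkers (relative risk 1 throughout), current
drinkers who do not binge, and binge drinkers (a subset of current
drinkers). Two exposure dimensions contribute independently:

* **Binge drinking** is summarised by a per-occasion dose (grams of
  pure ethanol) and a yearly occasion count. The main analysis fixes
  the dose at 5 drinks per occasion for men and 4 for women (68 g and
  54.4 g at the Canadian standard drink of 13.6 g); sensitivity
  analyses I and II raise this to 6/5 and 7/6 drinks, and sensitivity
  analysis III takes externally estimated per-stratum mean doses as
  data.
* **Average daily volume** among current drinkers is modelled as a
  gamma distribution. Its standard deviation is tied to the mean by a
  regression through the origin, sd = c·mean, with default
  coefficients c = 1.171 (men) and 1.258 (women); these are
  configuration, not constants of nature, and any monotone sd(mean)
  function can be substituted. Moment matching gives shape
  (mean/sd)² — which under the linear law is the mean-independent
  value 1/c² — and scale sd²/mean.

### Coverage up-shift

Surveys under-report consumption; sales-based adult per-capita
consumption is treated as the accurate population total, of which 10%
("spillage") is assumed never consumed. A single coverage factor

    coverage = (Σ w_g · p_current,g · raw_mean_g / Σ w_g) / (0.9 · per_capita)

is estimated for the whole population and every stratum mean is divided
by it. One common factor (rather than per-stratum factors) is used
because the published corrected/raw ratios are constant across strata
to within 1%. Stratum weights `w_g` default to equal; a `population`
column in the consumption CSV overrides them. The factor is recomputed
inside every Monte Carlo draw from the drawn means and prevalences, so
up-shift uncertainty propagates.

## Risk model

Crude per-occasion relative risks follow ln RR = β·x² (motor-vehicle)
and ln RR = β·√x (all other injury), the one-parameter fractional-
polynomial forms that reproduce all four published anchor doses
(54.4–95.2 g) to two decimals. β is estimated by least squares through
the origin on the log scale — through the origin so that RR(0) = 1
holds exactly. Curves are evaluated at min(x, 108 g) because the
underlying studies contain almost no data above ~100 g per occasion;
the cap applies to the dose argument, not the RR value. The same curve
serves both sexes: sex enters through dose. Published coefficients can
be substituted directly via the scenario YAML.

## Time at risk

Injury risk is elevated only while alcohol is active. Risk-period
duration is a piecewise-linear function of drinks per occasion through
the two experimentally grounded anchors (1 drink → 0.5 h, 3 drinks →
3 h), anchored at (0, 0), extrapolated linearly beyond the last anchor
(d(n) = 1.25n − 0.75 for n ≥ 3) and clamped to 24 h. The shape between
and beyond the anchors is not identified by the available data; the
anchor table is configurable so a blood-alcohol-clearance model can be
swapped in. Possible risk periods per day are floor(24/duration) — a
count, hence the floor. Fractional drink counts are allowed since doses
need not be drink multiples.

The adjusted relative risks are exposure-time mixtures,
RR' = 1 + (RR − 1)·p, with p = P_day·P_days for binge exposure and
p = P_day for daily average exposure. This is the unique linear form
that returns 1 at zero exposure time and the crude RR at full
exposure; the multiplicative alternative RR·p + (1 − p) is the same
expression.

## AAF assembly

The binge component is the three-category categorical AAF with only
the binge group exposed; non-binge current drinkers carry RR 1 in this
component because their volume risk is accounted for in the average
component, which the method computes separately. The average component
is A/(A+1) with A = p_current·∫ pdf(x)·(RR'_avg(x) − 1) dx. Components
add on the AAF scale and are clipped at 1; attributable deaths are
AAF·deaths per cause cell, and cause-level AAFs are death-weighted
means over strata. The binge and average exposures are treated as
independent additive contributions; any interaction between binge days
and habitual volume (double counting of binge-day consumption) is not
modelled. X45 and X65 (alcohol poisoning) are wholly attributable by
definition; their binge/average decomposition is not meaningful and is
reported as (0, 1) by convention.

### Numerics

The average-component integral uses the trapezoid rule on a fixed grid
from 0.1 to 250 g/day at 0.05 g steps. Mass beyond 250 g/day is
negligible for realistic means (tens of g/day) relative to the
reported 2-decimal precision, and the integrand vanishes at 0 like
x^(κ+0.13) even for shapes κ < 1, so the truncated grid is benign; the
test suite verifies agreement with a 10× finer midpoint Riemann sum to
10⁻⁶. A point-mass intake distribution (`intake_model: point`) bypasses
quadrature entirely and is exact; it is both a sensitivity variant
(collapse the distribution onto the mean) and the closed-form oracle
for end-to-end validation.

## Monte Carlo intervals

Intervals are empirical 2.5th/97.5th percentiles of 10,000 re-computed
AAFs (percentile rather than normal-theory intervals because AAF
distributions are skewed near 0). Per draw, one internally consistent
bundle is generated from the lowest-level parameters:

| input | family | dispersion |
|---|---|---|
| drinker-status prevalences | Dirichlet on the 3-group simplex | effective sample size per stratum |
| stratum mean intake | zero-truncated normal (inverse-CDF) | the stratum's standard error |
| coverage factor | derived per draw | — |
| gamma shape | mean-preserving lognormal around 1/c² | coefficient of variation |
| risk coefficient β | normal | meta-regression se per class |
| binge occasions/yr | fixed, negative binomial, or lognormal | size / CV |

The distribution families are configuration: the method prescribes
only "distribution, mean and variance" per parameter. Draws landing
outside the parameter space (β ≤ 0, occasions > 365) are resampled
rather than clipped, preserving the declared marginals; their count is
logged and a warning is emitted above 1%. Components with zero point
prevalence stay exactly zero (no Dirichlet mass on zero pseudo-counts).
The recomputation is vectorised across draws (chunked gamma-density
matrices for the volume integral), which is what makes the
10,000-draw × replicate validation experiments affordable on one CPU;
`draw_parameters` exposes the identical single-draw generation for
inspection.

## Synthetic data

The generator produces stratum-level summaries — the same unit the
pipeline consumes — from a `TruthSpec`: multinomial sampling of
drinker-status counts at a declared survey size, normal sampling noise
on the raw mean at its implied standard error, Poisson mortality
counts, and a survey-coverage factor (default 0.33, matching the
roughly threefold published up-shift) linking true to observed means.
The default population uses published corrected means (12.6–39.7 g/day
range) and realistic binge parameters. It does not emulate survey
design effects (random-digit dialling, weighting, non-response), recall
bias, or correlation between drinking volume and binge frequency, so
passing validation demonstrates internal consistency of the estimator
chain — not robustness to those real-data features.

Validation experiments and their sizes, chosen to give comfortable
Monte Carlo margins at the asserted tolerances: categorical-AAF
simulation oracle at 10⁶ person-days (sampling error ≈ 10⁻⁴ against a
10⁻³ assertion); interval coverage over 200 replicate surveys of
n = 3000 per stratum with 10,000 draws each (binomial se ≈ 1.5% against
a ±3-point band), run on a point-mass-intake truth so the true AAF is
exact closed form.

## Known limitations

* Binge exposure is a point estimate at the mean dose; because RR(x)
  is convex this understates the binge component relative to a full
  binge-dose distribution, which the data do not identify.
* The same non-motor-vehicle curve serves every non-MVA cause; real
  cause-specific dose-response surely varies.
* The coverage up-shift assumes under-reporting is proportionally
  equal across strata.
* Negative or protective effects (J-curves) are out of scope: all
  injury RRs are ≥ 1 by construction, and the engine rejects curves
  implying otherwise.
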