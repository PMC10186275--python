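# Methods

## Problem and model

Childhood idiopathic nephrotic syndrome (INS) is a rare glomerular disease
(roughly 1–17 new cases per 100,000 children per year, depending on region
and ethnicity), counted here as incident events in children aged 1–16 years.
Case ascertainment comes from hospital surveys, which are imperfect: when a
fraction `p` of surveyed hospitals responds and reports go missing at random
and independently, the observed count underestimates the truth. The package
implements the standard plug-in correction

    true_cases = reported / p

and quantifies its uncertainty by Monte Carlo: each replicate draws a case
count `k ~ Poisson(reported)` and a response rate `r = Binomial(n, p) / n`
(with `n` the number of surveyed hospitals) and forms `k / r`; the 95%
interval is the 2.5th–97.5th empirical percentile band of the replicates.
The Poisson mean and the binomial success probability are the
maximum-likelihood plug-ins (the observed count and the observed response
rate); the method itself does not prescribe them more finely.

Incidence over an observation window of `m` calendar months in a population
of `N` children at risk is

    I = true_cases / N × (12 / m) × 100,000     [cases per 100,000 children/year]

with a fixed census denominator (January 1st, 2021 in the shipped cohort
inputs) and no mid-period population interpolation. The transform is linear
in the case count, so Monte Carlo percentiles propagate directly to the
incidence scale.

Rates between strata or exposure windows are compared with a two-sided
two-proportion z-test on proportions of person-time: the "trials" for a
stratum are its child-years `N × m / 12` and the "successes" its corrected
case count, with pooled variance under the null.

## Key parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `n_sims` | 1000 | Monte Carlo replicates for the corrected-count interval |
| `seed` | 20180101 (CLI) | PCG64 seed; mandatory in the API, bit-reproducible |
| eligibility | 1 ≤ age < 17 years | study population; 16-year-olds included |
| `month_threshold_days` | 15 | days per month a measure must be in effect for the month to count as exposed |
| pandemic boundary | 2020-03-01 | presentation dates from March 2020 count as "during" |
| continuity correction | on | Yates-type: shrink the rate difference by `(1/n_a + 1/n_b)/2`, floored at 0 |
| comparison counts | rounded corrected counts | configurable; person-time is annualised child-years |

Design choices where the method text left the design open:

* **Interval algebra.** All calendar intervals are half-open `[start, end)`;
  a published "in effect until date D" is stored with end `D + 1 day`. Age
  bands are half-open too (`under7 = [1, 7)`), so a child aged exactly 7
  falls in the older band.
* **Zero-response replicates** (`r = 0`) are redrawn rather than dropped or
  capped, keeping the replicate count exact; at the cohort parameters
  (p = 0.9, n = 89) the event has probability ~10⁻⁸⁹.
* **Percentile method.** Empirical quantiles with linear interpolation
  between order statistics (`numpy.percentile` default).
* **Continuity correction on by default.** The uncorrected statistic
  reproduces neither published school-closure p-value (≈0.011 and ≈0.035
  against printed 0.017 and 0.049), while the corrected one gives ≈0.019 and
  ≈0.051. The Paris value straddles the 0.05 threshold either way; it is
  treated as a tolerance check, not an exact reproduction.
* **Exposure person-time.** Exposed months are computed at whole-month
  resolution with the 15-day rule, but the published month totals for the
  cohort tables (e.g. 42 open / 6 closed school months in the Dutch cohort)
  are not derivable from any single threshold rule, so the cohort inputs
  carry them as explicit overrides; the unexposed side is always the
  complement within the window.
* **Age-floored measures** (mask mandates from age 12 or 6) are analysed
  entirely within the age-restricted cases and population: both the exposed
  and unexposed rows use the age-floored denominator.
* **Rounding** happens only at the presentation layer: incidences to 2
  decimals, corrected counts half-up to integers, p-values to 3 decimals.

## The cohort reconstructions

The two shipped registries (Dutch cohort 2018–2021, Paris-area cohort
2017–2021) are *synthetic case-level reconstructions* built from the
published aggregate tables: every reproduced margin — totals, sex, age
bands, yearly counts, pandemic period, and each policy-exposure count — is
exact, while individual dates, ages within a band, and hospital assignments
are deterministic constructions carrying no information beyond those
margins. Quarterly presentation margins are not enforced (no downstream
quantity depends on them).

The published tables are not perfectly self-consistent; the reconstructions
resolve the conflicts as follows, always in favour of the stratified
incidence table (the quantity this package reproduces):

* Paris male count: the cohort-description table prints 216 but the
  stratified table prints 215 boys / 109 girls (sums to 324 and reproduces
  the printed boys incidence 3.36); the reconstruction uses 215.
* Dutch lockdown-specific counts print 5 + 20 + 4 = 29 against an
  "any lockdown" total of 28; the reconstruction uses 5/19/4 so the
  partition holds.
* Dutch mask-mandate rows print 13 + 4 cases against a ≥ 12-years stratum
  total of 16; the reconstruction uses 12/4.
* The Paris `< 12` and `≥ 12` populations (1,747,578 and 771,822) do not
  complement to the total; both printed values are stored as-is.

A handful of published stratified incidences differ by ±0.01 from the
plug-in recomputation of their own inputs (likely Monte Carlo means versus
point estimates at print time); these are documented, not chased.

## The synthetic-data generator

`synthdata.simulate_registry` draws monthly counts
`Poisson(rate × multiplier × N / 100,000 / 12)`, where multipliers apply in
months a calendar measure is in effect (15-day rule, concurrent measures
multiply); cases get a uniform day within the month, Bernoulli sex,
categorical age band with uniform age inside the band, and a uniform
hospital among `n_hospitals`. Non-response operates at the hospital level
for the whole window — a hospital either responds to the survey or not —
matching the survey design; observed cases are those at responding
hospitals (resampled in the measure-zero event that no hospital responds).
Defaults mirror the Dutch cohort conditions: 2.94M children, 48 months,
base rate 1.2 per 100,000 child-years, male share 0.625, 65.6% of cases
under 7, 89 hospitals, 90% response.

The generator deliberately omits features of real registries: no seasonal
or spatio-temporal clustering, no catchment-size heterogeneity (uniform by
default, weights configurable), no lag between measure onset and rate
change, no case-detail misclassification. Passing recovery tests therefore
show that the estimator is correct *under its own assumptions* (reports
missing at random, independent hospitals), not that those assumptions hold
in any particular surveillance system.

`recovery_experiment` measures the corrected incidence estimator against
the *generative* (configured) incidence: mean relative bias and empirical
coverage of the 95% Monte Carlo interval. At the default study-scale
configuration with 500 replicates the bias is a fraction of a percent and
coverage sits near the nominal 95%. Coverage of the *realised*
complete-registry count is reported as a secondary diagnostic
(`coverage_complete`); it is structurally near 100%, because the interval
width reflects the full Poisson-plus-binomial sampling variance while the
realised count differs from the estimate only through the masking step.

## Numerical and degenerate cases

* Zero reported cases give a degenerate interval [0, 0] and zero incidence.
* Zero person-time on either side of a comparison, non-positive
  denominators, rates outside (0, 1], and reversed intervals raise
  domain errors; a measure split whose exposed side accrues no whole month
  is skipped in the report with a logged warning.
* Equal observed rates give exactly z = 0, p = 1; the corrected difference
  is floored at zero so the correction can only increase p.
* All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed reproduces draws, registries, and report files byte-for-byte.

## Problem sizes

The shipped analyses use the cohort scales themselves (128 and 324 cases),
1000 Monte Carlo replicates as in the published tables (10⁵ where a test
checks distributional shape), and 500 replicates for the recovery
experiment — all of which run in seconds on one CPU.

## Known limitations

* The correction assumes reports go missing at random; clustered
  non-response (e.g. by hospital size) would bias it, and the package makes
  no attempt at capture–recapture or Bayesian reporting-rate estimation.
* Exposure classification is by presentation date only; no lag-time
  modelling between a measure taking effect and a change in incidence.
* Person-time uses one census; multi-year windows with population drift are
  approximated by the census chosen.
* The normal-approximation z-test is used even for small exposed counts
  (the published analyses do the same); the test suite bounds its error
  against an exact conditional oracle at small counts.
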