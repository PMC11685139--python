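# Methods

This note specifies the statistical models, conventions and numerical
choices implemented in `pvsignal`, in enough detail to reproduce every
number the package prints.

## Counting conventions

- The analysis unit is the distinct **(case, PT) pair**: a case
  reporting the same preferred term several times contributes one pair.
- **Patients** are distinct deduplicated cases; a case counts as a
  target patient if any of its drug records matches the target
  dictionary (by drug name or active ingredient, after upper-casing,
  trimming and whitespace collapse) in a primary-suspect (PS) or
  secondary-suspect (SS) role.
- The 2×2 table for term *j* has `a` = target pairs with term *j*,
  `b` = all other target pairs, `c` = non-target pairs with term *j*,
  `d` = the remaining non-target pairs; `N = a+b+c+d` is the universe
  of distinct case–PT pairs. The expected count used by MGPS is
  `E = (a+b)(a+c)/N`.
- SOC-level tables replace PTs with system organ classes via a
  three-column PT→SOC map, again counting distinct (case, SOC) pairs.

## Deduplication

FAERS cases accumulate follow-up versions. For each CASEID the version
with the greatest FDA receipt date is kept; ties break on the greatest
PRIMARYID. The sort is stable (mergesort), so the result is invariant
to input row order. Deleted-case lists are applied *after* version
selection and cumulatively across quarters; both steps are idempotent.
Partial receipt dates (YYYYMM or YYYY) sort with unknown month/day
padded to 01.

## Disproportionality statistics

**ROR.** ROR = ad/(bc) with the Woolf interval
exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). If b·c = 0 the
Haldane–Anscombe correction adds 0.5 to all four cells; a = 0 yields
ROR = 0 with a degenerate interval. Signal: a ≥ 3 and lower bound > 1.

**PRR and χ².** PRR = [a/(a+b)]/[c/(c+d)]; the Pearson statistic
without continuity correction is χ² = N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)].
Signal: PRR ≥ 2, χ² ≥ 4, a ≥ 3.

**BCPNN IC.** The closed-form posterior of the information component
uses the standard prior constants γ₁₁ = 1, α₁ = β₁ = 1, α = β = 2, with
γ = γ₁₁(N+α)(N+β)/[(a+b+α₁)(a+c+β₁)] so the prior IC expectation is 0.
The point estimate is E[IC] and the 95% interval is
E[IC] ± 1.96·sd[IC] from the posterior variance expansion. Signal:
IC025 > 0.

**MGPS EBGM.** The observed count is modelled as n ~ Poisson(λE) with a
two-component gamma mixture prior on λ: weight w on Gamma(α₁, β₁) and
1−w on Gamma(α₂, β₂). The prior is fitted to the entire set of (n, E)
pairs by maximum marginal likelihood — each component marginal is
negative binomial with p = β/(β+E) — using L-BFGS-B on log-transformed
shapes/rates and logit-transformed weight, initialised at
(0.2, 0.1, 2.0, 4.0, 1/3), `ftol = 1e-12`. The transformed parameters
are bounded to (−12, 12): beyond that range the marginal likelihood is
flat while the pmf under/overflows, so the bound stabilises the
optimiser without constraining any attainable optimum in practice.
Non-convergence raises rather than returning a silent fallback.

The posterior is again a two-gamma mixture with shapes αₖ+n, rates
βₖ+E and updated weight. EBGM = 2^{E[log₂ λ | n]} via the digamma
identity E[ln λ] = ψ(shape) − ln(rate) per component; EBGM05 is the
posterior 5th percentile, found by `brentq` (tolerance 1e-8) on the
mixture CDF with a bracket built from the component 5% quantiles and
widened adaptively. Signal: EBGM05 > 2.

**Composite criteria.** A PT is a signal when all four individual
criteria hold; a SOC is flagged when any one holds. Ranking is by
frequency (a) or intensity (ROR), mergesort-stable with ties broken on
the other key and then alphabetically.

**Margin inversion.** `solve_background_count` recovers c from (a, b,
ROR, c+d): with r = a/(b·ROR), c = (c+d)·r/(1+r). This lets a full
table be rebuilt from a published count, point estimate and the two
totals, so interval bounds and companion statistics can be recomputed
rather than transcribed.

## Time to onset

TTO is the day difference between the earliest target-drug therapy
start and the event date, computed only when both dates are complete;
partial dates, missing dates and negative differences are excluded with
recorded reasons. Bins are 0–30, 31–60, 61–90, 91–180, 181–360 and
>360 days, closed on both ends. Medians use the midpoint rule with
interquartile ranges. Two-group comparisons use the Wilcoxon rank-sum
test with tie-corrected normal approximation and 0.5 continuity
correction; when both groups have ≤ 8 observations the permutation
distribution of U is enumerated exhaustively, so the p-value is exact
even under ties. U counts `greater` pairs plus half of ties.

## Subgroups

Stratification factors are report year, sex, age band (<18, 18–44,
45–64, ≥65, unknown), reporter occupation and seriousness. Within each
stratum the comparator is the stratum's own non-target reports, so the
stratum 2×2 cells a and c pool exactly to the marginal table. ROR and
IC are reported per stratum; strata with no target reports return NaN
rows rather than raising.

## Synthetic generator

The generator emits quarterly "$"-delimited DEMO/DRUG/REAC/THER/OUTC
files, deleted-case lists, a PT→SOC map and a JSON ground-truth
manifest. Each case reports each of the 200 catalog PTs independently
as Bernoulli(baseline × λ), with baselines geometrically spaced from
0.003 to 0.1 over 20 SOCs; target cases carry the injected multipliers
λ, background cases λ = 1. At these small per-report probabilities
the Bernoulli scheme is the binomial analogue of the Poisson
gamma-Poisson sampling model and keeps the a-counts exactly
analyzable. Per-quarter streams come from `SeedSequence(seed).spawn`,
so quarters are independently reproducible.

Defaults describe a plausible oncology cohort: 20,000 background and
2,000 target cases over four quarters; sex F 26.3% / M 66.9%; 88.5%
serious; lognormal time-to-onset with median 18 days and σ = 1.3;
duplicate-version rate 5% (PRIMARYID = CASEID×100 + version, receipt
dates strictly increasing), deletion rate 1%, partial-date corruption
10% (to YYYYMM with probability 0.7, else YYYY). The generator
deliberately omits drug–drug interactions, dose records, country
fields and MedDRA hierarchy beyond PT→SOC; `truth_table` marks a PT a
true signal iff its injected λ > 1.

## Numerical notes and limitations

- With the default catalog the full-scale configuration yields well
  over 10⁵ distinct case–PT pairs, large enough for the mixture-prior
  fit to be stable; on very small databases the fitted mixture can
  place a small weight on a near-degenerate component, in which case
  EBGM05 may marginally exceed the geometric-mean EBGM (the 5th
  percentile of the mixture is not bounded by the mixed geometric
  mean). This is a property of the estimator, not an error.
- The Woolf interval and the BCPNN variance expansion are asymptotic;
  for a < 3 none of the criteria can fire and intervals should be read
  qualitatively.
- χ² is reported without the Yates correction, matching common
  pharmacovigilance practice; with tables this large the correction is
  immaterial.
- All statistics operate on spontaneous reports: no denominators, no
  causality, and reporting biases (stimulated reporting, masking) are
  inherited, not corrected.
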