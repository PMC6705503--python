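# Methods

## The metric

For one population stratum (country or region, sex, year) the input is the
set of cause-specific mortality rates for cardiovascular disease, cancer,
chronic obstructive pulmonary disease and diabetes mellitus in twelve
5-year age groups [x, x+5), x = 30, 35, …, 85. Age groups are half-open;
the label "30–34" denotes [30, 35).

1. The four cause rates are summed per age group into ₅Mₓ (deaths per
   person-year). Summing rates first, then converting, is the only variant
   implemented; converting per cause and combining probabilities is not
   offered.
2. ₅Mₓ is converted to the conditional probability of dying in the
   interval with the WHO NCD-monitoring life-table formula
   ₅qₓ = 5·₅Mₓ / (1 + 2.5·₅Mₓ). This is the mid-interval (a = 2.5)
   actuarial conversion; for ₅Mₓ ≤ 0.01 it agrees with the constant-hazard
   form 1 − e^(−5·₅Mₓ) to within 1e−4. The formula reaches 1 at ₅Mₓ = 0.4
   and would exceed it beyond; such rates are clamped to probability 1 with
   a warning, never returned silently above 1.
3. The unconditional probabilities are survival-chain products over
   ascending age: ⁴⁰q₃₀ over the eight groups 30–65, ²⁰q₇₀ over the four
   groups 70–85. With at most twelve factors far from underflow, plain
   products are numerically adequate; no log-space accumulation is used.
4. The comparison statistic is ²⁰q₇₀ / ⁴⁰q₃₀. When ⁴⁰q₃₀ = 0 the ratio is
   carried as an explicit missing value (NaN), excluded from medians and
   fits, and counted in the log — never silently dropped.

## Units and populations

The canonical internal rate unit is deaths per person-year; files may
declare per-1 000 or per-100 000 and are rescaled on read/write. All
reporting-layer values (e.g. rates per 1 000 in the descriptive table) are
produced by scaling at output time, so unit choices cannot contaminate the
metric chain. Downstream results are invariant (to ~1e−9 relative) to which
declared unit a file uses.

Populations are never an input: they are implied as deaths / rate (per
person-year), i.e. deaths × 1000 / rate per 1 000. Because rates differ by
age, the implication is done per (country, sex, year, age-group) cell, and
because the four causes describe the same people, the cell population is
taken from the cause-summed deaths and cause-summed rate. Cells with zero
deaths and zero rate have an undefined (0/0) population; they contribute
zero deaths to merges and are excluded from population sums with a logged
count. Positive deaths at zero rate are an inconsistency error.

Regional merging sums member deaths exactly and divides by the summed
implied populations, i.e. a population-weighted mean of member rates. The
alternative deaths-weighted reading is not offered.

## Power-function fit

The relationship between x = ⁴⁰q₃₀ and y = ²⁰q₇₀:⁴⁰q₃₀ is fitted as
y = a·xᵇ. The default estimator is nonlinear least squares on the original
scale (residuals in ratio units), initialised at the closed-form log–log
OLS solution so the optimisation is deterministic; parameter tolerance is
1e−10 with a hard evaluation budget (400 evaluations ≈ 200 iterations for
the two parameters), and non-convergence raises, never a silent
best-so-far. Log–log OLS is available as an explicit alternative
(`method="loglog"`). Goodness of fit is always r² = 1 − SS_res/SS_tot on
the original, untransformed scale, whatever the estimator — one
unambiguous definition. A flat response (zero total sum of squares up to
floating-point summation residue) is reported as r² = 0.

## Descriptive summaries

The two-band table (premature 30–69 vs older 70–89) reports summed deaths,
column percentages relative to the band total, and crude rates
deaths × 1000 / implied population, broken down by year, sex, region and
cause. Cause rows share the band's whole population denominator, since the
four causes apply to the same people. Medians use the midpoint-of-two
convention for even n (the full design gives n = 2 340, which is even).
Rounding is half-up and happens only at the reporting layer; internal
statistics keep full precision. Extreme-value labels are tie-broken
lexicographically on (unit, sex, year) so reports are deterministic.

## Synthetic generator

The generator emulates the *structure* of a GBD results-tool extract, not
the world: its purpose is to make every pipeline stage and the power-law
recovery testable without a download, with known ground truth.

The all-four-cause hazard is Gompertz on the log scale, evaluated at the
interval midpoint: m(x) = exp(α_sex + β_sex·(x + 2.5 − 30)) ·
frailty_country · trendᵖᵉʳⁱᵒᵈ, then split across causes by fixed shares.
Defaults:

| parameter | default | why |
|---|---|---|
| design | 195 countries × 2 sexes × 6 years (1992–2017, step 5) | the study design; 112 320 records, 2 340 strata |
| α (log-hazard at age 30) | −7.5 female, −7.1 male | premature/older band rates land near a few and a few tens per 1 000, the observed order-of-magnitude gap, with a male excess |
| β (slope per year of age) | 0.082 | ~90-fold rate rise from ages 32.5 to 87.5, reproducing older:premature ratios around 3 |
| frailty sd | 0.35 | lognormal country multipliers spanning roughly ×/÷2, a realistic between-country spread; the underlying normal draws are truncated at ±3 sd so no seed can push a default-scenario rate past the 0.4 formula bound |
| trend per 5-year period | 0.96 | the mild secular decline seen in global NCD rates over 1992–2017 |
| cause split | 0.507 / 0.372 / 0.077 / 0.044 | cardiovascular-and-cancer dominance of the four-NCD composition |
| population by age | 100 000 × 0.93^((x−30)/5) per country/sex cell | a gently shrinking pyramid; populations only matter for death counts and aggregation weights |

A single seeded generator governs all randomness; per-country frailties are
drawn first and in fixed country order, so output is byte-identical across
runs with one seed. Deaths are deterministic rounds of rate × population by
default, which keeps the file-based pipeline exactly equal to the
closed-form oracle; a Poisson option exists for robustness tests. Any
configuration that drives a cell rate above 0.4 is rejected with the
offending cell named.

`ground_truth_metrics` computes ⁴⁰q₃₀, ²⁰q₇₀ and the ratio directly from
the hazard model with independently written arithmetic (no file round
trip, no shared vectorised code), so pipeline-versus-oracle comparisons
cannot be satisfied by a common bug.

What the generator does **not** emulate: GBD's estimation uncertainty,
within-country age-pattern deviations from Gompertz, cause shares varying
by age and country, migration/population dynamics, or calibration to any
real country. Passing tests therefore demonstrate the pipeline's
correctness on data with the right shape and realistic magnitudes, not
agreement with the real GBD extract; headline statistics from the real
extract (e.g. its exact medians and r²) can only be reproduced by feeding
that extract through `read_mortality_table`.

## Problem sizes and determinism

The test suite and the acceptance script run the full 195 × 2 × 6 design —
the same size as the real analysis — since the whole pipeline completes in
seconds at that scale. Power-fit recovery is assessed at n = 2 340 points
with multiplicative lognormal noise (σ = 0.05), against Monte-Carlo
standard errors estimated from 100 replicate generations. All simulations
are seeded; the acceptance script derives every random stream from its
`--seed` argument.

## Known limitations

- The descriptive table's population denominators are reconstructed from
  deaths/rate; printed tables built from pre-rounded inputs can differ in
  the last printed digit.
- The rate-to-probability conversion is a single fixed formula; no option
  for alternative a(x) separation factors or for per-cause conversion.
- No uncertainty propagation: point estimates only, matching the metric's
  monitoring use.
- The column-name mapping defaults to this package's canonical schema
  (country, region, sex, year, age_group, cause, deaths, rate); a raw GBD
  results-tool export needs a `column_map` (a ready-made constant covers
  the common renames) and pre-splitting of its number/rate metric rows.
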