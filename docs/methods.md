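# Methods

This note documents the statistical procedures implemented in `faersig`,
the defaults they ship with, what the synthetic-report generator does and
does not emulate, and the numerical choices made where conventions differ.

## Cleaning cascade

A spontaneous-report set moves through five stages, each recorded in a
provenance ledger (stage name → report count) plus an audit ledger of
auxiliary counts (malformed lines, join failures, per-filter drop reasons):

1. **Parse.** The five `"$"`-delimited quarterly tables are joined on the
   report identifier; a report is kept only if it has at least one drug and
   one reaction row. Dates are `YYYYMMDD`; partial dates are resolved
   deterministically — `YYYYMM` to the first of the month, `YYYY` to July 1
   (median-unbiased within the year). Parsing never judges values: an age
   of 121 years survives to be removed by the plausibility filter, keeping
   the parse/filter separation auditable.
2. **Normalize.** Drug names are uppercased, whitespace-collapsed, stripped
   of trailing salt/ester tokens (an editable list: CALCIUM, SODIUM, HCL,
   MESYLATE, …) and passed through an optional brand→ingredient map.
   Because the ingredient is always recomputed from the raw name, the
   operation is idempotent. Leading salt words (as in SODIUM OXYBATE) are
   deliberately untouched.
3. **Deduplicate.** One report per case: the latest version date wins, ties
   broken by the lexicographically greatest report id. This mirrors the
   convention that the latest case version supersedes earlier ones.
4. **Primary suspect.** Only primary-suspect drug entries are analysed. An
   ingredient appearing in one report under both the primary-suspect role
   and any other role is excluded from that report entirely (the
   conservative reading of "concurrently labeled"); reports left with no
   analysable drug are dropped and counted.
5. **Demographics.** Reports must have age, weight and sex recorded, with
   age ≤ 120 years and weight ≤ 400 kg. The boundary values are retained:
   the exclusion wording is strict ("exceeded", "over").

## Disproportionality

Each drug's 2×2 table (a = event reports with the drug, b = non-event with,
c = event without, d = non-event without) shares margins with every other
drug's table. The reporting odds ratio is ROR = ad/bc with the Wald
interval exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)); the interval is
log-symmetric, so the point estimate equals the geometric mean of its
bounds — `point_from_ci` exploits this to check printed results for
internal consistency.

- **Zero cells.** Default policy is Haldane–Anscombe: add 0.5 to all four
  cells for the ROR and CI only, with a `zero_corrected` flag; a strict
  policy raises instead. Fisher's exact test always uses the raw counts.
- **p-values.** Two-sided Fisher exact p (scipy), defined as the total
  hypergeometric probability of tables no more probable than the observed
  one. Bonferroni multiplies by the number of drugs in the tested family —
  by default the drugs meeting the case-count threshold — and caps at 1;
  the family size is recorded with the output.
- **Screening.** A signal requires, with strict inequalities, more than
  `min_cases` (100) cases, ROR above `ror_min` (3), CI lower bound above
  `ci_lower_min` (1) and adjusted p below `alpha_adj` (0.01). Setting
  `ror_min = None` yields the univariate model-inclusion rule used to feed
  the risk model, which keeps drugs whose disproportionality is significant
  regardless of the point-estimate threshold. With several true signals
  sharing one comparator, marginal RORs are attenuated (the comparator's
  event odds are inflated by the other signal drugs), so a point-estimate
  threshold is intentionally not applied at the model-inclusion step.
- **Volcano table.** x = log₂ ROR, y = −log₁₀ adjusted p (p floored at
  10⁻³⁰⁰), colour = log₁₀ case count. Bases are recorded in the column
  names; both are conventions, not statistics.

## Risk modeling

The design matrix has one row per cleaned report: 0/1 primary-suspect
exposure indicators for the candidate drugs plus age (years), weight (kg)
and a female-sex indicator, all unstandardized; the matrix is complete-case
by construction because it is built after the demographic filter.

**Penalized selection.** L1-penalized logistic regression minimizes
(1/n)·Σ log-loss + λ·Σ_pen |βⱼ|, fit glmnet-style: an outer iteratively
reweighted quadratic approximation with an inner cyclic coordinate descent
(soft-thresholding penalized coordinates), warm-started along a geometric
grid of `grid_size` (default 50) λ values running four decades down from
λ_max — the smallest penalty at which every drug coefficient is zero,
computed as max |Xᵀ(y − p₀)|/n from the demographics-only fit. Covariates
are standardized internally and coefficients returned on the original
scale; the intercept and the three demographic columns are never penalized,
preserving their role as adjustment variables rather than selection
candidates. Cross-validation uses stratified folds (default k = 10 in the
API, smaller in the bundled pipeline configs) seeded on the canonical
sorted-report-id row ordering, so permuting input rows changes nothing;
the selected λ minimizes mean held-out deviance. Inner/outer convergence
tolerances are 10⁻⁹ and 10⁻⁶ on the maximum coefficient change; at
λ = λ_max·10⁻⁴ the remaining gap to the unpenalized fit is the
soft-threshold bias, of order λ/(w̄·sd) per coefficient.

**Multivariate fit.** Unpenalized maximum likelihood by IRLS with step
halving on the log-likelihood, on internally standardized covariates with
an exact affine back-transform of coefficients and covariance. Collinear
columns are removed up front by a pivoted-QR rank check (warned, recorded).
Convergence requires the score max-norm below 10⁻⁸ (at most 100
iterations). Standard errors come from the inverse observed information;
Wald 95% intervals are exp(β̂ ± 1.96·SE), hence log-symmetric around the
odds ratio. Bonferroni adjustment is applied over the drug terms only
(demographics are adjusters, not hypotheses; their adjusted p is reported
as NaN), and a drug is flagged an independent risk factor when its adjusted
p is below 0.01. Coefficients exceeding 15 in standardized magnitude are
flagged as possible separation; the fit is still returned.

**Discrimination.** The ROC-AUC uses the rank (Mann–Whitney) formulation
with ties counted one half, with curve points at every distinct fitted
probability.

## Time to onset

One record per event report: event date minus the earliest therapy start
among the report's primary-suspect entries. Records with a missing date or
a non-positive lag are excluded and counted by reason; no imputation from
the report receipt date is attempted, so the exclusion counters expose
exactly what the summary rests on. Quantiles use linear interpolation
between order statistics (type 7 — numpy's default, stated here because
quantile conventions differ); the cumulative curve is the empirical CDF
over distinct day values, ending at exactly 1. By default onset pools all
event reports; a drug filter is available.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes:

- exactly one primary-suspect drug per report, sampled from the panel's
  exposure probabilities (no polypharmacy — this keeps the mapping between
  a drug's 2×2 table and its model coefficient exact);
- demographics from normal/Bernoulli marginals; ages rounded to whole
  years, weights to 0.1 kg;
- a binary event from logit P = α + β_drug + β_age(age−μ_age) +
  β_wt(wt−μ_wt) + β_sex(female−p_female); centring the covariates makes α
  the baseline event logit and β_drug the conditional log odds ratio the
  multivariate fit should recover;
- a log-normal therapy-start→event lag for event reports, truncated at
  15,000 days so the extreme tail stays within the representable date
  range (negligible at the quartiles);
- blemishes injected last and recorded in a truth ledger: a fraction of
  cases re-emitted as an *earlier-dated* extra version (so keep-latest
  deduplication provably recovers the untampered copy), missing
  demographics, and implausible ages (>120 y) or weights (>400 kg).

Defaults describe a cataract-like extraction: 200,000 reports; a 30-drug
panel with five signal drugs at true odds ratios 14, 10, 6, 4 and 3 among
25 nulls, uniformly exposed; baseline event logit = logit(0.02), which puts
per-drug case counts in the >100-case screening regime at this sample
size; age 66.92 ± 11.95 years, 71.16% female, weight 72.44 ± 22.53 kg;
demographic effects 0.02/year, 0.003/kg and 0.18 (female); onset median
449 days with log-sd 1.33 (chosen to match an interquartile ratio of
901/150 — the quoted quartiles are not log-symmetric about the median, so
no log-normal matches all three exactly); duplicate rate 5%, missing
demographics 10%, implausible values 1%; years 2004–2024. Identical
configurations (including the seed) produce byte-identical output files.

**What the generator does not emulate** — and hence what passing recovery
tests do not establish about real spontaneous-report data: reporting
biases (stimulated reporting, the Weber effect, secular trends beyond
uniform year sampling), polypharmacy and drug–drug confounding, indication
bias, misspelled or free-text drug names, multi-event reports with
correlated reactions, and MedDRA hierarchy structure. Recovery results
validate the *computations*, not the causal interpretability of
disproportionality statistics.

## Descriptive outputs

Baseline tables report mean ± SD (n−1 denominator; a single-report set
reports SD 0 with a degeneracy flag) and percentages rounded half-up to
two decimals. Each report contributes one outcome category, chosen by the
severity order death > life-threatening > disability > congenital-anomaly
> required-intervention > hospitalization > other-serious > missing, so
outcome counts sum to the total — the attribution rule that makes a
single-category table internally consistent. Yearly counts are zero-filled
across the configured range; the age pyramid uses half-open five-year bins
[0,5), [5,10), …

The end-to-end `run` writes every stage output plus a manifest (config
echo, seed, stage provenance, package version, timestamp). Given the same
config and seed, all analysis outputs are byte-identical across runs; the
manifest's wall-clock timestamp is the only exception.

## Problem sizes and known limitations

Validation experiments run at the sizes stated in the tests: screening
recovery and coefficient coverage use 20 seeded replicates of 200,000
reports; null calibration uses 100 replicates; onset recovery uses ~10⁴
event reports; solver cross-checks use 500-row fixtures. Exact-agreement
checks (Fisher enumeration, AUC concordance, algebraic ROR identities) are
tolerance 10⁻⁹ or tighter.

Limitations: Bonferroni is conservative for correlated drug exposures; the
penalized path assumes complete cases and binary exposure coding; Wald
intervals degrade under separation (flagged, not corrected — no Firth
penalty); the per-drug time-to-onset stratification is a convenience, not
a validated signal test; and cleaning counts from a real archive will not
match any published extraction unless the same name-normalization map and
event-term list are supplied.
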