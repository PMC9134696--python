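# Methods notes

## The CHE chain

The package implements the WHO capacity-to-pay definition of catastrophic
health expenditure. Its assumptions, as implemented:

- All monetary fields are converted to a common monthly, deflated scale
  before the chain runs. Weekly food spending is multiplied by
  (365.25/7)/12 ≈ 4.348 (the mean number of weeks per month); annual OOP is
  divided by 12; each household's monetary fields are then divided by the
  CPI factor of its interview month. The CPI map is user supplied and
  defaults to the identity (nominal values).
- Household size enters through an equivalence scale `hhsize^β` with
  β = 0.56 (the cross-country estimate from household surveys in 59
  countries), configurable.
- The poverty line is survey-internal: the weighted mean equivalised food
  expenditure of households whose food share lies strictly between the 45th
  and 55th percentiles of the food-share distribution. Percentiles use
  linear interpolation between order statistics. With tiny surveys or heavy
  ties the open band can be empty; the implementation then falls back to the
  closed band [p45, p55], and raises a `BandError` if that is empty too.
  The ranking key for the band is the food share (the WHO convention); a
  `band_ranking="expenditure"` switch ranks by total consumption instead,
  since survey reports are occasionally ambiguous on this point.
- Capacity to pay branches on subsistence vs actual food spending exactly as
  displayed above; at equality both branches coincide. Households with
  food > consumption are retained (real surveys contain them) — the second
  branch absorbs them — and counted in the exclusion log as a flag line.
- Non-positive capacity to pay with positive OOP is counted as CHE (the
  conservative "infinite burden" convention); the share `oopctp` is
  reported as NaN for such households. Zero OOP is never catastrophic.
- The 40% threshold is inclusive: spending exactly 40% of capacity flags
  the household.
- Weights default to 1 everywhere (the CHARLS-style use case drops design
  weights); optional per-household weights are honoured in the poverty
  line, all incidence tables and the quintile summary, but not in the
  logistic model.

The poverty line and the economic quintiles are computed on the **full**
cleaned sample; the descriptive tables and the regression use the
chronic-disease subsample. (Both choices are configurable through which
records are passed in.)

## Cleaning rules

Deterministic supplements in a fixed order, every step logged:
missing OOP totals are replaced by outpatient + inpatient parts when both
are present; missing household size by the member-row count under the same
household id; then households are deleted whose food expenditure, OOP, or
size remain missing, or whose consumption expenditure is missing or
non-positive. Imputation never changes an observed value; the exclusion log
reconciles exactly (initial − Σremoved = final). No stochastic imputation
is performed.

## The synthetic generator

The generator emulates a CHARLS-like survey and is the package's test bed.
What it emulates:

- right-skewed spending: monthly consumption is log-normal (default median
  e^7.6 ≈ 2000 currency units, log-sd 0.7); the food share is
  Beta(4, 6) (mean 0.40); OOP is zero-inflated log-normal (zero
  probability 0.25; positive part median e^7 ≈ 1100 per year, log-sd 1.5);
- householder covariates drawn from categorical prevalences loosely
  matching the marginal proportions such surveys report (insurance mix
  dominated by NRCMS/URRBMI, ~70% rural, ~46% of householders 65+,
  utilisation rates of 22%/24.5% for outpatient/inpatient), documented as
  illustrative only — no attempt is made to match any real survey's joint
  distribution or CPI series;
- a member table consistent with the household size, with member ages
  scattered around the householder's and the 14 chronic-condition answers
  drawn per member (non-householders at 0.4 times the householder
  prevalence). The member-65+ flag is derived from the simulated ages.

The covariate→CHE mechanism: the probability that a household's OOP crosses
the 40%-of-capacity threshold is exactly logistic in the model's design
terms, `expit(base_log_odds + true_beta·x)` (default intercept −2.2, giving
~20% incidence under the default effects). A zero-OOP gate applies first;
among OOP-positive households a latent Bernoulli (conditional probability
scaled by 1/(1−zero_prob), capped at 1 — the cap binds only for profiles
whose implied probability exceeds 0.75, which are vanishingly rare under
the defaults) picks the side of the threshold, and the OOP amount is drawn
from the log-normal truncated to that side. The CHE flag is never set
directly: it emerges from the chain downstream. The derived covariates in
`true_beta` (economic quintile, size class) are computed internally from
the generator's own monetary draws with the same ranking rule the
preprocess stage uses. Default `true_beta` values mirror the odds ratios
such studies report (inpatient ln 2.73, outpatient ln 2.16, malignant
tumour ln 2.02, UEBMI ln 0.49, ...).

What passing tests on this generator do **not** show: robustness to
correlated covariates beyond the built-in age/member-65 link, to informative
missingness (missingness here is completely at random), to reporting error
in monetary fields, or to any real survey's joint distribution. Parameter
recovery is exact in expectation *by construction*; on real data the
logistic model is an approximation like any other.

Two small gaps between generation and analysis exist deliberately: the
generator's internal poverty line and quintiles are computed before
missingness, the analysis recomputes them on the cleaned sample. Both
perturbations are O(1%) and only move households adjacent to a boundary;
the induced attenuation is far below the tolerances used in the tests.

Randomness: one seed; every field draws from its own substream derived from
(seed, field name) via `SeedSequence` spawn keys, so adding a field never
perturbs earlier fields, and identical configs give byte-identical surveys.

`true_che_probability` is the ground-truth oracle: it Monte-Carlo simulates
the monetary mechanism at a fixed covariate profile (default 10^5 draws)
and converges to the closed-form logistic probability.

## Logistic model and diagnostics

- Fitting is maximum likelihood via iteratively reweighted least squares
  with step-halving; convergence when max |score| < 1e-8 or the relative
  log-likelihood change < 1e-10, capped at 100 iterations. Standard errors
  come from the inverse observed information. Wald (not profile) intervals,
  matching standard epidemiological reporting.
- Rank-deficient designs raise an error naming the collinear columns
  (QR diagonal test); perfect separation is detected by a diverging
  coefficient (|β| > 30) or a log-likelihood at machine zero, and raised
  explicitly rather than returned as a huge unstable estimate.
- Hosmer–Lemeshow: households sorted by fitted probability, split into 10
  near-equal groups; tied probabilities never straddle a boundary, so group
  sizes may deviate from n/10 and the df is (actual groups − 2) — 8 in the
  standard case. A group with zero expected events or non-events raises
  with advice to use fewer groups.
- VIF is computed per dummy column (least-squares R², VIF = 1/(1−R²),
  exact dependence reported as inf) and aggregated to one value per model
  term by the maximum, since study reports quote one VIF per variable.
  Note the default design carries age and the member-65+ indicator, which
  the generator links mechanistically; their VIFs (~3 on synthetic data)
  stay below the conventional threshold of 5.
- A single multivariable model is fitted (no univariable screens, no
  multiple-testing adjustment — deliberately, to match standard practice in
  this literature). Sex, marital status, residence, education and
  self-rated health are descriptive-only by default and enter the model
  only with `extended_design=True`.

## Stratified tables

Incidence is the weighted share of CHE households per stratum, reported to
2 decimals in the CSV output. Group comparisons are Pearson chi-square on
the strata × (CHE, no-CHE) contingency table, no continuity correction by
default (Yates available behind a flag), df = (r−1)(c−1). The
disease-by-utilisation analysis produces two separate table families —
condition contrasts within each disease group, and disease-vs-no-disease
contrasts within each condition level — rather than one annotated grid.
The per-quintile summary reports mean monthly *consumption expenditure*
(the survey layout carries no income variable) and incidence for the
chronic subsample and the full sample side by side.

## Problem sizes used in the tests

Unit tests run on constructed examples and 1,000-household random toys.
The simulation checks use the sizes the package's validation design calls
for: parameter recovery over 50 replicates of 20,000-household surveys
(inpatient effect ln 2.73), Hosmer–Lemeshow calibration over 500 replicates
of n = 2,000 under a correctly specified model, and the acceptance script
runs one study-scale survey of 9,186 households. The full suite completes
in well under a minute on one CPU.

## Known limitations

- No survey-design variance estimation (clustering/stratification), no
  penalised or exact logistic regression, no profile-likelihood intervals.
- No alternative CHE definitions (share-of-income denominators, normative
  food baskets) and no impoverishment measures.
- Deterministic supplement rules only; no multiple imputation.
- The generator's missingness is MCAR and its covariates are independent
  except where derived mechanistically; both are simplifications.
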