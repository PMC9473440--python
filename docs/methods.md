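# Methods

`femi` estimates six women's-empowerment domain scores and their composite
(the Female Empowerment Index, FEMI) for first-level administrative
subdivisions (admin-1) from DHS-style household survey microdata, and
carries them to fixed reference years. This note documents the model, the
coding rules, the synthetic-data generator that the test suite uses for
parameter recovery, and the numerical choices made where the design was
genuinely open.

## Domain coding

Every answer is coded on [0, 1], 0 = disempowerment, 1 = empowerment.
Domains are unweighted means of their coded components; a component that
was not asked or not answered is dropped from the mean (partial
availability), and a domain with no available component is missing for
that respondent. The rationale for partial availability is sample-size
preservation: only *fully* absent question blocks are handled by
imputation, so discarding a respondent over one unanswered sub-question
would waste information.

| Domain | Components |
|---|---|
| Intimate Partner Violence | mean of (a) share of the five beating-justified attitude questions answered "no" and (b) child marriage: 1 if first married at ≥ 18 or never married, else 0 |
| Family Planning | modern contraceptive use (0/1); denominator restricted to currently married women who do not want a child within two years |
| Reproductive Healthcare | mean of four categories over births in the last 3 years: antenatal visits (0 visits → 0, 1–3 → 0.5, ≥ 4 → 1), professional delivery (0/1), postnatal visit within 2 months (0/1), plus adolescent childbearing (1 if first birth at ≥ 18 or no children) |
| Employment | mean of work regularity (year-round 1, part-year/seasonal 0.5, none 0) and payment type (cash 1, cash+in-kind 0.75, in-kind only 0.5, unpaid 0; unemployed women receive 0) |
| Education | mean of primary completion (≥ 6 years of schooling) and literacy |
| Decision-Making | share of the five household-decision questions answered "self" or "self and partner"; asked of currently married women |

Structural missingness matters for two categories whose coding defaults to
"empowered" when the underlying event never happened: a missing age at
first marriage means *never married* (coded 1) only when the survey
actually asked that question, and likewise for age at first birth and
childlessness. Survey metadata therefore carries an explicit
`question_coverage` set, and the scorers return a missing category when
the question was never fielded. Without this distinction, a survey that
omitted the marriage module would spuriously score 1.0 on the sexual-
violence category instead of producing a missing cell for imputation.

Respondent scores are aggregated to survey regions by DHS sample-weighted
means (a switch disables weighting); `effective_n` counts contributors.
Education and Employment are additionally computed for men and the women's
region score is adjusted by the gender-inequality ratio:
`adjusted = women × (women / men)`, clamped to [0, 1]. The adjustment is
applied at region level to aggregated scores, after imputation (so imputed
men's scores participate), and a men's score of exactly 0 leaves the
women's score unchanged — no male advantage is evidenced and the ratio is
undefined.

Decision-Making uses all five listed decision questions. The age range is
the full 15–49 questionnaire sample; `summaries.cohort_sensitivity`
provides the 18–30 vs 18–49 check that justifies not restricting by age.

## Imputation

Missing (survey, region, domain) cells — typically whole question blocks
omitted by older surveys — are estimated by Random-Forest regression
(scikit-learn, 500 trees, default feature subsetting, fixed seed), pooled
across all surveys, one model per score series. Predictors: survey year,
country (one-hot), region means of age at first marriage, age at first
birth, years of education, respondent age, births in the last five years,
and the region centroid longitude/latitude. The education model drops the
years-of-education mean; men's Education/Employment models use year,
longitude and latitude only. A domain with fewer than 20 observed training
rows is skipped with a diagnostic — below that a pooled fit is too
degenerate to trust, and the threshold also guards the tiny test fixtures.
Feature cells that are NaN (e.g. the marriage-age mean in a survey that
never asked it) are median-filled from the training rows. Predictions are
clamped to [0, 1]; observed cells are never altered. Out-of-bag R² is
reported per model.

Note that a forest only interpolates within the hull of its training
features; cells in regions whose covariates lie outside every surveyed
region's range are predicted at the hull boundary. The FEMI is computed
only after imputation, so all six domains exist for every region.

## Boundary harmonization

Surveys reported on aggregated historical "super-regions" are downscaled
to current admin-1 units in one of two ways:

* **Bracketed** (admin-1 surveys exist before and after): per member unit,
  the year-weighted linear interpolation of the two neighbours,
  `v̂(r) = ((t1−t)·v0(r) + (t−t0)·v1(r)) / (t1−t0)`, then a per-super-region
  multiplicative factor `observed(g) / weighted-mean(v̂)` so the aggregate
  matches the observed value.
* **Single-predictor** (only one admin-1 survey): the predictor survey is
  aggregated onto the super-regions; the per-super-region difference from
  the observed values is added back to each member unit.

Both preserve the observed super-region aggregates exactly (to 1e-9)
before a final clamp to [0, 1]; clamping is applied after, not during,
factor application, so the preservation property is testable. When the
observed super-region value is 0 the multiplicative factor is undefined
and the bracketed method falls back to an additive shift. Aggregation
weights are the predictor survey's sample counts where they exist
(single-predictor case) and female population otherwise (bracketed case —
interpolated values carry no sample counts). Partial-country surveys are
handled generically by per-survey region subsets in the harmonization
plan, not country-specific code; admin-2 data are aggregated to admin-1
by weighted mean. The plan is derived automatically from survey metadata
(bracket when possible, else nearest admin-1 survey) and can be overridden
per survey via YAML.

## Reference-year estimation

For each country and reference year (defaults 1995, 2005, 2015):
**direct** if a survey lies within ±2 years (nearest survey; equidistant
ties pick the later fieldwork), else **linear** — an OLS line through all
of the region's (year, score) points, per region per domain — with two or
more surveys, else **rf**: a Random Forest per domain trained on the
pooled direct/linear region-year estimates with features HDI and maternal
mortality (country-year), population density (region), and the region's
own nearest survey value with a has-survey indicator (median-filled when
absent). Regions left without two usable surveys by partial-coverage
fieldwork fall through to the RF branch even when the country-level rule
says otherwise. All estimates are clamped to [0, 1].

## FEMI and summaries

FEMI is the unweighted arithmetic mean of the six domain estimates per
region-year (`femi_combiner: median` switches to the median). Continental
and national statistics weight regions by female population. Quantiles use
the left-continuous cumulative-weight rule — quantile *q* is the smallest
value whose cumulative normalized weight reaches *q* — which reduces to
the inverted-CDF empirical quantile under equal weights. Subnational
inequality is the p90 − p10 band across a country's admin-1 units;
cross-domain correlations are Pearson correlations over admin-1 units
using each country's most recent survey; national regressions fit FEMI
against HDI, GDI, GII and log10 GDP per capita by OLS.

## Synthetic-data generator

The generator emulates the structure of a multi-country DHS collection:
admin-1 units on a lon/lat grid, latent domain scores with a latitude
gradient (emulating the observed continental north–south gradient), a
linear annual trend (defaults ≈ +0.005/yr for most domains, ≈ 0 for
employment, matching the magnitude of observed decadal change), a
per-country baseline spread (default total range 0.10), and optional
region-level design noise (default sd 0.01). Surveys can use aggregated
region schemes, cover only a subset of regions, or omit whole question
groups; men's latent scores are the women's divided by a gender-gap ratio
(default 0.9). Default sample sizes are 1,000 women and 300 men per
region per survey.

Answer probabilities are solved so the *expected* coded respondent score
equals the latent score: binary components are Bernoulli(latent); work
regularity is the mean of two Bernoulli halves with the cash/in-kind
payment mixture solved to keep the expected payment component on target;
antenatal visit counts are drawn from {0, 2, 4} so the coded expectation
is linear in the latent score. For the child-marriage and adolescent-
childbearing categories, never-married and childless women always code 1,
so the probability for the remaining women is solved *conditionally on the
realized group counts*; the solution exists when the latent score exceeds
the structurally-empowered share (about 0.21 under the defaults), and is
clipped otherwise. Marriage and childbearing are assigned only to women
aged ≥ 18 so that "married/first birth at ≥ 18" draws can never contradict
the respondent's age. Sample weights are 1.0 by default; a lognormal mode
(σ = 0.5, normalized to mean 1) exercises weighted aggregation.

What the generator does **not** emulate: cluster sampling design effects,
nonresponse and interviewer effects, multi-birth histories beyond one
recent birth, within-region covariance between domains at respondent
level, and non-smooth spatial structure. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under idealized
sampling, not robustness to real-survey artifacts.

## Problem sizes used by the test suite

The recovery suites run at desk scale: the synthetic continent uses 10
countries × 5 regions × 3 surveys at 1,000 women per region; the
imputation recovery uses 5 countries × 6 regions × 2 surveys at 150 women
per region over 100 seeds; unbiasedness uses one region at n = 1,000 over
200 seeds. These sizes were chosen so each property is measured well below
its tolerance (binomial standard errors ≲ 0.016 per component) while the
whole suite stays fast.

## Known limitations

* Imputation and RF extrapolation cannot extrapolate beyond the covariate
  hull of their training data; isolated extreme regions are pulled toward
  the nearest trained value.
* The inequality adjustment amplifies sampling error roughly threefold
  near parity (d adjusted / d men ≈ w²/m²), so adjusted-domain estimates
  are noisier than raw ones at equal n.
* Harmonization assumes the member structure of historical super-regions
  is known exactly (crosswalk); geometric areal interpolation is out of
  scope.
* Single-point linear fallback, tie-breaks, and the RF training population
  are conventions chosen here; alternatives (e.g. pooling national trends)
  would be defensible.
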