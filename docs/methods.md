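# Methods

This note documents the models, conventions and numerical choices behind
`anccare`, what the synthetic-cohort generator does and does not emulate,
and the design decisions taken where the published description of the
analysis left the design open.

## The CTP classifier

The Content and Timing of care in Pregnancy tool grades one pregnancy's
visit diary on three dimensions: initiation (gestational age at the
first visit), quantity (occurrences of ultrasound, blood-pressure
measurement and blood screening against guideline lower/upper count
ranges) and timing (whether each recommended gestational-age window
contains at least one occurrence).  The decision table, evaluated in
order, is:

1. initiation after the first trimester → **inadequate**;
2. otherwise, any count below its lower range → **intermediate** if any
   other count exceeds its upper range, else **inadequate**;
3. otherwise → **sufficient** if any timing window is uncovered,
   **appropriate** if all are covered.

Conventions, each of which is configurable or documented because the
tool's published outline does not pin it down:

* **Trimester boundary** — strict comparison: a first visit exactly at
  the boundary (default 14.0 weeks; second boundary 28.0) falls in
  trimester 2.  Gestational ages are decimal weeks; day-precision data
  should be converted as days/7.
* **Counting** — an intervention is a per-visit flag: occurring twice at
  one visit counts once.
* **"Exceeding the range"** — read as exceeding the *upper* count bound;
  interventions configured without an upper bound never exceed.
* **Timing adequacy** — window-*coverage* semantics: every recommended
  window needs at least one occurrence, and occurrences outside windows
  are ignored.  This preserves monotonicity (an extra visit can never
  demote an appropriate trajectory) and matches the reading of a
  recommended schedule.  The alternative reading ("every occurrence
  must fall inside a window") is not monotone and is not implemented.

**Default ranges.**  The original guideline ranges live in national
obstetric guidance and are not printed in the study outline, so ranges
are configuration with illustrative NICE-like defaults (explicitly *not*
guideline-verbatim): US 2–3 with windows [10, 14) and [18, 24) weeks;
BP 7–12 with one window per trimester ([0, 14), [14, 28), [28, 42));
BS 1–3 with window [0, 14); first-trimester boundary 14 weeks.  These
defaults make all four categories reachable, which the test suite
verifies, and the number of windows never exceeds the lower count bound
(otherwise timing adequacy would demand more events than the quantity
minimum — rejected at validation).

## Care indices

**COC** = (Σⱼ nⱼ² − n)/(n(n − 1)); visit order is irrelevant, providers
compare by exact label, no weighting by provider type.  A single visit
makes the formula 0/0 and is defined as 1.0 (one visit is perfectly
concentrated) with a warning.  The dichotomisation puts 0.5 in the
high-continuity band.

**Modified OECD scale.**  The divisor is 1 + 0.5x + 0.3y.  Some survey
codebooks write x as "the number of adults in the household", which
taken literally gives a lone adult the divisor 1.5 and contradicts the
standard modified-OECD scale; the default here is the standard scale
(x = adults beyond the first), with the literal convention available via
`count_first_adult=True`.

**Income bands.**  low < 0.60·median (the at-risk-of-poverty threshold);
moderate spans 0.60–1.20·median with both edges inclusive; high above.
The three bands partition the positive reals (property-tested).

**Education recode.**  ISCED 2011 levels collapse to low (0–2),
medium (3–4), high (5–8); the binary analysis variable is up-to-secondary
(0–4) versus tertiary (5–8).

## Synthetic cohorts

The generator's default configuration encodes the study conditions: two
subsamples of 321 women each — "brussels" (a 2008 metropolitan cohort)
and "dutch_urban" (a 2009–2010 urban midwifery cohort) — with the
published marginal distributions of the predisposing, enabling and
pregnancy-related characteristics, a per-region CTP category mix equal
to the published composition (Brussels 31/26/118/146 and Dutch
18/20/96/187 across inadequate/intermediate/sufficient/appropriate),
and household income drawn log-normally then masked missing-at-random
with cell probabilities depending on occupation × education (0.30/0.20/
0.15/0.08 for unemployed/employed × lower/tertiary education in the
Dutch region, averaging ≈ 15% as reported for that study's income
non-response; none in the Belgian region, where no missing income was
reported).  Income-model location/scale and the national medians (1150
and 1300 currency units/month) are illustrative values chosen to spread
the equivalised-income bands in roughly the published proportions.
Household composition (1–3 adults, 0–3 children) uses a small
categorical distribution — it is not tabulated anywhere and only needs
to exercise the OECD scale.

Within region, variables are drawn independently except for the
constraints that "no partner" on the partner variables coincides with
single marital status, age in years is drawn within the age band, and
income missingness depends on occupation and education.  Each woman's
diary is constructed by inverting the classifier for her drawn target
category; the construction is self-checking (every diary is re-classified
before being returned, so the generator/classifier round trip is exact
by contract), and provably unreachable targets (e.g. *intermediate*
when every lower count range is zero) raise an error naming the
category.

**What passing tests on this generator do not show.**  Covariates are
generated independently of the CTP category, so the synthetic cohorts
carry no true covariate–outcome associations (the determinant model's
operating characteristics are instead validated on outcomes simulated
from a proportional-odds generator with injected log-odds-ratios).  No
correlation structure beyond the ones listed exists — no
assortative partnership, no income–education gradient, no
region-specific age structure — and the diary provider process (a
dominant provider plus up to three others) is a convenience for
spreading COC values, not a model of real referral patterns.  Results on
real registries depend on structure that is absent here by design.

## Pooled-cohort construction

* **Inclusion** — adults strictly over 18, urban density at least
  2500 households/km² (inclusive), low-risk onset of pregnancy; the
  low-risk and urbanicity criteria are taken as input flags because
  their clinical/geographic operationalisation is study-specific.
* **Hot-deck imputation** — m = 5 independent uniform draws with
  replacement from respondents in the same occupation × education cell;
  the completed value is the mean of the draws (the published procedure
  collapses the five imputed sets into a mean income rather than
  analysing them separately, so no Rubin-rules variance pooling is
  performed).  Empty donor cells widen to an education-only class and
  then to the full respondent pool, with each widening recorded in the
  audit log.
* **Exact matching** — donors permuted by seed, treated units processed
  in input order (the published account randomises only the donor side),
  each paired to the first unused donor identical on binary education
  and three-band maternal age.  Matching on the categorical versions is
  deliberate: exact per-category equality across regions after matching
  is what the published balance shows, and year-exact age matching would
  not generally achieve the reported match rate.  Unmatched treated
  units are excluded from the pooled set.

## Bivariate screening

Plain Pearson chi-squared (no Yates continuity correction — the
reproduced p-values 0.009/0.042/0.013 confirm the uncorrected statistic),
p from the χ² survival function at (r−1)(c−1) df.  Validity follows the
Cochran rule: flagged when more than 20% of expected counts are below 5
or any expected count is below 1.  (The published footnote's "and the
minimum expected count is less than 1" is treated as a typo for "not
less than".)  Complete-case per test, with the dropped count logged.
Displayed p-values use three decimals with a "<0.001" floor.

## Ordinal model and selection

* **Orientation** — P(Y ≤ k) = expit(αₖ − x′β): exp(β) is the odds
  ratio of a *higher* adequacy category, so disadvantaged covariate
  levels (relative to the reference levels: tertiary education,
  employed, COC ≥ 50%, attended classes, …) get ORs below 1.
* **Fitting** — direct maximum likelihood: BFGS on a log-increment
  threshold reparameterisation (keeps thresholds ordered), then Newton
  polishing in the natural parameterisation using central-difference
  Hessians of the analytic gradient, until the gradient's infinity norm
  is below 1e-8 (at most 100 polish steps).  Standard errors from the
  inverse observed information; 95% CIs are Wald intervals on the log
  scale, exponentiated.  Any parameter exceeding 20 in absolute value
  (probabilities ~1e-9) is treated as (quasi-)separation and raises an
  error with diagnostics, as does rank deficiency (aliased columns are
  named via pivoted QR).
* **Score test** — the alternative gives each covariate its own slope
  per cut point; the score of that model is evaluated at the
  proportional fit and U′I⁻¹U is referred to χ² on p·(K−2) df.  With a
  binary outcome the test is reported "not applicable".
* **Concordance** — over observation pairs with different outcome
  levels, the share whose fitted latent scores order the same way;
  score ties count as neither and are reported separately (SAS-style).
* **Elimination** — multi-df Wald test per covariate (the SAS-flavoured
  workflow this mirrors); the largest p at or above the 0.05 stay level
  is removed and the model refit, with region never tested.  Survivors
  of each behavioural-model block are fixed for later blocks.
* **Collinearity** — VIF per design column from auxiliary least-squares
  regressions; flagged above 10; aliased columns get infinite VIF.

**Partner variables.**  Because "no partner" on partner education and
partner nationality coincides exactly with single marital status, the
dummy blocks of marital status and either partner variable (or the two
partner variables together) are linearly dependent, and the rank check
refuses such designs.  The default model blocks therefore include
marital status but not the partner variables, which remain in the
bivariate screening tables.  This mirrors the published final model, in
which the partner variables are likewise absent.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks use sizes chosen to keep the full suite under a
minute of fitting time while leaving comfortable statistical margins:
score-test size uses 1000 replicates at n = 400 (acceptance band
0.025–0.075 around the nominal 0.05); noise-retention under backward
elimination uses 500 replicates of four null binary covariates at
n = 400 (band 0.02–0.10 around the stay level); parameter recovery
injects the published adjusted ORs (0.49, 0.60, 0.67, 0.90) at
n = 10 000 and requires recovery within 3 standard errors.  The fit is
cross-checked against an independent ordered-logit implementation to
1e-6 in log-likelihood, and the chi-squared statistic against a
textbook double-loop oracle to 1e-10 relative error.

## Known limitations

* The published adjusted odds ratios themselves are not reproducible
  without the undeposited raw data; the package validates parameter
  *recovery* under the published effect sizes instead.
* The CTP default ranges are illustrative; users analysing real diaries
  must supply their national guideline ranges via the configuration
  file.
* Hot-deck draws are uniform within cell (no distance metric), matching
  the simplest faithful reading of the published procedure.
* The score test uses the observed (not expected) information, via
  numerical differentiation of the analytic gradient; on small samples
  with sparse cells it can be conservative.
* No partial-proportional-odds fallback is provided when the score test
  rejects; the test's result is reported for the analyst to judge.
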