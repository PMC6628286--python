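# Methods

## E-DII scoring

The energy-adjusted dietary inflammatory index converts each food
parameter's raw daily intake to a density per 1000 kcal of **total** energy
(alcohol-derived kilocalories included, at 7 kcal/g ethanol; the alcohol
parameter itself is densified the same way). The density is standardised
against the reference global mean and SD, mapped through the standard
normal CDF to a proportion in (0, 1), centred and doubled to a symmetric
score in (−1, 1), weighted by the parameter's inflammatory effect score,
and summed. Including alcohol in the energy denominator is a documented
convention of this implementation — the alternative (densifying by
non-alcohol energy) appears in the analysis layer only as a sensitivity
adjustment covariate.

The CDF is the default proportion map; an empirical mid-rank percentile
variant is available in the vectorised scorer
(`score_intake_frame(..., method="empirical")`) for cohorts that do not
trust an external reference. Parameters absent from a subject's data are
*skipped*, not imputed as zero intake — zero intake is a strong statement
about a diet, absence of measurement is not — and the number of parameters
used is reported per subject.

Consequences used as test invariants: the score is exactly zero for a diet
at every global mean; it is invariant under isocaloric scaling (all intakes
and energy multiplied by the same constant); it is strictly bounded by the
sum of absolute effect scores; it is monotone in any single parameter's
intake in the direction of that parameter's effect score; and it
decomposes exactly into the per-parameter contributions.

All arithmetic is double precision with no intermediate rounding; CSV
output is rendered at 6 significant digits.

## NEAC scoring

Total dietary non-enzymatic antioxidant capacity is the gram-weighted sum
of per-item TEAC contents, grams/day ÷ 1000 × mmol TE/kg, giving mmol
Trolox equivalents per day. Totals are computed with and without
coffee-flagged items; the **without-coffee** total is the default exposure
(coffee's enormous TEAC content otherwise dominates the between-subject
variance). Items missing from the TEAC table are skipped with a logged
count; a subject matching no item at all is an error. The operation is
linear and additive over disjoint item sets, which the property tests
exploit.

Units: contents are mmol TE/kg and totals mmol TE/day throughout. (Source
tables in the literature occasionally print µmol where the magnitudes imply
mmol; this package standardises on mmol and leaves unit reconciliation of
external tables to the user.)

## Quartiles, profile and combined category

Exposure categories are quartiles of the **control** distribution, computed
sex-specifically when both sexes are analysed. The percentile estimator is
linear interpolation between order statistics (the "type 7" rule, numpy's
default); intervals are closed above / open below (Q1 iff value ≤ q25, Q4
iff value > q75). Both choices are conventions — quartile counts near ties
depend on them — and are fixed here so that results are reproducible.
Cases never enter cutpoint estimation, so adding or removing cases cannot
move any subject's category.

The combined inflammatory–antioxidant profile assigns 0–3 to ascending
E-DII quartiles, 3–0 to ascending NEAC quartiles, and sums: 0 =
anti-inflammatory and high-antioxidant, 6 = pro-inflammatory and
low-antioxidant. The four-level median cross-classification uses the same
closed-above rule ("low" E-DII means ≤ median; "high" TEAC means > median)
with the low-inflammatory / high-antioxidant cell as the reference.
Degenerate control distributions (all values tied) saturate to Q1 with a
logged warning rather than failing.

## Logistic analysis layer

Models are unconditional logistic regressions estimated by IRLS
(statsmodels GLM/binomial; relative tolerance 1e-10, at most 100
iterations). Confidence intervals and p-values are Wald,
exp(β ± 1.96·se) — the style of most published case-control tables.
Categorical covariates are dummy-coded against a declared (or first
sorted) reference level; an explicit "unknown" level is retained as its
own dummy, never dropped, and genuine missing values cause row-wise
exclusion with a count. Rank-deficient designs and separation (detected by
diverging estimates) raise errors naming the offending terms.

Trend tests enter the quartile index itself (1–4) as a single continuous
term — not quartile medians — and report its Wald p. Interaction is tested
by a likelihood-ratio test between the covariate-adjusted model (modifier
as main effect) and the same model plus exposure × modifier products;
degenerate products (constant or duplicating an existing column) are
dropped, and a modifier with no contrast yields statistic 0, df 0, p 1.
Stratified analyses drop the stratifier from the covariate set and skip
strata lacking both outcome levels. The sensitivity suite refits a final
model (1) excluding cases interviewed more than 6 months after diagnosis,
(2) further adjusted for non-alcohol energy and alcohol grams, and
(3) restricted to non-drinkers. No multiple-testing correction is applied
(single-test significance at p < 0.05 is the field's reporting
convention); reports carry the number of tests run.

The crude 2×2 cross-product OR with Woolf CI serves as an independent
oracle: on any saturated binary design the regression must match it to
relative 1e-6, which the tests assert — including on a published
highest-versus-lowest category contrast (499/790 vs 642/1404, OR 1.3814).

## Synthetic-study generator

The generator emulates the *structure* of FFQ-derived case-control data,
not real dietary patterns. Each subject has a latent bivariate standard
normal (F, G): F is the pro-inflammatory diet axis, G the antioxidant
axis, correlated at the configured value (default −0.32, the inverse
relation typically observed between the two scores). Parameter densities
are lognormal with the reference global mean/SD as moments (nonnegativity
guaranteed), loaded on F at 0.85 through a Gaussian copula with the sign
of the parameter's effect score; item grams are lognormal with CV 0.6,
loaded on G at 0.90. Alcohol is a zero-inflated lognormal (30%
non-drinkers; drinker mean 15 g/day, SD 16), independent of the latent
axes. Non-alcohol energy is lognormal with mean 1805 kcal/day and SD 535;
raw intakes are density × total energy / 1000, so scoring recovers the
planted densities exactly.

Because E-DII and NEAC are nonlinear transforms of the latents, the
realised correlation between the *computed* scores is mildly attenuated
relative to the latent value; with the default loadings the attenuation is
a few hundredths (realised ≈ −0.28 to −0.30 for a configured −0.32),
inside the ±0.05 calibration band asserted by the tests. Latent
correlations beyond ±0.95 are rejected up front as infeasible for this
marginal structure. The analytic expectation of the generated E-DII
(1-D Gauss–Hermite quadrature per parameter, a 2-D mixture integral for
alcohol) is exposed as `expected_edii_mean` and used as the closed-form
oracle for Monte-Carlo means.

Case status is drawn from logistic(α + β·exposure + γ′·covariates
[+ interaction]), with the exposure either the computed E-DII (default
planted OR 1.14 per point) or the 0–6 profile (default planted OR 1.10 per
point); α is solved by root-finding to hit the requested case fraction
(default 0.35 of 5299 subjects). Covariate marginals (52% male, age
63 ± 12, BMI 26.6 ± 4.4, 4-level education and activity, 3-level smoking,
no/yes/unknown family history and NSAID use across five study areas) and
their moderate log-odds effects are calibration conveniences loosely
mirroring a population-based study of this design, not estimates. For the
profile exposure, generation uses sex-specific whole-sample quartiles
(control-based quartiles are definable only after case status exists); the
analysis layer then recomputes control-based quartiles on the realised
study, a slight exposure-misclassification that attenuates recovered
effects by well under the Monte-Carlo tolerance at the sizes used.

Covariates are generated independently of diet, so they are
non-confounding by construction; fitting the *same* conditional model used
for generation recovers β despite the non-collapsibility of odds ratios.
One integer seed drives a master `SeedSequence` with per-stage spawned
sub-streams: identical config + seed gives bit-identical tables.

What passing tests therefore show: the scoring algebra, category
construction and estimation machinery are correct, and effects planted at
published magnitudes are recovered at realistic sample sizes. What they do
not show: anything about FFQ measurement error, real food-pattern
correlation structure, selection or recall bias — none of which the
generator models.

## Problem sizes and numerical choices

Simulation-based tests use 20000 subjects for parameter recovery (fitted
SE ≈ 0.004–0.008 on the log-OR, so 3 SE is a tight band around the planted
value), 10000 for calibration checks (correlation SE ≈ 0.01), 1000
replicates of n = 250 for null-calibration of the trend and LRT rejection
rates, and 20 seeds of n = 4000 for interaction power; these sizes keep the
whole suite under a minute while leaving Monte-Carlo error far below the
asserted tolerances. The LRT statistic is clipped at zero against roundoff;
quartile boundary ties follow the closed-above rule exactly; the intercept
search brackets α in ±30 log-odds and reports unattainable case fractions
as errors.

## Known limitations

* The bundled reference and TEAC tables are synthetic placeholders; results
  computed from them are structurally, not nutritionally, meaningful.
* Conditional (matched-set) logistic regression is out of scope; controls
  are assumed frequency-matched and handled by covariate adjustment.
* The empirical-percentile E-DII variant is sample-dependent by design and
  should not be compared across cohorts.
* Profile-likelihood CIs are not implemented; Wald intervals can be
  anti-conservative near separation (which is instead reported as an
  error).
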