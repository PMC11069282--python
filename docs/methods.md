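# Methods

This note documents the models, parameter choices and numerical conventions
behind `glycostrat`, and what the synthetic-data-driven tests do and do not
establish about real cohorts.

## Glycemic indexes

For one admission with glucose series `g₁..g_m` (mg/dl) and admission HbA1c
`A` (%):

- pre-admission mean glucose `eAG = 28.7·A − 46.7` (ADAG linear
  regression; slope/intercept are configurable so other published linear
  maps can be swapped in). The domain is restricted to `A ∈ [4, 15]` % —
  outside it the linear relationship is not physiologic.
- `in_mean`, `in_median` — arithmetic mean and sample median of the series.
- `in_sd` — sample standard deviation with the n−1 denominator. The series
  is a finite sample of the patient's underlying glycemic process, so the
  unbiased-variance convention is used; it is configurable (`ddof`) because
  source analyses rarely state which denominator they used, and a cutoff
  printed to two decimals cannot adjudicate it.
- `in_cv = 100·in_sd/in_mean`, `est_pre_cv = 100·in_sd/eAG` (both %),
  `ratio_in_pre = in_mean/eAG`. `est_pre_cv = in_cv` exactly when the
  in-hospital mean equals the HbA1c-derived mean — a tested identity.
- Hirsch rule: `hirsch_ok = (3·in_sd ≤ in_mean)`, the "SD no more than one
  third of mean" heuristic for acceptable control.

Charlson comorbidity index: original weights (1/2/3/6 point tiers), CKD
mapped to 2 (the cohort label is moderate-or-severe), exactly one diabetes
term (uncomplicated 1 / complicated 2) may contribute, and the optional age
adjustment adds 1 point per decade from 50, capped at 4. Non-age-adjusted by
default.

Inclusion filters (in order, first failure recorded as the exclusion
reason): ≥ 12 glucose determinations; stay ≥ 2 days; HbA1c present.

## Synthetic cohort generator

The generator is the package's study-conditions module: its defaults are the
published cohort marginals (n=120; mortality 17/120; age 78.4 ± 8.9 y
truncated at ≥ 18; HbA1c 7.0 ± 1.6 % truncated to [4, 15]; male 60%;
smoker 36.7%; the stated comorbidity prevalences; home-treatment categories
at their printed frequencies, normalized because the printed counts sum to
119; in/pre-hospital glucose ratio 1.12 ± 0.27 truncated to [0.3, 3]).
Truncated normals are moment-matched — location and scale are solved by
root-finding so the post-truncation mean and SD equal the targets —
because naive truncation of N(7, 1.6) at 4 would shift the HbA1c mean to
7.15.

Per patient, the glycemic process is latent-first: `eAG` from the drawn
HbA1c; a latent in-hospital mean `eAG · ratio`; a latent CV drawn uniformly
from 10–45% (chosen so the in-hospital CV distribution brackets the
published 25.8% cutoff and its mean matches the cohort-level SD/mean of
~28%). The observed series is lognormal noise with those two moments
(lognormal keeps glucose positive), clipped to 30–600 mg/dl, four slots per
stay day (breakfast/lunch/dinner/bedtime).

Death is Bernoulli from a logistic model: user-specified log-odds
(`effect_log_odds`, defaults: hemiplegia 2.5, dementia 1.3, male 1.0,
est_pre_cv 0.06 per percentage point — directions mirroring the clinical
findings, magnitudes chosen to be detectable at n≈120 without separation at
n=10⁴) plus an intercept calibrated by monotone root-finding so the mean
predicted probability equals the target mortality rate. Length of stay is
lognormal given outcome (deceased 9.3 ± 4.6 d, survivors 15.5 ± 12.6 d,
floor 2 d); for deceased patients the stay is the day of death, and the
timing of death within the stay is otherwise not modelled (it is a
configuration choice, not a fitted quantity). Comorbidities are drawn
independently — only marginals are published.

`simulate_cohort` also returns the latent covariate frame. Planted-effect
recovery is tested against the latent values: refitting against re-derived
sample summaries would attenuate coefficients through measurement error,
which is a property of the noise model, not of the fitters under test.
Because the death model is logistic (no true hazard ratios exist), Cox
recovery uses `simulate_survival_times` — exponential proportional-hazards
times over generator covariates, censored at 30 days.

What the generator does not emulate: comorbidity correlations, within-day
glucose structure (meal effects, insulin titration dynamics), informative
censoring, or any joint distribution beyond marginals + planted effects.
Passing tests therefore certify the *methods* (estimators recover what was
planted; identities hold; pipelines are deterministic), not clinical claims
about real cohorts.

## Stratification statistics

ROC curves are built with thresholds at midpoints between adjacent distinct
scores, bracketed by ∓∞ endpoints; "score ≥ threshold" predicts death. AUC
is the trapezoid over the staircase, which equals the Mann–Whitney
concordance U/(n₁n₀) — an identity the tests verify against both an
enumeration and scikit-learn. The optimal cutoff minimizes
√((1−sens)² + (1−spec)²); ties break toward the lower (more sensitive)
threshold, and the infinite endpoints are not candidates since they define
no split. Midpoint thresholds are why a published cutoff like 42.55 mg/dl
falls *between* observed values.

Tests: Pearson chi-square on 2×2 tables without continuity correction
(validated against published p-values 0.039/0.006/0.025, which match the
uncorrected statistic on the printed counts); Mann–Whitney two-sided, exact
enumeration when both groups have n ≤ 8, tie-corrected normal approximation
otherwise; Welch t with Satterthwaite df. Continuous variables route to the
t-test only when a Lilliefors + Shapiro–Wilk screen passes in both groups
(either test rejecting at α = 0.05 → non-normal); Mann–Whitney is the
default, matching standard practice for skewed clinical variables. Report
percentages are rounded half-up to one decimal, matching the printed-table
convention. No multiple-testing correction is applied anywhere, mirroring
the source analysis. Two published stratification p-values (0.06, 0.14) do
not match any standard uncorrected chi-square on their printed counts
(0.055, 0.135 here) and are not asserted at printed precision.

## Risk models

Logistic regression: Newton–Raphson/IRLS with step-halving (log-likelihood
never decreases), convergence at max |score| < 1e-8 or 100 iterations,
rank-revealing-QR naming of collinear columns, Wald CIs `exp(β ± 1.96·SE)`.
Separation is *flagged* (any |β| > 15) rather than penalized: unpenalized ML
mirrors the SPSS-style output of the source analysis, whose odds ratios in
the tens with CIs spanning hundreds are exactly near-separation artifacts.
Firth correction is deliberately out of scope.

Cox model: Newton on the Efron-tie-corrected partial likelihood (many
same-day deaths are expected at daily resolution), administrative censoring
at 30 days, event time = day of death, survivors censored at
min(stay, 30). Risk-set sums are cumulative sums over descending time
(O(n·p²) per evaluation); single-event tie blocks — where Efron equals
Breslow — are vectorized. Survival curves use the Breslow baseline
cumulative hazard evaluated at covariate means with the stratum flag set to
0/1: `S(t|x) = exp(−H₀(t)·e^{x'β})`. At β = 0 this is the Nelson–Aalen
survival estimate, which agrees with Kaplan–Meier asymptotically but not
exactly; the null-model test asserts closeness, not identity. Whether "days
of stay" in a mortality model is a legitimate covariate or the censoring
time itself (an immortal-time concern) is a design question the package
leaves to the caller: the covariate set is configurable.

## AdaBoost-FAS

Order of operations: stratified 75/25 split (per-class rounding) → min-max
parameters fitted on training rows, applied frozen to test with clipping to
[0, 1]; constant continuous features dropped → SMOTE on the training set
only (k = 5 neighbours, the method's canonical default, reduced with a
warning if the minority is smaller; synthetic rows are flagged and any
attempt to evaluate on them raises) → FAS: squared terms for continuous
features, products for every unordered feature pair (binary×binary products
are logical ANDs and stay binary) → L1-logistic selection → boosting on the
selected columns.

LASSO selection solves the liblinear L1 path over 20 log-spaced penalties,
choosing λ by stratified 5-fold cross-validated log-loss with the
one-standard-error rule — the sparsest λ within one SE of the minimum. The
plain CV minimum was evaluated and drags pure-noise features along, which
defeats the selection-consistency property the augmented feature space
needs. Selection never returns empty: under full shrinkage the single
largest-|coefficient| feature at the smallest λ is kept.

Boosting is discrete AdaBoost, L = 100 rounds by default (configurable; the
choice is conventional), exhaustive search over (feature, midpoint
threshold, polarity) plus the two *constant* stumps (threshold +∞) — the
stump a depth-1 CART produces when both leaves share a majority class.
Without that intercept learner the ensemble cannot represent class-prior
offsets; concretely, the XOR-with-interaction-feature construction is only
separable through it. Ties in weighted error break toward (constant, lower
feature index, lower threshold, polarity +1) for determinism.
`α = ½·ln((1−ε)/ε)`, capped at ε = 1e-10 on a perfect stump (then training
stops); training also stops when no stump beats ε < 0.5. Prediction is
`sign(Σ αₗ gₗ(x))` with margin 0 resolved to the surviving (majority)
class. AUC is computed on the real-valued margin, never on hard labels.

Model reliance for base feature f: resample f's test column with
replacement from its own values, *recompute every derived feature with
parent f*, re-evaluate; reliance = mean perturbed error / baseline error
(∞-flagged when the baseline error is zero), with a standard error over
repeats. Reliance is meaningful on held-out data: in-sample, an overfit
model genuinely relies on noise features, so the inert-feature ⇒
reliance → 1 property only holds out of sample. Base features are perturbed
(with re-derivation) rather than engineered columns directly, so the report
reads in the original clinical variables.

The ML feature set excludes length of stay (not available prospectively at
admission) and the estimated pre-hospital CV (the stratification index
under study is kept out of the classifier). Baselines: Majority, CART
(Gini, depth 5), CART-FAS, LASSO-FAS logistic at a 0.5 threshold, and
AdaBoost without FAS, all evaluated with the common metric set
(sensitivity = recall on the deceased class; balanced accuracy =
(sens+spec)/2).

## Pipeline and reproducibility

A single global seed fans out to per-stage child seeds via
`child = (seed·1000003 + stage_index) mod 2³¹`, so stages can be re-run in
isolation. The manifest hashes the analysis-defining configuration (the
output directory is excluded — it names where results go, not what is
computed) and every output file; two runs of one configuration produce
identical manifests. One subtle determinism requirement: liblinear's
internal coordinate shuffling must be explicitly seeded, or repeated L1
fits within a process drift.

Problem sizes in the test suite and acceptance script: marginal-recovery
and calibration checks use n = 10⁴–2·10⁴ draws; CI-coverage studies use 50
seeds (tests) and 200 seeds (acceptance script) of n = 10⁴ cohorts; oracle
equivalences use 100 random instances with n ≤ 50, p ≤ 5; the full
pipeline runs at the cohort's natural n = 120. The marginal-recovery test
checks ~19 marginals simultaneously and therefore uses a 3.5 SE
family-wise bound rather than 3 SE per variable.

## Known limitations

- Comorbidities are independent in the generator; Charlson-index
  distributions in real cohorts are overdispersed relative to it.
- The classifier metrics on synthetic cohorts depend on the planted effect
  sizes and are not comparable to any published figure; the package's
  claims about the ML arm are mechanism-level (oracle equivalence, FAS/XOR,
  reliance calibration), not performance-level.
- Wald intervals are first-order; with very rare covariates (e.g. 4%-
  prevalence flags at n = 120) near-separation inflates them, which is
  faithful to the unpenalized-ML convention but makes single-cohort odds
  ratios unstable by construction.
- The Hirsch rule, CCI age adjustment and SD denominator are configurable
  precisely because the conventions behind the published values are
  under-specified; defaults are documented above.
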