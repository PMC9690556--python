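# Methods

## Data-generating process

The synthetic cohort emulates a diabetes-registry population with six
baseline covariates, a binary treatment and a binary outcome:

| variable | meaning (analogue) | law |
|---|---|---|
| W1 | sex | Bernoulli(0.6) |
| W2 | age at diagnosis, years | N(60, 8²) |
| W3 | BMI, kg/m² | N(35, 6²) |
| W4 | LDL cholesterol, mg/dL | N(90 if W1=1 else 97, 30²) |
| W5 | insulin use | Bernoulli(expit(−2 + 0.05 W2)) |
| W6 | macroangiopathy | Bernoulli(expit(−12 + 0.50 W3 − W1)) |
| Z | treatment | Bernoulli(expit(−2 + 0.05 W3 − 0.20 W5 + 0.10 W6)) |
| Y | outcome | Bernoulli(expit(−3 + Z − 0.05 W2 + 0.05 W4 − 0.80 W1 − 0.20 W1 W2)) |

Both potential outcomes are drawn with one shared uniform per subject
(U < p ⇒ Y = 1), which guarantees consistency Y = Z·Y1 + (1−Z)·Y0 row by
row and couples the counterfactuals monotonically; the marginal OR is
unaffected by the coupling. Each variable draws from its own child stream
of the root seed, in fixed topological order, so extending the generator
never perturbs existing columns. The true marginal OR of the default
configuration, evaluated by counterfactual Monte Carlo on 5,000,000
subjects, is 1.66 (p1 ≈ 0.189, p0 ≈ 0.123); an independent brute-force
integration of the same equations in the test suite agrees.

Two structural facts shape everything downstream. First, the W1·W2
interaction makes the outcome essentially impossible for the W1 = 1
majority, so events are rare (P(Y=1) ≈ 0.15) and the conditional OR of the
true model (e¹ ≈ 2.72) is far from the marginal 1.66 — strong
non-collapsibility. Second, confounding is negligible by construction: the
crude OR equals the marginal OR to Monte-Carlo precision. The estimator
comparison therefore isolates model misspecification and outcome
missingness rather than confounding control.

## Working (misspecified) models

The simulation study deliberately misspecifies both analysis models:
outcome Y ~ Z + W3 + W4 (W3 is irrelevant; W1, W2 and their interaction are
omitted) and treatment Z ~ W2 + W6 (W2 is irrelevant; W3 and W5 omitted).
The fitted propensity score is consequently nearly uninformative
(sd ≈ 0.04).

A design consequence, verified empirically: because the misspecified score
carries almost no information, pure score-only analyses (Y ~ Z + PS, the
unadjusted matched-sample OR, weighted Y ~ Z) all converge to the crude OR
and stop measuring anything about the propensity-score strategy itself.
The estimator classes therefore default to covariate-retaining forms — PS
adjustment fits Y ~ Z + W3 + W4 + PS, matching fits Y ~ Z + W3 + W4 within
the matched sample, IPTW fits the weighted Y ~ Z + W3 + W4 — so that every
PS method augments the same misspecified outcome model and the comparison
isolates what the score contributes. The score-only forms remain available
(`outcome_spec=None`, or the module-level functions) and are exercised by
the unit tests.

## Missingness mechanisms

MNAR: P(Δ=0 | Y=1) = 0.70; P(Δ=0 | Y=0) is solved per cohort from the
overall-rate constraint using the cohort's empirical event rate, clamped to
[0, 1] with a warning when infeasible. Masked outcomes are set to NaN; the
potential-outcome columns keep the truth for the harness only. MAR: an
equal-weighted sum score of the standardized covariates (W1–W6 and Z, never
Y) enters a right-tailed logistic P(Δ=0) = expit(score − shift), the shift
solved by root finding so the expected rate meets the target. Covariates
are standardized before weighting because their raw scales differ by two
orders of magnitude (W4 would otherwise dominate). Z is included in the
score, as in multivariate-amputation practice. MCAR is provided for tests.

## Super learner

V-fold stratified cross-validation (default V = 10; V = 5 is used for the
benchmark runs and is the pragmatic choice at these sample sizes);
candidate probabilities are stacked by non-negative least squares on the
out-of-fold predictions and normalized to the simplex (a negative
log-likelihood meta-learner is available via `meta="nll"`). A failing
candidate is given weight zero with a logged warning. Library presets:
`tmle1` = {main-terms GLM, bidirectional-AIC stepwise GLM, GLM with all
pairwise interactions}; `tmle2` adds stepwise-with-interactions, a logistic
GAM (unpenalized B-splines, 4 df per continuous covariate, linear in
binaries, inputs clamped to the training range at prediction), a random
forest, and a CART tree pruned at 1% of the root Gini impurity
(rpart-style cp with minsplit 20). The forest default is 100 trees with
minimum leaf size 5: at benchmark sample sizes the fit is dominated by tree
construction and the error of the stacked ensemble is insensitive to more
trees, while the Monte-Carlo loop is linear in them. "Interaction terms"
means all pairwise products of the supplied covariates. Stepwise selection
is bidirectional on AIC from the intercept-only model over the main terms
(plus pairwise products in the interaction variants).

## TMLE

Nuisance fits: Q⁰ on observed-outcome rows (covariates: treatment plus the
outcome working-model set), g on all retained rows, and — in IPW mode — the
missingness model d = P(Δ=1 | Z, W) on all rows with covariates Z plus the
outcome-model set (the Δ-model's regressors are a genuinely open design
choice; this one is flagged for sensitivity analysis and configurable via
`d_covariates`). In CC mode, rows with Δ = 0 are dropped before anything is
fit and d ≡ 1. Bounds: g and d truncated to [0.025, 0.975], Q⁰ to
[0.0005, 0.9995] (canonical defaults; configurable).

Fluctuation: a single offset-logistic step with no intercept. The default
update uses one coefficient per treatment arm (columns 1{Z=1}/(g·d) and
1{Z=0}/((1−g)·d)), which solves both arm-specific efficient-score equations
exactly, so the empirical mean of each influence-curve column is zero to
numerical precision — the convention of standard TMLE implementations. The
textbook single-ε update on the signed clever covariate is available via
`fluctuation="combined"` (it zeroes only the contrast's score), and
`fluctuation="none"` gives the plug-in G-computation from Q⁰, used by the
tests as the null-fluctuation identity.

Inference: IC_a = 1{Z=a}·Δ·(Y − Q*)/(gₐ·dₐ) + Q*(a, W) − p̂ₐ; the variance
of log mOR follows by the delta method from the empirical 2×2 covariance of
(IC₁, IC₀); CI on the log scale, then exponentiated. Agreement with a
nonparametric bootstrap is verified in the tests (within 25% at n = 2000).

Note on IPW mode under MNAR-by-Y: Δ depends on Y itself, so
P(Δ=1 | Z, W) is not the true observation mechanism and consistency is not
guaranteed; empirically the IPW-weighted targeting still removes most of
the complete-case bias in these scenarios, which is the property the
harness asserts (|bias IPW| ≤ |bias CC| ≤ |bias LR|).

## Monte-Carlo harness

Per replicate: generate → ampute → run each method; complete-case methods
see only Δ = 1 rows; TMLE follows its `missing_mode`. Per-replicate seeds
derive from the scenario seed by counter-keyed spawning, so runs are
reproducible bit for bit and parallelizable in principle. Summaries report
the mean OR, bias = mean OR − true OR (a positive bias means
over-estimation), the empirical SE (SD of estimates across
replicates — the mean model-based SE is logged alongside), and 95% nominal
coverage. A method failing in more than 5% of replicates aborts the run;
isolated failures are logged and excluded with counts reported.

Rubin's rules (`rubins_pool`) are included as a utility for multiply-imputed
real-data analyses: pooled point = mean, total variance W̄ + (1 + 1/m)B,
Barnard–Rubin degrees of freedom when a complete-data df is supplied.

## Problem sizes and numerical choices

The acceptance script uses 200 replicates per scenario (100 for the
seven-learner TMLE2 variant) with 5-fold super-learner CV; the test suite
uses 100–150 replicates with Monte-Carlo tolerances computed from the
realized empirical SE (3·SE/√reps). The truth is always recomputed at
5,000,000 subjects in chunks of 1,000,000. Logistic fits are unpenalized
maximum likelihood; zero-variance covariates are dropped with a warning
(aliased with the intercept); perfect separation raises an error naming the
offending covariate when one column separates on its own. Matching is
greedy, deterministic (treated in descending propensity, ties by row
index), without replacement, caliper 0.15 pooled-sample SD of the logit
score. IPTW truncates scores to [0.001, 0.999].

## What the generator does and does not emulate

It fixes a registry-like dependency structure with realistic effect sizes,
event rarity and missingness patterns; it does not include covariate
missingness
(real cohorts need imputation before these estimators — hence the pooling
utility), measurement error, time-varying treatment, or clustering.
Passing tests demonstrate correct implementation of the estimators and
their comparative behaviour under this specific misspecification pattern,
not performance guarantees on arbitrary observational data.

## Known limitations

- TMLE IPW mode treats the missingness model as MAR-given-(Z, W); under
  MNAR-by-Y its bias reduction is empirical, not guaranteed.
- The stepwise learners use AIC over a fixed scope; with many covariates
  the interaction scope grows quadratically.
- Coverage estimates at 100–200 replicates carry ±3–5 percentage points of
  Monte-Carlo noise.
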