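# tmlebench

Marginal treatment-effect estimation for a **binary outcome that may be
missing not at random**, under **misspecified working models** — the setting
of real-world pharmaco-epidemiology cohorts (the motivating example is a
type-2-diabetes registry comparing two glucose-lowering drug classes on a
composite cardiovascular risk endpoint, where roughly half the outcomes
were never measured at follow-up).

The package provides, as scikit-learn-style estimators:

- **`LogisticOR`** — covariate-adjusted logistic regression (the conditional
  OR used as a marginal-effect surrogate);
- **`PSCovariateOR` / `PSMatchingOR` / `IPTWOR`** — propensity-score
  adjustment, 1:1 greedy caliper matching (0.15 SD of the logit PS), and
  inverse-probability-of-treatment weighting with sandwich SEs;
- **`TMLE`** — targeted maximum likelihood estimation of the marginal odds
  ratio with a missingness-aware clever covariate and a **`SuperLearner`**
  (cross-validated NNLS stacking over GLM, stepwise-AIC, interaction,
  GAM, random-forest and CART candidates);
- a fully specified **synthetic cohort generator** (`dgp`), an outcome
  **amputation** module (MNAR / MAR / MCAR), and a Monte-Carlo **harness**
  that reports mean OR, bias, empirical SE and 95% nominal coverage per
  method, plus Rubin's-rules pooling as a utility.

## The estimand and the estimator

Each subject has potential outcomes Y(1), Y(0) under treatment Z ∈ {0, 1}
with covariates W. The estimand is the marginal odds ratio

    mOR = odds(E[Y(1)]) / odds(E[Y(0)]),   odds(p) = p / (1 − p),

which differs from the conditional OR of a covariate-adjusted logistic
model even without confounding (non-collapsibility). With Δ the indicator
that Y is observed, TMLE proceeds by

1. an initial outcome regression Q⁰(Z, W) = E[Y | Z, W, Δ = 1] (super
   learner, observed rows),
2. a treatment model g(W) = P(Z = 1 | W) and, in IPW mode, a missingness
   model d(Z, W) = P(Δ = 1 | Z, W),
3. a one-step logistic fluctuation with offset logit Q⁰ along the clever
   covariate H(Z, W) = [1/d(Z, W)] · [Z/g(W) − (1 − Z)/(1 − g(W))],
4. plug-in: p̂ₐ = mean over subjects of the updated Q*(a, W), mOR̂ =
   odds(p̂₁)/odds(p̂₀), with the SE from the efficient influence function
   and a Wald 95% CI on the log-OR scale.

The estimator is doubly robust: consistent when either the outcome or the
treatment model is correct.

## Worked example

```python
import tmlebench as tb

frame = tb.generate_cohort(tb.DgpConfig(n=5000, seed=42))      # synthetic cohort
frame = tb.ampute(frame, tb.MissingnessSpec(mechanism="MNAR",
                                            target_rate=0.20, seed=3))

lr = tb.LogisticOR().fit(frame)             # misspecified Y ~ Z + W3 + W4
tm = tb.TMLE(library="tmle1", missing_mode="ipw", folds=5, seed=0).fit(frame)
print(f"LR   OR = {lr.or_:.3f}  CI ({lr.ci_low_:.3f}, {lr.ci_high_:.3f})")
print(f"TMLE OR = {tm.or_:.3f}  CI ({tm.ci_low_:.3f}, {tm.ci_high_:.3f})")
print(f"true mOR = {tb.true_marginal_or(tb.DgpConfig(seed=1)).m_or:.3f}")
```

prints

```
LR   OR = 1.489  CI (1.124, 1.973)
TMLE OR = 1.395  CI (1.072, 1.814)
true mOR = 1.658
```

Both methods estimate the same cohort; across many replicates the
misspecified logistic regression is biased upward (mean ≈ 1.78 at these
settings) while the missingness-aware TMLE centres on the true marginal OR
of 1.66 — single replicates, as here, scatter around those means.

The command line mirrors the library:

```bash
tmlebench simulate --n 5000 --seed 42 --out cohort.csv
tmlebench ampute --mechanism MNAR --target-rate 0.2 --inp cohort.csv --out masked.csv
tmlebench estimate --method LR --method "TMLE1 (IPW)" --inp masked.csv
tmlebench report --scenario 3 --reps 200 --outdir results/scen3
```

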