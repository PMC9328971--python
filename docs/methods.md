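# Methods

This note records the modeling decisions behind `ferropair`: what each
stage computes, the defaults and why, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## The pair encoding

For an unordered gene pair stored in canonical orientation (A, B), A < B
lexicographically, sample *s* scores `I = 1` iff `expr(A, s) >= expr(B, s)`.
Ties score 1 — the tie falls to the non-"lower" branch of the rule. With
continuous expression ties have measure zero, but integer counts and
rounded toy data do produce them, so the convention is fixed and tested.
Canonical orientation matters because downstream Cox coefficients are
orientation-dependent; a deterministic convention makes signatures
comparable across runs.

The indicator uses only the within-sample ordering of two genes, so any
strictly increasing per-sample transform of expression leaves the entire
downstream analysis (pair matrix, selected signature at a fixed seed, risk
scores, groups) bit-identical. The test suite asserts this for log2(x+1),
cubing and within-sample ranks.

**Frequency filter.** Pairs whose indicator mean across the cohort lies
outside the open interval (0.20, 0.80) are removed: a pair that is nearly
always 0 or always 1 cannot stratify patients. Boundaries are strict
(frequency exactly 0.20 or 0.80 is removed); both bounds are arguments.

## Screening

*Coexpression*: Pearson r between each lncRNA and each ferroptosis-related
gene (FRG) on log2(x+1) values across all samples (tumor-only is an
option); the p-value is the exact t transform of r with n−2 df. A lncRNA is
ferroptosis-related when at least one FRG partner has r > 0.4 and
p < 0.001, with signed r — positive coexpression — by default and |r|
behind a flag. Raw p-values are used at this stage (the screen is an
enrichment heuristic, not an inference).

*Differential expression*: log2FC = log2((mean_tumor + 1)/(mean_normal + 1))
on the linear scale (pseudocount 1 avoids division by zero), p from the
two-sided Wilcoxon rank-sum test, q by Benjamini–Hochberg. A gene passes at
q < 0.05 and |log2FC| ≥ 1.5; both thresholds are arguments (fold-change
conventions in this genre vary between 1 and 1.5). The rank-sum test was
chosen over moderated linear models because it is self-contained and
exactly testable by enumeration; the DE stage sits behind one function and
can be swapped.

The BH step-up rule is implemented literally (q(i) = min over j ≥ i of
m·p(j)/j, clipped at 1) and cross-checked against statsmodels in tests.

## Survival modeling

All Cox machinery uses the Efron approximation for tied event times. A
dedicated Newton–Raphson fitter handles the two hot loops — one fit per
candidate pair in the univariate screen and one per candidate threshold in
the cutoff search — with a fully vectorized path for distinct times and a
per-tie-block fallback otherwise; lifelines is the independent cross-check
in tests (agreement to ~1e-5, with our optimum never worse) and remains
the engine for the clinical independence models and the nomogram.
Monotone partial likelihoods (perfect separation) are capped at |β| = 20;
for such fits the reported p-value comes from the likelihood-ratio test,
since the Wald standard error is meaningless there.

*Univariate screen*: single-covariate fits per pair, retained at Wald
p < 0.05 (the threshold is an argument; no multiplicity correction, matching
the genre's practice at this stage).

*LASSO-Cox*: `scikit-survival`'s coxnet path (pure L1), with the penalty
chosen by K-fold (default 10) cross-validated partial-likelihood deviance in
the Verweij–van Houwelingen form, computed with Breslow ties to match the
coxnet objective. Folds are assigned by a seeded shuffle, so selection is
reproducible; λ_min is the default rule with λ_1se behind a flag, and a
zero-penalty override returns all pairs (the unpenalized limit).

*Stepwise multivariate Cox*: backward–forward search from the full
candidate set minimizing AIC = 2k − 2 logPL, with a cache over visited
models. The empty model competes too; when it wins (nothing prognostic),
a typed `EmptySignatureError` propagates and the pipeline returns a result
with no model rather than crashing.

*Risk score*: the Cox linear predictor Σ βᵢ·Iᵢ of the final fit — the only
score formula consistent with multivariate Cox output.

## Time-dependent ROC and the cutoff

Discrimination at horizon *t* uses the cumulative-case / dynamic-control
definition: cases have an observed event by *t*, controls are still at risk
past *t*, and subjects censored before *t* contribute to neither class.
Both classes are weighted by inverse probabilities of censoring from the
Kaplan–Meier estimate of the censoring distribution (G(T⁻) for cases,
G(t) for controls), which makes sensitivity and specificity monotone along
the threshold sweep by construction and reduces the trapezoidal AUC exactly
to the binary AUC (ties counted ½) when no censoring occurs before the
horizon. Horizons are expressed in days, 365.25 per year.

The high/low risk cutoff is the score threshold minimizing the AIC of a
one-covariate Cox model fit to the dichotomized cohort, over all midpoints
between consecutive sorted unique scores; ties resolve to the smallest
threshold, and the full AIC-vs-threshold profile is returned for plotting.
For thresholds that separate the cohort perfectly the partial likelihood is
monotone but bounded, and the AIC is evaluated at its supremum (numerically
at the ±20 cap) — excluding such splits would discard exactly the best
split when the data separate cleanly. A sample whose score equals the
cutoff is low-risk.

## Evaluation

Kaplan–Meier curves and the two-group log-rank test come from lifelines.
Clinical association uses the chi-squared test without Yates correction
(expected counts below 1 trigger a warning, not a Fisher fallback) per
feature against the high/low group, and a rank-sum (Kruskal–Wallis for
multi-level strata) comparison of the scores; age is dichotomized at
65 years; unknown categories are excluded per feature. Group comparisons
use the rank-sum (Mann–Whitney) test throughout — a signed-rank test would
require paired data, which risk groups are not.

The independence Cox models enter the risk score continuously alongside
age (continuous) and dummy-coded categoricals with the first observed level
as reference. Unknown categories, and levels observed fewer than 5 times
(which make the partial likelihood unidentifiable), pool with the
reference. A rank-deficient design is flagged as collinear and reduced to a
maximal independent column subset before the joint fit; if a fit still
fails, it is retried with a light ridge penalty and a warning.

Decision-curve analysis at a horizon derives per-subject risks
1 − S₀(t)^exp(βx) from a one-covariate Cox fit on the score (Breslow
baseline, computed in log space so separated fits cannot overflow), and the
net benefit TP/n − FP/n · p_t/(1−p_t) classifies treated subjects by the
Kaplan–Meier event fraction within the treated subset, which handles
censoring. Treat-all and treat-none references are included.

The nomogram assigns each covariate points linear in β·(value − reference),
scaled so the widest covariate contribution spans 100 points, with the
reference chosen per covariate as the observed value minimizing β·x (so
points are non-negative and the all-reference profile scores 0). Predicted
survival is S₀(t)^exp(lp) with the Breslow baseline of the fit; horizons
beyond the last event time are refused.

## The synthetic cohort generator

The generator emulates exactly the statistical structure the analysis
consumes, nothing more:

- **Expression** is exp2 of a Gaussian model on the log2 scale: gene
  baselines ~ N(5, 1.5²), unit noise. A configured fraction of lncRNAs
  (default 30%) is tied to an FRG as z = r·u_FRG + √(1−r²)·ε, giving
  population Pearson correlation equal to `target_r` (default 0.75) on the
  log scale. A prefix fraction (default 15%) receives a tumor-only shift of
  `de_log2fc` (default 2) log2 units. There are no library-size, GC or
  batch effects: genes without a planted tie are independent, which makes
  the null calibration of the screens exact. Passing tests therefore show
  correctness of the computations under the model's own assumptions, not
  robustness to real-data artifacts.
- **Survival** (tumor samples only, mirroring how public tumor cohorts are
  modeled) is exponential proportional hazards: hazard
  λ₀·exp(Σ β·I(pair)) over the planted pairs, with λ₀ = log 2 / (6·365.25)
  per day. The 6-year baseline median was chosen so that, under the planted
  hazard ratios (cohort-level 5-year survival around 15%, in the range of
  an aggressive carcinoma cohort), follow-up still spans the 5-year
  evaluation horizon. Censoring is an independent exponential whose rate is
  calibrated by bisection so the expected censored fraction matches
  `censoring_rate` (default 30%).
- **Planted pairs** are listed as (gene_a, gene_b, β) with β the log hazard
  ratio of the indicator I(a ≥ b). Pair members are assigned a shared
  baseline mean so the pair's indicator frequency concentrates near ½ —
  planted signal is deliberately frequency-informative, inside the 20–80%
  band. Default recovery conditions: 300 tumor / 30 normal samples, 300
  lncRNAs, 200 mRNAs (50 FRGs), three planted pairs with β = 1.
- **Clinical covariates** (age, gender, grade, stage, T/N/M) are drawn from
  categorical distributions matching a published HNSCC cohort's composition
  and are independent of survival — so the independence Cox model has a
  known answer.
- **Determinism**: one integer seed; each stage draws from its own
  `SeedSequence([seed, stage])` sub-stream, so adding a stage never
  perturbs earlier draws. Same seed ⇒ bit-identical cohorts.

A fixed 8-gene × 10-sample toy (`worked_toy`) with hand-enumerable
correlations, fold changes and pair indicators anchors the unit tests.

## Problem sizes

The test suite and the reproduction script run the full cascade on
300-tumor cohorts with 300 lncRNAs (~900 pairs before filtering), repeat
the recovery experiment over 10–20 seeds, and verify the encoders against
brute-force enumeration on ~1,000 random small matrices; the complete suite
finishes in a couple of minutes on one CPU.

## Known limitations

- The generator's cleanliness (no batch structure, no shared library-size
  factors, exponential hazards) means recovery results bound what the
  method can do under its own assumptions; real cohorts will be harder.
- The univariate screen's p < 0.05 threshold, the λ_min rule and the
  AIC-based cutoff are conventions of the genre, not optimized choices;
  all are exposed as arguments.
- Stepwise AIC selection retains weakly contributing shadow pairs that are
  correlated with true signal (visible in the worked example); the pair
  representation cannot distinguish a planted pair from an equally
  predictive correlated pair.
- The score's group assignment places cutoff-equal scores in the low-risk
  group; with continuous scores this is immaterial, but frozen models
  applied to small panels can produce exact ties.
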