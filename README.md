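# ferropair

Expression-level-free prognostic signatures from rank-based gene-pair
indicators, for survival analysis of bulk RNA-seq cohorts.

## The problem

Prognostic lncRNA signatures are usually linear combinations of expression
values, which makes them fragile across platforms, batches and normalization
pipelines. A rank-based alternative replaces each gene pair (A, B) with a
within-sample binary indicator

```
I(A, B; s) = 1  if  expr(A, s) >= expr(B, s),   else 0
```

which depends only on the ordering of the two genes inside sample *s*. Any
strictly increasing per-sample transform of expression — log, quantile,
rank, unit changes (FPKM vs TPM) — leaves every indicator, and hence the
fitted signature and all risk scores, bit-identical. That invariance is the
point of the representation.

`ferropair` implements the full analysis around this encoding for
ferroptosis-related lncRNAs in a tumor/normal cohort:

1. **Screening** — lncRNAs coexpressed with ferroptosis-related genes
   (FRGs; Pearson r > 0.4, p < 0.001 on log2(x+1) values), then the
   tumor-vs-normal differentially expressed subset (rank-sum test,
   Benjamini–Hochberg FDR < 0.05, |log2FC| ≥ 1.5).
2. **Pair encoding** — all C(n,2) pairs of screened genes as 0/1
   indicators, keeping pairs whose indicator frequency lies strictly inside
   (20%, 80%) — pairs that are nearly always 0 or 1 carry no class
   information.
3. **Signature selection** — univariate Cox screen (p < 0.05) → LASSO-Cox
   with a seeded, cross-validated penalty (λ_min) → backward–forward
   stepwise multivariate Cox minimizing AIC. The risk score of a sample is
   the Cox linear predictor Σᵢ βᵢ·Iᵢ.
4. **Risk stratification** — time-dependent ROC/AUC at 1/3/5 years
   (cumulative-case / dynamic-control, Kaplan–Meier censoring weights); the
   high/low cutoff is the score threshold minimizing the AIC of a
   one-covariate Cox model on the dichotomized groups.
5. **Evaluation** — Kaplan–Meier curves and the log-rank test, chi-squared
   and rank-sum clinical associations, univariate/multivariate independence
   Cox models, survival decision-curve analysis, a nomogram, and risk-group
   comparisons of gene panels (e.g. immune-checkpoint or m⁶A regulators).

Because no public cohort ships with the package, a first-class synthetic
generator (`ferropair.simulate`) produces tumor/normal cohorts with exactly
the structure the method assumes — planted FRG coexpression, tumor shifts,
and survival driven by planted pair indicators under a proportional-hazards
model — so every stage is testable end to end.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort and write TSV tables under `results/`:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_screen_lncrnas.py
python analysis/03_encode_pairs.py
python analysis/04_fit_signature.py --seed 1
python analysis/05_evaluate_signature.py
```

With seed 1 this prints (abridged):

```
cohort: 500 genes x 330 samples (300 tumor / 30 normal)
survival: 213 events, 29% censored
planted pairs: ['LNC0001|LNC0002', 'LNC0003|LNC0004', 'LNC0005|LNC0006']
coexpression screen: 90/300 lncRNAs have an FRG partner at r > 0.4, p < 0.001
differential expression: 43 DEFRlncRNAs (43 up, 0 down) at FDR < 0.05, |log2FC| >= 1.5
pairing: 43 genes -> 903 pairs (= 43*42/2)
frequency filter (20%, 80%): retained 450, removed 453
univariate Cox: 83/450 pairs at p < 0.05
LASSO-Cox (lambda_min, 10-fold CV): 24 candidates
stepwise multivariate Cox: 13 pairs in the signature
time-dependent AUC: 1y = 0.807, 3y = 0.892, 5y = 0.949
AIC-minimizing cutoff = -0.8273: 229 high-risk / 71 low-risk
log-rank high vs low risk: chi2 = 95.89, p = 1.22e-22
risk score in the joint Cox model: HR = 3.13 [2.62, 3.75], p = 5.72e-36
```

Two of the three planted pairs appear verbatim in the fitted signature
(`LNC0001|LNC0002`, `LNC0003|LNC0004`; the third survives through strongly
correlated shadow pairs such as `LNC0001|LNC0006`), the risk groups
separate sharply, and the risk score stays prognostic after adjusting for
age, gender, grade, stage and TNM.

A fitted signature is a plain table of pairs and coefficients; applying it
to a new cohort needs no normalization:

```python
import ferropair as fp

scores, profile = fp.apply_model(model, new_expression, cutoff=0.302)
```

## Layout

```
src/ferropair/        library: io, types, simulate, screening, pairs,
                      cox, model, evaluate, pipeline
analysis/             numbered drivers for the worked study
tests/                pytest suite (unit, property and acceptance checks)
scripts/acceptance.py end-to-end reproduction script
docs/methods.md       modeling choices, defaults and limitations
```
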