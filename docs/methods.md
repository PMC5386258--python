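# Methods

## Data model and notation

Each record is O = (W, Y) with W = (W₁, …, W₂₈) categorical predictors and
Y ∈ {0, 1} the treatment-completion indicator; records are assumed i.i.d.
draws from an unknown P₀ (the real cohort kept only first-treatment
episodes precisely to defend this assumption). The estimand is
Q̄₀(W) = P₀(Y = 1 | W) and model quality is the AUC of the predicted
probability on held-out data.

Dummy coding drops one reference level per predictor — the first level in
schema order, a deterministic convention since the original analysis does
not state its parametrization. The packaged default schema replicates the
published cohort's structure: 28 predictors whose level cardinalities sum
to 163, hence 135 main-effect dummy terms; the ten predictors with
published level counts (age, gender, ethnicity, education, employment,
primary substance, its use frequency and age of first use, SUD type,
referral source, length of stay) carry those categories verbatim, and the
remaining 18 use standard TEDS-D-style category sets.

The train/test split is simple (unstratified) random sampling with
|train| = ⌊fraction · n⌋. At the published N = 99,013 and fraction 0.8
this gives 79,210 training records, matching the printed figure; the
printed test n (19,802) is one short of the remainder (19,803), an
inconsistency in the source we do not attempt to resolve — we always use
the remainder.

## Synthetic generator

No data-generating process is published (the original analysis used real
records), so the generator is this package's own design:

- **Predictors** come from a latent Gaussian copula: each record draws
  equicorrelated standard-normal latents Zⱼ = √ρ·G + √(1−ρ)·εⱼ (one shared
  factor G), maps them through Φ to uniforms, and thresholds each uniform
  at the predictor's cumulative marginal probabilities. This reproduces
  arbitrary categorical marginals exactly (in expectation) with one
  dependence parameter ρ ∈ [0, 1). ρ defaults to 0.15 in the signal
  presets — mild, positive association of the kind administrative
  covariates show; the published tables print no cross-tabulations, so
  any joint structure is necessarily invented.
- **Marginals** for the ten predictors with published counts are the
  empirical shares (e.g. alcohol 51.3% of primary substances); the other
  eighteen use shares we consider realistic for an adult Hispanic
  outpatient first-treatment population (e.g. 57.8% criminal-justice
  referrals are published; we set 3% pregnant, 4% veterans, 25% with a
  recorded mental-health problem, 45%/72% with no secondary/tertiary
  substance).
- **Outcome**: Y ~ Bernoulli(expit(β₀ + Σ main effects + Σ interaction
  effects)), all effects on the log-odds scale attached to specific
  non-reference levels. Interaction entries are indicator products of one
  level pair each; a *threshold* effect (extra boost only when both
  length-of-stay and use-frequency are in their top bands) is expressed as
  the four level-pair entries it covers.
- **Intercept calibration**: β₀ is set by bisection so the Monte-Carlo
  mean success probability (200,000 draws, fixed internal seed) matches
  the target prevalence of 0.452 — the published success rate — within
  0.002. Mean expit(β₀ + s) is monotone in β₀, so bisection on [−30, 30]
  always converges.

### Packaged presets

- `null` — no effects, ρ = 0; for calibration and type-I-error checks.
- `main-effects` — additive log-odds on the ten high-importance
  predictors, signed plausibly (long stays, criminal-justice referral,
  older age help completion; daily use, unemployment hurt) with monotone
  gradients on ordinal predictors.
- `recovery` — additive effects confined to four predictors whose every
  level has ≥ 8% marginal mass. This is the scenario for
  parameter-recovery checks: a coefficient on a level with share q has
  asymptotic standard error ≈ (n·q·p̄(1−p̄))^(−1/2); at n = 200,000 the
  rarest effect-bearing cell here gives SE < 0.02, so a ±0.05 recovery
  band is a 3–4σ criterion. Effects on the sub-1% cells that Table-style
  marginals contain (e.g. hallucinogens 0.3%) are *not* identifiable to
  ±0.05 at that n — SE ≈ 0.1 by the same formula — which is why recovery
  is checked on this preset rather than on `main-effects`.
- `interactions-nonlinear` (default, the "hard" scenario) — the
  main-effects pattern plus five pairwise interactions and the threshold
  effect, all scaled by a single factor of 1.38 calibrated once so that
  the scenario's Bayes-optimal AUC (the AUC of the true probability as a
  score, estimated by Monte Carlo) is ≈ 0.82, the top of the published
  benchmark range. On this preset main-effects regressions are genuinely
  misspecified, so ensemble and interaction-aware methods can win — the
  qualitative ordering of the published comparison.

All randomness flows from one integer seed through named
`numpy.random.Generator` instances; there is no global state, and
generation is reproducible bit-for-bit.

## Screening

**RF importance.** One random forest (50 trees by default, impurity-
decrease importances) is fitted on the dummy-coded training design; a
predictor's importance is the sum over its dummy columns, and ties at the
k-th rank break by schema order. The importance metric is the common
impurity-decrease default; the original platform's metric is unnamed in
the source.

**Interaction screen.** For each of the C(28, 2) = 378 unordered pairs, a
block likelihood-ratio test compares logistic regression with both
main-effect dummy blocks against the same model plus the interaction
block, on df = the number of non-degenerate interaction columns
(all-zero columns from unobserved level combinations are dropped from
block and df). One p-value per pair; a pair is retained when p < α
(α = 10⁻⁴ by default, no multiplicity correction — the threshold itself
is the screen). Pairs whose fits fail (separation, singular designs) are
skipped with a logged warning rather than crashing the run. The screen
runs once on the full training set before cross-validation, matching the
described sequence of the original workflow. A per-pair block test was
chosen over per-dummy-term tests because the screen is described as
testing "their 2-way interaction" (singular) and a block test is well
defined for multi-level factors; retaining a pair adds all its
interaction dummies to the interaction-model design.

## Learner library

Six families behind one contract (fit on a dummy-coded design, predict a
probability): unpenalized logistic regression (lbfgs), lasso / ridge /
elastic-net logistic regression, random forest, and a feed-forward
neural network. Defaults, all overridable per family through the config:

| family | default settings | note |
|---|---|---|
| logistic | lbfgs, max_iter 2000 | no penalty |
| lasso | liblinear, penalty by 5-fold CV on deviance over 7 C values | exact zeros |
| ridge | lbfgs, same CV | keeps all terms |
| elastic_net | saga, mixing 0.5, same CV | balance of the two |
| random_forest | 50 trees, unbounded depth | platform default in the source is unstated |
| neural_net | hidden layers (200, 200), max_iter 200 | see below |

Penalized families standardize the dummy columns internally (penalties
are not scale-equivariant); the coefficient accessor undoes the
standardization so estimates are comparable to ground-truth log-odds.
"Hidden layer sizes of 200" in the source is ambiguous between one layer
of 200 and the referenced platform's default of two; we default to
(200, 200) and both are one hyperparameter away. Passing a fixed `C`
skips the internal CV — the *reduced settings* used by the multi-seed
simulation studies and the analysis scripts (fixed C = 0.5, one 16-unit
hidden layer, 60 ANN iterations) so a full 17-model comparison at
n = 20,000 takes ~40 s on one core instead of minutes. Every stochastic
family derives its random state as pipeline seed + a stable per-label
offset (Adler-32 of the label, mod 10⁵).

The default grid is 6 families × {all predictors, top-k} plus the four
regression families × {all predictors + screened interactions} = 16 base
configurations; the super learner over them is the 17th compared model.

## Super learner

V = 2 folds by default (matching the original workflow; configurable),
balanced random partition, unstratified by default with a stratified
option for small n. Each member is fitted on each fold complement and
predicts the held-out fold, filling Z (n × L). Per-learner CV AUC is
computed within each fold and averaged (not pooled); the discrete SL is
the member with the **maximum** CV AUC — the source's one sentence saying
"minimum" contradicts its AUC-maximization framing everywhere else and is
treated as a typo. Ties break to the lowest index.

The metalearner regresses Y on Z. The source says only "regressing Y";
we default to non-negative least squares on the probabilities with
sum-to-one renormalization — the standard stacking choice: convex,
interpretable weights, and the SL prediction is then a convex combination
bounded by its members. A nonnegative-constrained logistic metalearner
(L-BFGS-B on the bounded log-likelihood, normalized coefficients reported
as weights) is the config-reachable alternative, since the original
platform's regression family is unstated. An all-zero solution falls
back to uniform weights with a warning. Degenerate (constant-prediction)
members are retained with whatever weight they earn; no pre-filtering.

After weighting, every member is refitted on the full training set and
the SL prediction is Σₗ wₗ Q̄ₗ. The whole fit is reproducible bit-for-bit
given (data, config, seed).

## AUC inference

The AUC is computed by midranks in O((m+n) log(m+n)) and equals the
pairwise Mann–Whitney kernel mean exactly, ties counting ½ (the tie
convention of the DeLong framework; the source is silent on ties).
DeLong structural components are also computed from midranks
(within-group vs combined), so the variance is O((m+n) log(m+n)) too and
invariant under strictly increasing score transforms. Confidence
intervals are Wald intervals on the probability scale truncated to
[0, 1]; no logit-scale transform, matching the plain asymptotic method
cited by the source. Reporting mirrors the published precision: AUC to 3
decimals, relative improvement (100·(max−min)/max) to 1 decimal,
variance excess (100·(max/ref − 1)) to the nearest integer. The published
σ² column's absolute scale is implausibly large for AUC variances at its
test-set size and is undocumented in the source; only its ratios (the
variance-excess statistic) are used here.

## Problem sizes in the tests and analyses

The simulation studies run at sizes chosen to make their statistical
criteria sharp while a full run stays in the minutes range on one core:
marginal goodness-of-fit at n = 100,000; prevalence and oracle-AUC checks
at n = 50,000–100,000 Monte-Carlo draws; interaction-screen power (20
seeds) and the oracle-property study (10 seeds, full 16-member library,
reduced settings) at n = 20,000 with an 80/20 split; parameter recovery
at n = 200,000; leave-fold-out integrity at n = 240 where exactness, not
power, is at stake. The oracle-property study feeds its "+ interactions"
models the scenario's true interacting pairs instead of re-screening 378
pairs in every replicate; screening power and calibration are
established separately (planted-interaction detection in ≥ 19/20 seeds;
null retention rate within binomial error of α).

## What the synthetic tests do and do not show

Passing on synthetic data shows the machinery is correct: the encoder,
screens, learners, stacking algebra, and inference behave as specified
under a known truth, and the SL's oracle property holds at realistic n.
It does not show that the packaged scenario captures real discharge
data: true joint dependence is richer than a one-factor copula, real
effects are not confined to a handful of terms, and the published
real-data AUC values, top-10 list, and 257 retained interactions depend
on the restricted records and are not reproducible here. The published
test-set AUC/variance columns are therefore used only for the arithmetic
they directly support (comparison statistics, term bookkeeping).

## Known limitations

- Complete-case ingestion only; no imputation (the original analysis was
  complete-case).
- No paired DeLong test for correlated AUCs and no partial AUC; the
  comparison reports per-model CIs only.
- The interaction screen refits statsmodels logistic models pair by pair;
  at very large n this is the slowest stage.
- No attempt at bit-compatibility with the original H2O implementations;
  defaults here are explicit and documented instead of platform-implicit.
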