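# Methods

## The model

Per-sample risk is modelled through three stacked stages. Stage 1 converts
expression into binary within-sample gene-pair orderings and selects a
sparse prognostic subset; Stage 2 fits a fixed grid of survival learners to
those features; Stage 3 stacks a subset of the learners, chosen by a
genetic algorithm, under a random-survival-forest meta-learner. The output
is a scalar risk score per sample, defined only up to monotone
transformation: it is validated through ranking metrics (Harrell's C,
time-dependent AUC) and group contrasts (median-split log-rank), never
through calibrated absolute risk.

### Pair features

The feature for pair *(a, b)* in sample *s* is `1 if E_a(s) > E_b(s) else
0`. Exact ties emit 0 (the indicator is undefined at equality; a fixed
rule keeps the matrix deterministic, and near-constant columns produced by
heavy ties are removed by the frequency filter anyway). Each unordered
pair appears once, oriented lexicographically. The defining property,
enforced by property tests: applying any strictly increasing function to
all of one sample's values leaves the matrix bit-identical. The property
covers per-sample (hence per-cohort) monotone distortions — scaling,
power transforms, log — but **not** per-gene distortions such as
probe-affinity differences between platforms; the synthetic generator
exposes both regimes so the boundary of the claim is itself tested.

The 20–80 % frequency filter is evaluated on training set 1 only, with
inclusive bounds, and the surviving pair list is frozen for every other
cohort: the pair list is part of the model, not of per-cohort processing.

### Screens and L1 selection

Univariate screens are single-covariate Cox fits with the Breslow tie
convention, Wald p-values, retention at p < α (default 0.05). The solver is
a damped Newton iteration vectorised across features, so screening
thousands of candidates costs milliseconds; it is cross-checked against
lifelines (untied data) and scikit-survival (tied data) in the tests.
Constant features receive p = 1 by definition. Gene-level Cox models (the
gene screen and the unpaired-ablation features) see `log1p` expression:
raw intensity scales are heavy-tailed enough that a handful of outliers
dominates the Wald statistic, and log-scale screening is the field's
standard practice. Pair features are built from raw values — they are
scale-free by construction.

L1-penalised Cox selection uses a 100-point penalty path, log-spaced from
the smallest penalty that zeroes all coefficients down to 1/1000 of it
(coxnet's default path construction), 10-fold cross-validation seeded and
stratified by event, and the Verweij–van Houwelingen cross-validated
partial-likelihood deviance `-2·(l_full(β₋ₖ) − l₋ₖ(β₋ₖ))` summed over
folds. Features with nonzero coefficients at the deviance minimum are
kept. Binary pair features enter unstandardised.

### The learner grid

47 specifications: 3 stepwise Cox + 16 RSF + 6 CoxBoost + 16 GBM + 6
survival SVM.

* *Stepwise Cox* starts from the full model of the Stage-1 features and
  takes greedy AIC steps in the given direction. Starting from the full
  model, "forward" has nothing to add and reduces to the full fit,
  "backward" drops terms, "both" drops and reconsiders — matching the
  semantics of R's `step()` on a full model, which is the conventional
  reading of direction = forward/backward/both.
* *RSF* uses log-rank splits, bootstrap resampling (n draws with
  replacement ≈ 2/3 unique per tree), `max_features="sqrt"`, terminal-node
  Nelson–Aalen cumulative hazards, and ensemble mortality (the cumulative
  hazard summed over the training event-time grid) as the risk score.
  nodesize maps to the minimum terminal-node size.
* *CoxBoost* is componentwise likelihood boosting implemented in-package
  (no Python implementation of componentwise Cox boosting exists): at each
  of `stepno` steps, compute the penalised one-parameter score update
  `U_j/(I_j + λ)` for every feature at the current linear predictor, apply
  the feature with the largest penalised score statistic `U_j²/(I_j + λ)`.
  λ defaults to 9 × (number of events), the canonical default of the
  reference tool. `stepno = 0` leaves all coefficients at zero.
* *GBM* is gradient boosting with the Cox partial-likelihood loss,
  shrinkage fixed at 0.1; only depth and ntree vary, as printed.
* *survsvm* is a linear ranking survival SVM (squared hinge loss over
  comparable pairs); the grid's regularisation value maps to the cost
  weight α on the ranking loss — larger values penalise ranking violations
  harder, matching the cost-parameter role in the classification-form
  objective.

Orientation contract: every family's `predict` returns scores where higher
means higher hazard; this is asserted on steep-signal simulations for all
five families.

### Cross-validation protocol

Training set 2 is split into 10 folds, stratified by event status and
seeded (unstratified splits at desk-scale sample sizes too easily produce
event-free folds). Each fold model scores its held-out tenth — giving each
sample exactly one out-of-fold score — and all of training set 1. A
learner's training-set-1 prediction is the *average over its 10 fold
models*, and the same fold-averaged form is used at predict time on new
cohorts; no refit-on-full is performed (a refit option exists behind the
API). Learners are ranked m1…mL by mean fold C-index, ties broken by
smaller standard deviation, then grid order.

Harrell's C is implemented directly from its definition: pair (i, j)
comparable iff `t_i < t_j` and `event_i = 1`; concordant when
`score_i > score_j`; score ties count ½. A printed shorthand that divides
by "number of samples" rather than comparable pairs is read as the
standard comparable-pair denominator — anything else would not be a
concordance. The implementation is verified against brute-force pair
enumeration on hundreds of random censored instances.

### GA stacking

Individuals are one-hot masks over the ranked learners. Fitness is exactly
1 for masks with fewer than two learners, else `1 − C`, where C is the
concordance of the meta random survival forest (nodesize 30, ntree 100)
fitted on the selected learners' fold-averaged training-set-1 scores. C is
evaluated on the meta-forest's out-of-bag predictions (per sample, average
the per-tree risk over trees whose bootstrap excluded it): in-sample
concordance of a forest is strongly optimistic and would make the GA
reward overfitting masks; an in-sample option remains behind a flag.
Fitness is memoised by mask, since the GA revisits masks constantly.

Operators: tournament selection (q = 2) by default; roulette applied to
the suitability `1 − f` (normalising raw minimised fitness would favour the
*worst* individuals — the cited GA tooling maximises, so the intended
quantity is a suitability); linear rank with default weights
`P_min = 2/(N(N+1))`, `P_max = 2/(N+1)` (the normalised-rank form);
single-point crossover with probability 0.8 and interior cut point I
uniform in {2,…,L−1}; per-individual mutation probability 1/population
flipping one uniformly chosen locus (count configurable); elitism 1.
Population 50, at most 100 generations, early stop after 20 generations
without improvement of the best-ever fitness. The takeover time — the
first generation at which the whole population equals the best individual
— is recorded as a selection-pressure diagnostic. Population size,
generation budget, patience and elitism are package defaults chosen in the
usual GA range; all are config-exposed.

### Evaluation battery

Median splits are per cohort; the median-valued sample goes to the
low-risk group. Log-rank and Kaplan–Meier come from lifelines.
Time-dependent AUC is the cumulative-case/dynamic-control estimator with
Kaplan–Meier IPCW (scikit-survival); horizons are expressed in the
cohort's own time unit and must precede the last observed event. Top-k
no-GA baselines z-score each learner's scores within the cohort before
averaging — the families' native scales (linear predictors, mortalities,
SVM margins) are not commensurable, so raw averaging would be dominated by
whichever family has the widest scale. The PCA batch diagnostic computes
mean-centred PCs of pooled samples (log1p scale for raw expression, as
expression PCA conventionally is) and reports the silhouette of cohort
labels in (PC1, PC2); the batch-correction comparator is a plain per-gene
mean/variance standardisation rather than an external batch tool.

## Synthetic data

The generator emulates the statistical structure the method assumes, with
a known ground truth:

* per-gene log-normal latent expression; the two genes of an informative
  pair share (μ, σ) so the pair indicator sits near frequency 0.5 and can
  survive the 20–80 % filter; informative pairs use disjoint genes so
  recovery is unambiguous;
* true linear predictor η = Σⱼ βⱼ · indicator_j on pre-distortion values;
  event times exponential (Weibull shape exposed) with hazard λ₀·e^η,
  λ₀ = 0.05;
* independent uniform censoring, with the upper bound calibrated by
  bisection so the realised censoring fraction hits the target (default
  0.30) — verified to ±0.03 at n = 500;
* batch distortion on a random stream separate from the biology stream,
  so switching batch models never changes outcomes: `per_sample_monotone`
  applies x → a_s·x^{p_s} with cohort-level a_c log-uniform in [0.25, 4]
  and p_c uniform in [0.5, 1.5] plus per-sample jitter — the magnitude
  emulates cross-platform cohorts (array intensities vs RNA-seq
  abundances), which is exactly the setting the pair features exist for;
  `per_gene_shift` multiplies each gene by a cohort-specific log-normal
  factor and deliberately *breaks* pair features, marking the limit of
  the batch-robustness claim.

What the generator does not emulate: gene–gene correlation structure,
non-proportional hazards, informative censoring, platform-specific
missingness, and real probe-level artefacts. Passing tests therefore show
that the implementation does what the design claims under the design's own
assumptions — not that the score transfers to any particular clinical
cohort.

## Problem sizes and study conditions

Desk-scale conditions used by the tests and the acceptance script, chosen
once:

* recovery benchmark: 3 planted pairs, β = 1.2, n = 400, 60 noise genes,
  20 seeds;
* main end-to-end run: 4 cohorts × 300 samples, 66 genes, full 47-learner
  grid, default GA (population 50);
* repeated ablation comparisons: 4 cohorts × 200 samples, 60 genes,
  β = 1.5, a 7-learner subset drawn from the printed grids and a small GA
  (population 16, ≤12 generations) so that 20 replicates of three full
  pipeline fits stay tractable on one core; both pipeline arms always use
  identical settings, so the comparisons are internally controlled. AUC
  horizons for the overfit-gap measurements are the quartiles of the
  training cohort's event times, with censoring weights estimated per
  evaluated cohort.

## Known limitations

* The stepwise-Cox "forward" direction is a no-op from the full model; it
  is retained because the grid is fixed, but it duplicates the full fit.
* The SVM cost mapping is a convention; only the ordering of the grid
  values matters for the pipeline.
* OOB-based fitness still shares Stage-1 feature selection with the
  evaluation cohort (training set 1); genuinely unbiased performance
  numbers come only from the held-out cohorts.
* With very few selected pairs (p pairs → 2^p distinct feature patterns)
  all learners collapse onto the same coarse partition and the ensemble
  degenerates gracefully to a pattern ranking.
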