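# tristage

Batch-robust survival-risk modelling across transcriptome cohorts, built
around three stages:

1. **Gene-pair featurization + screening (Stage 1).** Every feature is a
   within-sample indicator `1[E_a > E_b]` for a pair of genes *(a, b)*.
   Because the indicator only compares two measurements inside the same
   sample, any strictly increasing per-sample rescaling — library size,
   platform scale, log transforms, the usual face of a cross-cohort batch
   effect — leaves the feature matrix bit-identical, so cohorts from
   different platforms can be scored without normalisation. On training
   set 1 the pipeline runs: univariate Cox gene screen (Wald *p* < 0.05) →
   all pairs of surviving genes → keep pairs whose "1" frequency is within
   20–80 % → univariate Cox pair screen (*p* < 0.05) → L1-penalised Cox
   with the penalty at minimum 10-fold cross-validated partial-likelihood
   deviance. The selected pair list is frozen.
2. **A fixed grid of 47 basic survival learners (Stage 2).** Five families
   over their printed hyperparameter grids — AIC-stepwise Cox
   (forward/backward/both), random survival forests (nodesize ∈
   {5,10,15,30} × ntree ∈ {50,100,200,500}), componentwise Cox likelihood
   boosting (stepno ∈ {50,…,300}, penalty 9 × events), gradient-boosted
   trees with Cox loss (depth ∈ {1,2,5,10} × ntree ∈ {20,50,100,200},
   shrinkage 0.1) and linear ranking survival SVMs (cost ∈
   {0.1,0.5,1,5,10,50}). Each learner is 10-fold cross-validated on a
   *second* training cohort (folds stratified by event status); learners
   are ranked m1…m47 by mean Harrell's C-index, and their fold-averaged
   risk predictions for training set 1 become the stacking inputs.
3. **GA-selected stacked ensemble (Stage 3).** A genetic algorithm searches
   over one-hot learner-inclusion masks; the fitness of a mask is 1 if it
   selects fewer than two learners and otherwise `1 − C`, where `C` is the
   out-of-bag concordance of a random-survival-forest meta-learner
   (nodesize 30, ntree 100) stacked on the selected learners' training-set-1
   scores. Selection (tournament *q* = 2 by default; roulette and linear
   rank available), single-point crossover with probability 0.8, mutation
   probability 1/population, elitism. The final model is the meta-forest on
   the best mask; its per-sample output is the risk score (higher = worse
   prognosis).

The split across two training cohorts is deliberate: features frozen on
cohort 1, learners tuned on cohort 2, ensemble stacked back on cohort 1 —
collapsing everything onto one cohort is the overfitting-prone variant the
ablation tooling quantifies.

The package also ships the full assessment battery (median-split
Kaplan–Meier + log-rank, time-dependent ROC-AUC with IPCW, C-index
comparison tables, no-GA top-k baselines, PCA cohort-separation
diagnostics, pairing and single-training-set ablations) and a synthetic
multi-cohort generator in which hazards are driven by planted gene-pair
orderings with known effect sizes, cohort-specific monotone batch
distortion and calibrated censoring — every stage can therefore be tested
against a ground truth.

## Worked example

```python
import numpy as np
import tristage as ts

cfg = ts.SimConfig(n_cohorts=4, n_samples=300, n_genes=66,
                   n_informative_pairs=3, beta=1.2, seed=7,
                   batch_model="per_sample_monotone")
train1, train2, test1, test2 = ts.simulate_multicohort(cfg)[0]

res = ts.run_pipeline(train1, train2, None,
                      ts.PipelineConfig(seed=7, ga=ts.GAConfig(seed=7)))
print(res.stage_counts)
for c in (test1, test2):
    s = res.ensemble.predict(c)
    print(c.cohort_id, round(ts.concordance_index(s, c.time, c.event), 3))
```

prints

```
{'input_genes': 66, 'screened_genes': 9, 'candidate_pairs': 36,
 'frequency_filtered_pairs': 23, 'screened_pairs': 14, 'selected_pairs': 6}
sim_c2 0.719
sim_c3 0.725
```

i.e. Stage 1 distils 66 genes down to 6 prognostic pairs, and the stacked
ensemble scores two held-out, differently-distorted cohorts with a
concordance of about 0.72 — comfortably above the 0.5 of a random score,
with no cross-cohort normalisation anywhere.

The same flow is available from the shell:

```bash
tristage simulate --seed 7 --out-dir cohorts/
tristage fit --train1-expr cohorts/sim_c0_expr.tsv --train1-surv cohorts/sim_c0_surv.tsv \
             --train2-expr cohorts/sim_c1_expr.tsv --train2-surv cohorts/sim_c1_surv.tsv \
             --seed 7 --out-dir model/
tristage predict --model model/ --expr cohorts/sim_c2_expr.tsv \
                 --surv cohorts/sim_c2_surv.tsv --out scores.tsv
tristage evaluate --model model/ --expr cohorts/sim_c2_expr.tsv \
                  --surv cohorts/sim_c2_surv.tsv --out report.json
```

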