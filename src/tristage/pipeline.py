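"""End-to-end glue: Stage 1 on training set 1, Stage 2 on training set 2,
Stage 3 back on training set 1.

The double-training-set protocol is deliberate: features are frozen on one
cohort, learner grids are cross-validated on a second, and the stacked
ensemble is trained on the first again using the fold-averaged base-learner
scores.  Using a single cohort for all three stages is the overfitting-prone
variant exercised by the ablation in :mod:`tristage.evaluation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cohorts_io import ExpressionCohort
from .ga_ensemble import (
    GAConfig,
    GAResult,
    EnsembleModel,
    fit_ensemble,
    make_stacking_fitness,
    optimize,
)
from .learners import cross_validate, enumerate_grid, rank_learners
from .screening import FeatureSet, featurize, stage1_run

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("tristage")


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    freq_lo: float = 0.20
    freq_hi: float = 0.80
    lasso_folds: int = 10
    cv_folds: int = 10
    grid: list | None = None  # None = the full 47-point grid
    ga: GAConfig = field(default_factory=GAConfig)
    meta_nodesize: int = 30
    meta_ntree: int = 100
    feature_mode: str = "pairs"  # "pairs" | "genes" (unpaired ablation)
    seed: int = 0


@dataclass
class PipelineResult:
    featureset: FeatureSet
    cv_results: list  # ranked, labelled m1..mL
    ga_result: GAResult
    ensemble: EnsembleModel

    @property
    def stage_counts(self) -> dict:
        return self.featureset.stage_counts


def run_pipeline(train1: ExpressionCohort, train2: ExpressionCohort,
                 gene_set=None, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run all three stages and return the fitted ensemble.

    ``train1`` and ``train2`` may be the same cohort (single-training-set
    ablation), in which case the out-of-fold structure of Stage 2 is the
    only thing separating meta-training data from base-training data.
    """
    cfg = cfg or PipelineConfig()

    featureset = stage1_run(
        train1, gene_set,
        alpha=cfg.alpha, freq_lo=cfg.freq_lo, freq_hi=cfg.freq_hi,
        lasso_folds=cfg.lasso_folds, seed=cfg.seed, mode=cfg.feature_mode,
    )
    feats1 = featurize(train1, featureset)
    feats2 = featurize(train2, featureset)

    grid = cfg.grid if cfg.grid is not None else enumerate_grid()
    results = []
    for spec in grid:
        results.append(
            cross_validate(
                spec, feats2, train2.time, train2.event, feats1,
                k=cfg.cv_folds, seed=cfg.seed,
            )
        )
    ranked = rank_learners(results)
    logger.info(
        "stage2: %d learners cross-validated; best %s (C=%.3f)",
        len(ranked), ranked[0].spec.grid_id, ranked[0].cindex_mean,
    )

    import numpy as np

    scores1 = np.column_stack([r.train1_scores.to_numpy() for r in ranked])
    fitness_fn = make_stacking_fitness(
        scores1, train1.time, train1.event,
        seed=cfg.ga.seed, nodesize=cfg.meta_nodesize, ntree=cfg.meta_ntree,
    )
    ga_result = optimize(fitness_fn, L=len(ranked), cfg=cfg.ga)
    logger.info(
        "stage3: GA selected %d learners, fitness %.4f after %d generations",
        ga_result.best.n_selected, ga_result.best.fitness, ga_result.generations_run,
    )

    ensemble = fit_ensemble(
        ga_result.best, ranked, train1.time, train1.event, featureset,
        seed=cfg.ga.seed, nodesize=cfg.meta_nodesize, ntree=cfg.meta_ntree,
        ga_history={
            "best_fitness_trace": ga_result.best_fitness_trace,
            "takeover_time": ga_result.takeover_time,
            "n_evaluations": ga_result.n_evaluations,
        },
    )
    return PipelineResult(
        featureset=featureset, cv_results=ranked, ga_result=ga_result, ensemble=ensemble
    )
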