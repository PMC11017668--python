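"""Stage 1 feature engineering: univariate Cox screens and L1-Cox selection.

The chain run on training set 1 is

    gene screen (Wald p < alpha)
      -> enumerate pairs among surviving genes
      -> pair matrix on training set 1
      -> frequency filter (20-80 %)
      -> pair screen (Wald p < alpha)
      -> L1-penalised Cox, penalty at minimum cross-validated deviance

and its output — the selected pair list — is frozen: every other cohort is
featurised with exactly these pairs.

Screens report Wald p-values from single-covariate Cox fits (Breslow ties).
The L1 path uses 100 log-spaced penalties from the smallest penalty that
zeroes every coefficient down to 1/1000 of it, with seeded k-fold
cross-validation and the Verweij-van Houwelingen cross-validated partial
likelihood as the deviance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from . import _cox
from .cohorts_io import ExpressionCohort
from .genepair import (
    GenePair,
    GenePairMatrix,
    build_pair_matrix,
    enumerate_candidate_pairs,
    frequency_filter,
)

__all__ = [
    "ScreenResult",
    "FeatureSet",
    "ScreeningError",
    "univariate_cox_screen",
    "lasso_cox_select",
    "stage1_run",
    "featurize",
]

logger = logging.getLogger("tristage")


class ScreeningError(RuntimeError):
    """A screening stage left no usable features, or its inputs were
    degenerate (no events)."""


@dataclass
class ScreenResult:
    feature_ids: list
    hazard_ratio: np.ndarray
    p_value: np.ndarray
    retained: np.ndarray  # bool

    @property
    def retained_ids(self) -> list:
        return [f for f, r in zip(self.feature_ids, self.retained) if r]


@dataclass
class FeatureSet:
    """The frozen output of Stage 1.

    ``mode`` is "pairs" for the pair pipeline or "genes" for the unpaired
    ablation variant (where ``selected_genes`` holds the features).
    """

    mode: str = "pairs"
    stage1_genes: list = field(default_factory=list)
    candidate_pairs: list = field(default_factory=list)
    screened_pairs: list = field(default_factory=list)
    selected_pairs: list = field(default_factory=list)
    selected_genes: list = field(default_factory=list)
    lasso_lambda: float | None = None
    stage_counts: dict = field(default_factory=dict)
    train_cohort_id: str | None = None

    @property
    def feature_ids(self) -> list:
        if self.mode == "pairs":
            return [p.label for p in self.selected_pairs]
        return list(self.selected_genes)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "stage1_genes": self.stage1_genes,
            "candidate_pairs": [p.label for p in self.candidate_pairs],
            "screened_pairs": [p.label for p in self.screened_pairs],
            "selected_pairs": [p.label for p in self.selected_pairs],
            "selected_genes": self.selected_genes,
            "lasso_lambda": self.lasso_lambda,
            "stage_counts": self.stage_counts,
            "train_cohort_id": self.train_cohort_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        unlab = lambda ls: [GenePair(*s.split("|")) for s in ls]
        return cls(
            mode=d["mode"],
            stage1_genes=list(d["stage1_genes"]),
            candidate_pairs=unlab(d["candidate_pairs"]),
            screened_pairs=unlab(d["screened_pairs"]),
            selected_pairs=unlab(d["selected_pairs"]),
            selected_genes=list(d["selected_genes"]),
            lasso_lambda=d["lasso_lambda"],
            stage_counts=dict(d["stage_counts"]),
            train_cohort_id=d.get("train_cohort_id"),
        )


def univariate_cox_screen(features, time, event, alpha: float = 0.05) -> ScreenResult:
    """One single-covariate Cox fit per feature; retain those with Wald
    p < alpha.  Constant features get p = 1 and are never retained."""
    if isinstance(features, pd.DataFrame):
        ids = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        ids = list(range(X.shape[1]))
    if int(np.sum(event)) == 0:
        raise ScreeningError("no events; cannot screen")
    res = _cox.univariate_cox(X, time, event)
    retained = res["p"] < alpha
    return ScreenResult(
        feature_ids=ids,
        hazard_ratio=np.exp(res["beta"]),
        p_value=res["p"],
        retained=retained,
    )


def _cv_deviance(X, time, event, alphas, n_folds, seed):
    """Mean cross-validated partial-likelihood deviance per penalty.

    Verweij & van Houwelingen: for fold k with estimate b_k(alpha),
    CV-PL_k = l_full(b_k) - l_without-k(b_k);  deviance = -2 * sum_k CV-PL_k.
    """
    y = Surv.from_arrays(event.astype(bool), time)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros(len(alphas))
    for tr, _te in skf.split(X, event):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, fit_baseline_model=False, tol=1e-7
        )
        model.fit(X[tr], y[tr])
        coefs = model.coef_  # (p, n_alphas_fit)
        fit_alphas = list(model.alphas_)
        for ai, a in enumerate(alphas):
            if a in fit_alphas:
                b = coefs[:, fit_alphas.index(a)]
            else:  # penalty dropped by the solver: nearest fitted penalty
                b = coefs[:, int(np.argmin(np.abs(np.array(fit_alphas) - a)))]
            ll_full = _cox.breslow_loglik(X @ b, time, event)
            ll_train = _cox.breslow_loglik(X[tr] @ b, time[tr], event[tr])
            dev[ai] += -2.0 * (ll_full - ll_train)
    return dev / n_folds


def lasso_cox_select(pairmatrix, time, event, n_folds: int = 10, seed: int = 0):
    """L1-penalised Cox over a descending penalty path; keep the features
    with nonzero coefficients at the deviance-minimising penalty.

    Accepts a GenePairMatrix or a plain DataFrame of features.  Returns
    (selected_ids, lambda, coefficients at optimum).
    """
    if isinstance(pairmatrix, GenePairMatrix):
        Xdf = pairmatrix.values.astype(float)
    else:
        Xdf = pd.DataFrame(pairmatrix).astype(float)
    if Xdf.shape[1] < 2:
        raise ScreeningError("need at least 2 features for L1 selection")
    X = Xdf.to_numpy()
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    y = Surv.from_arrays(event.astype(bool), time)

    path_model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=100, alpha_min_ratio=0.001, fit_baseline_model=False
    )
    path_model.fit(X, y)
    alphas = np.asarray(path_model.alphas_)

    dev = _cv_deviance(X, time, event, alphas, n_folds=n_folds, seed=seed)
    best = int(np.argmin(dev))
    lam = float(alphas[best])
    coef = path_model.coef_[:, best]
    nz = np.flatnonzero(np.abs(coef) > 0)
    if len(nz) == 0:
        raise ScreeningError(
            "L1 selection kept no features at the deviance optimum; "
            "consider a weaker screen alpha"
        )
    selected = [Xdf.columns[j] for j in nz]
    return selected, lam, coef


def stage1_run(
    train1: ExpressionCohort,
    gene_set,
    alpha: float = 0.05,
    freq_lo: float = 0.20,
    freq_hi: float = 0.80,
    lasso_folds: int = 10,
    seed: int = 0,
    mode: str = "pairs",
) -> FeatureSet:
    """Run the full Stage-1 chain on training set 1 and freeze the result.

    ``gene_set`` restricts the analysis to a curated list (e.g. a pathway
    signature); pass None to use every gene in the cohort.  ``mode="genes"``
    is the unpaired ablation variant: gene screen then L1 selection directly
    on expression values, no pairing.
    """
    counts = {}
    genes = list(map(str, train1.genes)) if gene_set is None else [
        str(g) for g in gene_set if str(g) in set(map(str, train1.genes))
    ]
    if len(genes) < 2:
        raise ScreeningError("stage 1 aborted at gene intersection: <2 genes available")
    counts["input_genes"] = len(genes)

    # gene-level Cox models see log1p expression: raw intensity scales are
    # heavy-tailed and would let a handful of outliers dominate the Wald
    # screen.  The pair features are built from the raw values — they are
    # scale-free by construction.
    expr_t = np.log1p(train1.expr.loc[genes]).T  # samples x genes
    gene_screen = univariate_cox_screen(expr_t, train1.time, train1.event, alpha=alpha)
    stage1_genes = gene_screen.retained_ids
    counts["screened_genes"] = len(stage1_genes)
    logger.info("stage1: %d/%d genes pass univariate screen", len(stage1_genes), len(genes))
    if len(stage1_genes) < 2:
        raise ScreeningError("stage 1 aborted at gene screen: <2 genes retained")

    if mode == "genes":
        sel, lam, _ = lasso_cox_select(
            expr_t[stage1_genes], train1.time, train1.event, n_folds=lasso_folds, seed=seed
        )
        counts["selected_genes"] = len(sel)
        return FeatureSet(
            mode="genes",
            stage1_genes=stage1_genes,
            selected_genes=list(sel),
            lasso_lambda=lam,
            stage_counts=counts,
            train_cohort_id=train1.cohort_id,
        )

    candidate = enumerate_candidate_pairs(stage1_genes)
    counts["candidate_pairs"] = len(candidate)
    pm = build_pair_matrix(train1, candidate)
    pm = frequency_filter(pm, lo=freq_lo, hi=freq_hi)
    counts["frequency_filtered_pairs"] = len(pm.pairs)
    logger.info("stage1: %d pairs survive the %g-%g frequency filter",
                len(pm.pairs), freq_lo, freq_hi)
    if len(pm.pairs) == 0:
        raise ScreeningError("stage 1 aborted at frequency filter: no pairs retained")

    pair_screen = univariate_cox_screen(
        pm.values.astype(float), train1.time, train1.event, alpha=alpha
    )
    keep = np.flatnonzero(pair_screen.retained)
    pm_screened = pm.subset(keep)
    counts["screened_pairs"] = len(pm_screened.pairs)
    logger.info("stage1: %d pairs pass the pair-level screen", len(pm_screened.pairs))
    if len(pm_screened.pairs) < 2:
        raise ScreeningError("stage 1 aborted at pair screen: <2 pairs retained")

    sel_labels, lam, _ = lasso_cox_select(
        pm_screened, train1.time, train1.event, n_folds=lasso_folds, seed=seed
    )
    label_to_pair = {p.label: p for p in pm_screened.pairs}
    selected = [label_to_pair[s] for s in sel_labels]
    counts["selected_pairs"] = len(selected)
    logger.info("stage1: %d pairs selected by L1-Cox (lambda=%.4g)", len(selected), lam)

    return FeatureSet(
        mode="pairs",
        stage1_genes=stage1_genes,
        candidate_pairs=candidate,
        screened_pairs=list(pm_screened.pairs),
        selected_pairs=selected,
        lasso_lambda=lam,
        stage_counts=counts,
        train_cohort_id=train1.cohort_id,
    )


def featurize(cohort: ExpressionCohort, featureset: FeatureSet) -> pd.DataFrame:
    """Build the frozen feature matrix (samples x features) for any cohort."""
    if featureset.mode == "pairs":
        pm = build_pair_matrix(cohort, featureset.selected_pairs)
        return pm.values.astype(float)
    missing = sorted(set(featureset.selected_genes) - set(map(str, cohort.genes)))
    if missing:
        raise KeyError(f"cohort {cohort.cohort_id!r} lacks genes: {missing}")
    return np.log1p(cohort.expr.loc[featureset.selected_genes].T.astype(float))
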