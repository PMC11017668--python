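"""Assessment battery: median-split Kaplan-Meier with log-rank tests,
time-dependent ROC-AUC, concordance comparisons, no-GA top-k baselines, the
two ablation experiments and the PCA batch diagnostic.

Evaluation horizons are expressed in the cohort's own time unit; nothing is
ever converted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .cohorts_io import ExpressionCohort
from .genepair import build_pair_matrix, enumerate_candidate_pairs, frequency_filter
from .learners import concordance_index
from .pipeline import PipelineConfig, run_pipeline

__all__ = [
    "EvaluationReport",
    "median_split",
    "km_logrank",
    "time_dependent_auc",
    "baseline_topk",
    "cindex_compare",
    "ablate_no_pairing",
    "ablate_single_trainset",
    "pca_batch_check",
]

logger = logging.getLogger("tristage")


@dataclass
class EvaluationReport:
    per_cohort: dict = field(default_factory=dict)
    comparison: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)


def median_split(scores, cohort: ExpressionCohort | None = None) -> np.ndarray:
    """Per-cohort median split: score > median -> "high", <= median -> "low"
    (the median-valued sample goes to the low-risk group)."""
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 samples to split")
    med = np.median(s)
    groups = np.where(s > med, "high", "low")
    if len(set(groups)) < 2:
        raise ValueError("all scores equal; median split impossible")
    return groups


def km_logrank(groups, time, event) -> dict:
    """Two-group log-rank p-value and per-group Kaplan-Meier curves."""
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    masks = {g: groups == g for g in labels}
    if any(m.sum() == 0 for m in masks.values()):
        raise ValueError("a group has no observations")
    a, b = labels
    res = logrank_test(time[masks[a]], time[masks[b]],
                       event_observed_A=event[masks[a]], event_observed_B=event[masks[b]])
    curves = {}
    for g, m in masks.items():
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(g))
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return {"p_value": float(res.p_value), "test_statistic": float(res.test_statistic),
            "curves": curves}


def time_dependent_auc(scores, time, event, horizons=(1.0, 2.0, 3.0),
                       train_time=None, train_event=None) -> dict:
    """Cumulative-case / dynamic-control AUC at each horizon, with
    Kaplan-Meier inverse-probability-of-censoring weights.

    The censoring distribution is estimated from (train_time, train_event)
    when given, else from the evaluation data itself.  Horizons beyond the
    last observed event time are an error.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    horizons = np.asarray(horizons, dtype=float)
    ev_times = time[event == 1]
    if len(ev_times) == 0:
        raise ValueError("no events; AUC undefined")
    if (horizons >= ev_times.max()).any() or (horizons < time.min()).any():
        raise ValueError(
            f"horizons {list(horizons)} outside the event-time range "
            f"({time.min():.3g}, {ev_times.max():.3g})"
        )
    y_test = Surv.from_arrays(event.astype(bool), time)
    if train_time is None:
        y_train = y_test
    else:
        y_train = Surv.from_arrays(
            np.asarray(train_event).astype(bool), np.asarray(train_time, dtype=float)
        )
    auc, mean_auc = cumulative_dynamic_auc(y_train, y_test, np.asarray(scores, float), horizons)
    return {"horizons": list(map(float, horizons)),
            "auc": [float(a) for a in auc],
            "mean_auc": float(mean_auc)}


def baseline_topk(cv_results, k: int, learner_scores: pd.DataFrame) -> np.ndarray:
    """No-GA baseline: average the top-k learners' scores on one cohort.

    ``learner_scores`` holds one column per ranked learner (same order as
    ``cv_results``) on the target cohort.  Scores are z-scored per learner
    within the cohort before averaging — the families' native scales are
    not commensurable.
    """
    if k > len(cv_results):
        raise ValueError(f"k={k} exceeds the {len(cv_results)} available learners")
    order = sorted(range(len(cv_results)), key=lambda i: -cv_results[i].cindex_mean)[:k]
    cols = learner_scores.iloc[:, order].to_numpy(dtype=float)
    sd = cols.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (cols - cols.mean(axis=0)) / sd
    return z.mean(axis=1)


def cindex_compare(model_scores: dict, covariates: pd.DataFrame | None,
                   time, event) -> pd.DataFrame:
    """C-index of each model score and each (numeric or ordinal-encoded)
    clinical covariate on the identical sample set, sorted descending."""
    rows = []
    for name, s in model_scores.items():
        rows.append({"predictor": name, "kind": "model",
                     "cindex": concordance_index(s, time, event)})
    if covariates is not None:
        for col in covariates.columns:
            v = covariates[col]
            if not pd.api.types.is_numeric_dtype(v):
                codes, _ = pd.factorize(v, sort=True)
                v = pd.Series(codes, index=v.index)
            if v.nunique() < 2:
                logger.warning("covariate %r has one level; skipped", col)
                continue
            rows.append({"predictor": col, "kind": "covariate",
                         "cindex": concordance_index(v.to_numpy(float), time, event)})
    return (pd.DataFrame(rows)
            .sort_values("cindex", ascending=False)
            .reset_index(drop=True))


def _evaluate_model(result, cohorts, horizons, train1) -> dict:
    out = {}
    for c in cohorts:
        scores = result.ensemble.predict(c)
        entry = {"cindex": concordance_index(scores, c.time, c.event)}
        try:
            entry["auc"] = time_dependent_auc(
                scores, c.time, c.event, horizons,
                train_time=train1.time, train_event=train1.event,
            )
        except ValueError as exc:
            entry["auc"] = None
            entry["auc_error"] = str(exc)
        out[c.cohort_id] = entry
    return out


def ablate_no_pairing(train1, train2, gene_set, test_cohorts,
                      cfg: PipelineConfig | None = None,
                      horizons=(1.0, 2.0, 3.0)) -> EvaluationReport:
    """Run the pipeline twice — pair features vs raw gene features — and
    evaluate both on the same (typically batch-distorted) test cohorts."""
    cfg = cfg or PipelineConfig()
    from dataclasses import replace

    paired = run_pipeline(train1, train2, gene_set, replace(cfg, feature_mode="pairs"))
    unpaired = run_pipeline(train1, train2, gene_set, replace(cfg, feature_mode="genes"))
    report = EvaluationReport()
    report.per_cohort = {
        "paired": _evaluate_model(paired, test_cohorts, horizons, train1),
        "unpaired": _evaluate_model(unpaired, test_cohorts, horizons, train1),
    }
    report.notes = {
        "paired_counts": paired.stage_counts,
        "unpaired_counts": unpaired.stage_counts,
    }
    rows = []
    for mode in ("paired", "unpaired"):
        for cid, e in report.per_cohort[mode].items():
            rows.append({"mode": mode, "cohort": cid, "cindex": e["cindex"]})
    report.comparison = pd.DataFrame(rows)
    return report


def ablate_single_trainset(train1, train2, gene_set, test_cohorts,
                           cfg: PipelineConfig | None = None,
                           horizons=(1.0, 2.0, 3.0)) -> EvaluationReport:
    """Double-training-set pipeline vs the variant that runs all three
    stages on training set 1 alone; reports each model's training-cohort AUC
    against its held-out AUC (the overfitting gap)."""
    cfg = cfg or PipelineConfig()
    double = run_pipeline(train1, train2, gene_set, cfg)
    single = run_pipeline(train1, train1, gene_set, cfg)

    report = EvaluationReport()
    for name, res in (("double", double), ("single", single)):
        train_scores = res.ensemble.predict(train1)
        train_auc = time_dependent_auc(
            train_scores, train1.time, train1.event, horizons,
            train_time=train1.time, train_event=train1.event,
        )["mean_auc"]
        held = _evaluate_model(res, test_cohorts, horizons, train1)
        test_aucs = [e["auc"]["mean_auc"] for e in held.values() if e["auc"]]
        report.per_cohort[name] = {
            "train_auc": train_auc,
            "test_auc_mean": float(np.mean(test_aucs)) if test_aucs else float("nan"),
            "gap": train_auc - float(np.mean(test_aucs)) if test_aucs else float("nan"),
            "held_out": held,
            "roles": {"train1": train1.cohort_id,
                      "train2": train2.cohort_id if name == "double" else train1.cohort_id},
        }
    report.comparison = pd.DataFrame(
        [{"variant": k, "train_auc": v["train_auc"],
          "test_auc_mean": v["test_auc_mean"], "gap": v["gap"]}
         for k, v in report.per_cohort.items()]
    )
    return report


def pca_batch_check(cohorts, feature_mode: str = "raw", pairs=None,
                    freq_bounds=(0.20, 0.80)) -> dict:
    """PCA of pooled samples with cohort labels; the silhouette of the
    labels in (PC1, PC2) measures cohort separation (batch effect).

    ``feature_mode="raw"`` uses log1p expression of the shared genes (PCA
    of expression is conventionally done on the log scale); ``"paired"``
    uses pair indicators (pairs enumerated from shared genes and
    frequency-filtered on the pooled matrix unless given);
    ``"standardized"`` is the simple batch-correction comparator: per-gene
    mean/variance standardisation within each cohort before pooling.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    shared = sorted(set.intersection(*(set(map(str, c.genes)) for c in cohorts)))
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes across cohorts")
    blocks, labels = [], []
    if feature_mode in ("raw", "standardized"):
        for c in cohorts:
            x = np.log1p(c.expr.loc[shared].T.to_numpy(dtype=float))
            if feature_mode == "standardized":
                sd = x.std(axis=0, ddof=0)
                sd[sd == 0] = 1.0
                x = (x - x.mean(axis=0)) / sd
            blocks.append(x)
            labels += [c.cohort_id] * c.n_samples
    elif feature_mode == "paired":
        if pairs is None:
            pairs = enumerate_candidate_pairs(shared)
        mats = [build_pair_matrix(c, pairs) for c in cohorts]
        pooled = np.vstack([m.values.to_numpy(dtype=float) for m in mats])
        freq = pooled.mean(axis=0)
        keep = (freq >= freq_bounds[0]) & (freq <= freq_bounds[1])
        if not keep.any():
            keep = np.ones_like(keep, dtype=bool)
        blocks = [m.values.to_numpy(dtype=float)[:, keep] for m in mats]
        for c in cohorts:
            labels += [c.cohort_id] * c.n_samples
    else:
        raise ValueError(f"unknown feature mode {feature_mode!r}")
    X = np.vstack(blocks)
    X = X - X.mean(axis=0, keepdims=True)
    if X.shape[0] < 3:
        raise ValueError("fewer than 3 samples")
    pcs = PCA(n_components=2, random_state=0).fit_transform(X)
    labels = np.asarray(labels)
    sil = float(silhouette_score(pcs, labels)) if len(set(labels)) > 1 else float("nan")
    return {"pcs": pcs, "labels": labels, "silhouette": sil}
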