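"""Stage 2: the 47-point grid of basic survival learners and their
cross-validation on training set 2.

Five families, hyperparameter grids exactly as printed in the protocol:

* ``cox_stepwise`` — AIC-guided stepwise Cox starting from the full model of
  the Stage-1 features; direction forward / backward / both (3 specs).
* ``rsf`` — random survival forest, log-rank splits, terminal-node
  Nelson-Aalen cumulative hazards; nodesize {5,10,15,30} x ntree
  {50,100,200,500} (16).
* ``coxboost`` — componentwise likelihood boosting of the penalised Cox
  partial likelihood; stepno {50,...,300} (6), penalty 9 x events.
* ``gbm`` — gradient-boosted trees with Cox partial-likelihood loss,
  shrinkage 0.1; depth {1,2,5,10} x ntree {20,50,100,200} (16).
* ``survsvm`` — linear ranking survival SVM (hinge loss over comparable
  pairs); gamma.mu {0.1,0.5,1,5,10,50} mapped to the cost weight (6).

Every family obeys one orientation contract: higher predicted score means
higher predicted hazard.

The cross-validation protocol: training set 2 is split into 10 folds
(stratified by event status, seeded); each fold model scores its held-out
tenth (out-of-fold scores) and all of training set 1; per-learner train-1
predictions are the average over the 10 fold models, and these averages are
what Stage 3 stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.ensemble import GradientBoostingSurvivalAnalysis, RandomSurvivalForest
from sksurv.svm import FastSurvivalSVM
from sksurv.util import Surv

from . import _cox

__all__ = [
    "BasicLearnerSpec",
    "FittedLearner",
    "CVResult",
    "LearnerError",
    "enumerate_grid",
    "fit_basic_learner",
    "predict_risk",
    "concordance_index",
    "cross_validate",
    "rank_learners",
    "node_cumulative_hazard",
]

GBM_SHRINKAGE = 0.1
COXBOOST_PENALTY_PER_EVENT = 9.0
MIN_SAMPLES = 20
MIN_EVENTS = 5


class LearnerError(RuntimeError):
    """Degenerate input for a learner fit (too few samples/events,
    all-censored data, empty model after stepwise)."""


@dataclass(frozen=True)
class BasicLearnerSpec:
    family: str
    params: tuple  # sorted (name, value) pairs, hashable

    @property
    def grid_id(self) -> str:
        kv = "_".join(f"{k}{v}" for k, v in self.params)
        return f"{self.family}_{kv}" if kv else self.family

    def param(self, name):
        return dict(self.params)[name]


def _spec(family, **params) -> BasicLearnerSpec:
    return BasicLearnerSpec(family=family, params=tuple(sorted(params.items())))


def enumerate_grid() -> list:
    """The 47 learner specs, in family order, deterministic ids."""
    grid = []
    for direction in ("forward", "backward", "both"):
        grid.append(_spec("cox_stepwise", direction=direction))
    for nodesize in (5, 10, 15, 30):
        for ntree in (50, 100, 200, 500):
            grid.append(_spec("rsf", nodesize=nodesize, ntree=ntree))
    for stepno in (50, 100, 150, 200, 250, 300):
        grid.append(_spec("coxboost", stepno=stepno))
    for depth in (1, 2, 5, 10):
        for ntree in (20, 50, 100, 200):
            grid.append(_spec("gbm", depth=depth, ntree=ntree))
    for gamma_mu in (0.1, 0.5, 1, 5, 10, 50):
        grid.append(_spec("survsvm", gamma_mu=gamma_mu))
    return grid


# ---------------------------------------------------------------------------
# family fits


@dataclass
class _StepwiseCox:
    features: list
    beta: np.ndarray

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.features].to_numpy(dtype=float) @ self.beta


@dataclass
class _CoxBoost:
    features: list
    beta: np.ndarray
    penalty: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.features].to_numpy(dtype=float) @ self.beta


def _aic(loglik: float, k: int) -> float:
    return -2.0 * loglik + 2.0 * k


def _fit_stepwise_cox(X: pd.DataFrame, time, event, direction: str) -> _StepwiseCox:
    """Greedy AIC stepwise from the full model of the Stage-1 features.

    Starting from the full model, "forward" has nothing left to add and
    returns the full fit; "backward" drops terms while the AIC improves;
    "both" additionally reconsiders dropped terms at every step.
    """
    cols = list(X.columns)
    live = [c for c in cols if X[c].nunique() > 1]
    if not live:
        raise LearnerError("stepwise Cox: all features constant")

    def fit(subset):
        beta, ll, _ = _cox.cox_fit(X[subset].to_numpy(dtype=float), time, event)
        return beta, _aic(ll, len(subset))

    current = list(live)
    beta, aic = fit(current)
    if direction == "forward":
        return _StepwiseCox(features=current, beta=beta)

    while True:
        best = None
        if len(current) > 1:
            for c in current:
                sub = [x for x in current if x != c]
                b, a = fit(sub)
                if a < aic - 1e-9 and (best is None or a < best[1]):
                    best = (sub, a, b)
        if direction == "both":
            for c in live:
                if c in current:
                    continue
                sub = current + [c]
                b, a = fit(sub)
                if a < aic - 1e-9 and (best is None or a < best[1]):
                    best = (sub, a, b)
        if best is None:
            break
        current, aic, beta = best[0], best[1], best[2]
    if not current:
        raise LearnerError("stepwise Cox eliminated every feature")
    return _StepwiseCox(features=current, beta=beta)


def _fit_coxboost(X: pd.DataFrame, time, event, stepno: int, penalty=None) -> _CoxBoost:
    """Componentwise likelihood boosting (Breslow partial likelihood).

    Each step computes the penalised one-parameter score update
    U_j / (I_j + lambda) for every feature at the current linear predictor,
    applies the one with the largest penalised score statistic
    U_j^2 / (I_j + lambda), and repeats.  ``stepno=0`` leaves all
    coefficients at zero.
    """
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    n_events = int(np.sum(event))
    lam = COXBOOST_PENALTY_PER_EVENT * n_events if penalty is None else penalty
    beta = np.zeros(p)
    eta = np.zeros(n)
    for _ in range(int(stepno)):
        u, info = _cox.cox_score_info_at_offset(Xv, eta, time, event)
        gain = u**2 / (info + lam)
        j = int(np.argmax(gain))
        delta = u[j] / (info[j] + lam)
        beta[j] += delta
        eta = eta + Xv[:, j] * delta
    return _CoxBoost(features=list(X.columns), beta=beta, penalty=lam)


@dataclass
class FittedLearner:
    spec: BasicLearnerSpec
    model: object
    columns: list
    negate: bool = False  # families whose native output is protective

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.columns:
            raise LearnerError(
                f"feature columns do not match training columns for {self.spec.grid_id}"
            )
        if isinstance(self.model, (_StepwiseCox, _CoxBoost)):
            s = self.model.predict(X)
        else:
            s = self.model.predict(X.to_numpy(dtype=float))
        s = np.asarray(s, dtype=float)
        if not np.all(np.isfinite(s)):
            raise LearnerError(f"non-finite predictions from {self.spec.grid_id}")
        return -s if self.negate else s


def fit_basic_learner(spec: BasicLearnerSpec, features: pd.DataFrame, time, event,
                      seed: int = 0) -> FittedLearner:
    """Fit one grid point on (features, survival).  Refuses degenerate
    inputs (fewer than 20 samples or 5 events)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(features)
    if n < MIN_SAMPLES:
        raise LearnerError(f"refusing to fit on {n} samples (<{MIN_SAMPLES})")
    if int(event.sum()) < MIN_EVENTS:
        raise LearnerError(f"refusing to fit with {int(event.sum())} events (<{MIN_EVENTS})")
    y = Surv.from_arrays(event.astype(bool), time)
    X = features.to_numpy(dtype=float)
    fam = spec.family
    if fam == "cox_stepwise":
        model = _fit_stepwise_cox(features, time, event, spec.param("direction"))
    elif fam == "rsf":
        model = RandomSurvivalForest(
            n_estimators=spec.param("ntree"),
            min_samples_leaf=spec.param("nodesize"),
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        ).fit(X, y)
    elif fam == "coxboost":
        model = _fit_coxboost(features, time, event, spec.param("stepno"))
    elif fam == "gbm":
        model = GradientBoostingSurvivalAnalysis(
            loss="coxph",
            learning_rate=GBM_SHRINKAGE,
            max_depth=spec.param("depth"),
            n_estimators=spec.param("ntree"),
            random_state=seed,
        ).fit(X, y)
    elif fam == "survsvm":
        model = FastSurvivalSVM(
            alpha=float(spec.param("gamma_mu")),
            rank_ratio=1.0,
            max_iter=200,
            random_state=seed,
        ).fit(X, y)
    else:
        raise LearnerError(f"unknown learner family {fam!r}")
    return FittedLearner(spec=spec, model=model, columns=list(features.columns))


def predict_risk(fitted: FittedLearner, features: pd.DataFrame) -> np.ndarray:
    """Per-sample risk scores; higher = higher predicted hazard."""
    return fitted.predict(features)


def node_cumulative_hazard(times, events, at=None):
    """Nelson-Aalen cumulative hazard of one terminal node: sum of
    deaths/at-risk over the node's ordered event times up to ``at``."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="mergesort")
    t, d = times[order], events[order]
    at_risk = len(t) - np.arange(len(t))
    uniq = []
    cum = 0.0
    for tt in np.unique(t[d == 1]):
        mask = t == tt
        deaths = int(d[mask].sum())
        risk = int(at_risk[np.argmax(mask)])
        cum += deaths / risk
        uniq.append((tt, cum))
    if at is None:
        return uniq
    val = 0.0
    for tt, c in uniq:
        if tt <= at:
            val = c
    return val


def concordance_index(scores, time, event) -> float:
    """Harrell's C over comparable pairs.

    Pair (i, j) is comparable iff t_i < t_j and event_i = 1; it is
    concordant when score_i > score_j, and score ties count 1/2.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    if not (len(s) == len(t) == len(d)):
        raise ValueError("scores/time/event length mismatch")
    comp = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_comp = int(comp.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs; concordance undefined")
    diff = s[:, None] - s[None, :]
    n_conc = float(((diff > 0) & comp).sum())
    n_tied = float(((diff == 0) & comp).sum())
    return (n_conc + 0.5 * n_tied) / n_comp


@dataclass
class CVResult:
    spec: BasicLearnerSpec
    cindex_mean: float
    cindex_std: float
    fold_cindex: list
    oof_scores: pd.Series  # out-of-fold scores on training set 2
    train1_scores: pd.Series  # fold-averaged scores on training set 1
    fold_models: list = field(repr=False, default_factory=list)
    label: str | None = None

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Fold-averaged prediction on new data (the frozen-learner form
        used by the ensemble at predict time)."""
        return np.mean([m.predict(features) for m in self.fold_models], axis=0)


def cross_validate(spec: BasicLearnerSpec, train2_features: pd.DataFrame, time2, event2,
                   train1_features: pd.DataFrame, k: int = 10, seed: int = 0) -> CVResult:
    """k-fold CV of one learner on training set 2 plus fold-averaged
    predictions for training set 1.

    Folds are stratified by event status so every training part keeps
    events; a split that still produces an event-free training part is
    refused.
    """
    time2 = np.asarray(time2, dtype=float)
    event2 = np.asarray(event2, dtype=int)
    n = len(train2_features)
    if n < k:
        raise LearnerError(f"cannot make {k} folds from {n} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(n, np.nan)
    t1_acc = np.zeros(len(train1_features))
    fold_c = []
    models = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(n), event2)):
        if event2[tr].sum() == 0:
            raise LearnerError(f"fold {fold}: no events in training part; re-stratify")
        fitted = fit_basic_learner(
            spec, train2_features.iloc[tr], time2[tr], event2[tr], seed=seed + fold
        )
        models.append(fitted)
        oof[te] = fitted.predict(train2_features.iloc[te])
        t1_acc += fitted.predict(train1_features)
        fold_c.append(concordance_index(oof[te], time2[te], event2[te]))
    assert not np.isnan(oof).any(), "every sample must receive one out-of-fold score"
    return CVResult(
        spec=spec,
        cindex_mean=float(np.mean(fold_c)),
        cindex_std=float(np.std(fold_c, ddof=1)),
        fold_cindex=[float(c) for c in fold_c],
        oof_scores=pd.Series(oof, index=train2_features.index),
        train1_scores=pd.Series(t1_acc / k, index=train1_features.index),
        fold_models=models,
    )


def rank_learners(cvresults) -> list:
    """Sort descending by mean C-index (ties: smaller std, then grid order)
    and label m1..mL.  Returns a new sorted list."""
    if not cvresults:
        raise ValueError("no CV results to rank")
    order = sorted(
        range(len(cvresults)),
        key=lambda i: (-cvresults[i].cindex_mean, cvresults[i].cindex_std, i),
    )
    ranked = []
    for rank, i in enumerate(order, start=1):
        r = cvresults[i]
        r.label = f"m{rank}"
        ranked.append(r)
    return ranked
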