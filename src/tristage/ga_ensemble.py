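"""Stage 3: genetic-algorithm selection of the base-learner subset and the
stacked meta-learner.

An individual is a one-hot mask over the L base learners (1 = included).
Its fitness is 1 exactly when fewer than two learners are selected, and
otherwise 1 - C, where C is the concordance of a random-survival-forest
meta-learner (nodesize 30, ntree 100) fitted on the selected learners'
fold-averaged training-set-1 risk scores.  The concordance is evaluated on
training set 1 through the forest's out-of-bag predictions, which removes
most of the in-sample optimism of stacking on the same cohort; an in-sample
option is available behind ``oob=False``.

The GA minimises fitness with elitism, single-point crossover (cut point I
uniform in {2,...,L-1}, applied with probability 0.8), per-individual
mutation probability M = 1/population_size flipping ``n_mutated_digits``
distinct loci, and one of three selection operators (roulette on the
suitability 1 - f, linear rank, or tournament of size q = 2).  Selection
pressure is tracked through the takeover time: the first generation at
which the whole population equals the best individual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .cohorts_io import ExpressionCohort
from .learners import CVResult, concordance_index
from .screening import FeatureSet, featurize

__all__ = [
    "Individual",
    "GAConfig",
    "GAResult",
    "EnsembleModel",
    "fitness",
    "make_stacking_fitness",
    "select_parents",
    "crossover",
    "mutate",
    "optimize",
    "run_ga",
    "fit_ensemble",
    "ensemble_predict",
    "aggregate_oob",
    "rsf_oob_risk",
]

META_NODESIZE = 30
META_NTREE = 100


@dataclass
class Individual:
    mask: np.ndarray  # uint8 one-hot vector over base learners
    fitness: float | None = None

    def copy(self) -> "Individual":
        return Individual(mask=self.mask.copy(), fitness=self.fitness)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class GAConfig:
    population_size: int = 50
    max_generations: int = 100
    patience: int = 20
    selection: str = "tournament"  # roulette | linear_rank | tournament
    tournament_q: int = 2
    p_crossover: float = 0.8
    mutation_rate: float | None = None  # default 1 / population_size
    n_mutated_digits: int = 1
    p_min: float | None = None  # linear rank; default 2/(N(N+1))
    p_max: float | None = None  # linear rank; default 2/(N+1)
    elitism: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if not (0 < self.p_crossover <= 1):
            raise ValueError("p_crossover must be in (0, 1]")
        if self.mutation_rate is not None and not (0 < self.mutation_rate <= 1):
            raise ValueError("mutation_rate must be in (0, 1]")

    @property
    def effective_mutation_rate(self) -> float:
        return self.mutation_rate if self.mutation_rate is not None else 1.0 / self.population_size

    def rank_weights(self, n: int) -> tuple:
        p_min = self.p_min if self.p_min is not None else 2.0 / (n * (n + 1))
        p_max = self.p_max if self.p_max is not None else 2.0 / (n + 1)
        return p_min, p_max


# ---------------------------------------------------------------------------
# out-of-bag machinery for the meta random survival forest


def aggregate_oob(tree_scores, inbag) -> np.ndarray:
    """Out-of-bag ensemble risk: for each sample, the mean of the per-tree
    risks over the trees whose bootstrap did not contain it.

    tree_scores: (B, n) per-tree risk predictions; inbag: (B, n) boolean.
    Samples in every bag get NaN (no OOB prediction exists for them).
    """
    tree_scores = np.asarray(tree_scores, dtype=float)
    oob = ~np.asarray(inbag, dtype=bool)
    n_oob = oob.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(n_oob > 0, (tree_scores * oob).sum(axis=0) / n_oob, np.nan)
    return out


def rsf_oob_risk(forest: RandomSurvivalForest, X: np.ndarray) -> np.ndarray:
    """OOB cumulative-hazard risk scores of a fitted survival forest on its
    own training matrix."""
    n = X.shape[0]
    inbag = np.zeros((len(forest.estimators_), n), dtype=bool)
    for b, idx in enumerate(forest.estimators_samples_):
        inbag[b, idx] = True
    tree_scores = np.stack([est.predict(X) for est in forest.estimators_])
    return aggregate_oob(tree_scores, inbag)


def _fit_meta_rsf(scores: np.ndarray, time, event, seed: int,
                  nodesize: int = META_NODESIZE, ntree: int = META_NTREE):
    y = Surv.from_arrays(np.asarray(event).astype(bool), np.asarray(time, dtype=float))
    return RandomSurvivalForest(
        n_estimators=ntree,
        min_samples_leaf=nodesize,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    ).fit(scores, y)


def fitness(ind: Individual, base_scores_train1, time, event, seed: int = 0,
            nodesize: int = META_NODESIZE, ntree: int = META_NTREE,
            oob: bool = True) -> float:
    """Fitness of one learner subset: 1.0 if fewer than two learners are
    selected, else 1 - C-index of the stacked meta-forest on training set 1
    (out-of-bag by default)."""
    scores = np.asarray(base_scores_train1, dtype=float)
    if scores.shape[1] != len(ind.mask):
        raise ValueError(
            f"base score matrix has {scores.shape[1]} columns but mask length "
            f"is {len(ind.mask)}"
        )
    if ind.n_selected < 2:
        return 1.0
    cols = np.flatnonzero(ind.mask)
    forest = _fit_meta_rsf(scores[:, cols], time, event, seed, nodesize, ntree)
    if oob:
        risk = rsf_oob_risk(forest, scores[:, cols])
        ok = np.isfinite(risk)
        c = concordance_index(risk[ok], np.asarray(time)[ok], np.asarray(event)[ok])
    else:
        c = concordance_index(forest.predict(scores[:, cols]), time, event)
    return 1.0 - c


def make_stacking_fitness(base_scores_train1, time, event, seed: int = 0,
                          nodesize: int = META_NODESIZE, ntree: int = META_NTREE,
                          oob: bool = True):
    """Memoised fitness callable over masks (the GA revisits masks often;
    the meta-forest fit is deterministic given the mask and seed)."""
    cache: dict = {}

    def fn(mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=np.uint8).tobytes()
        if key not in cache:
            cache[key] = fitness(
                Individual(mask=np.asarray(mask, dtype=np.uint8)),
                base_scores_train1, time, event,
                seed=seed, nodesize=nodesize, ntree=ntree, oob=oob,
            )
        return cache[key]

    fn.cache = cache
    return fn


# ---------------------------------------------------------------------------
# GA operators


def _selection_probabilities(fitnesses: np.ndarray, cfg: GAConfig) -> np.ndarray:
    """Selection probabilities for the probability-based operators.

    Roulette normalises the suitability s_i = 1 - f_i (with minimised
    fitness, normalising raw f would favour the worst individuals; the
    suitability form preserves the intended direction).  Linear rank assigns
    P_min..P_max linearly over ascending-suitability ranks, then normalises.
    """
    n = len(fitnesses)
    if cfg.selection == "roulette":
        s = 1.0 - np.asarray(fitnesses, dtype=float)
        s = np.clip(s, 0.0, None)
        total = s.sum()
        return np.full(n, 1.0 / n) if total <= 0 else s / total
    if cfg.selection == "linear_rank":
        p_min, p_max = cfg.rank_weights(n)
        asc = np.argsort(np.argsort(-np.asarray(fitnesses), kind="mergesort"), kind="mergesort")
        w = p_min + (p_max - p_min) * asc / max(n - 1, 1)
        return w / w.sum()
    raise ValueError(f"unknown selection operator {cfg.selection!r}")


def _select_one(fitnesses: np.ndarray, cfg: GAConfig, rng: np.random.Generator) -> int:
    if cfg.selection == "tournament":
        contenders = rng.integers(0, len(fitnesses), size=cfg.tournament_q)
        return int(contenders[np.argmin(np.asarray(fitnesses)[contenders])])
    p = _selection_probabilities(np.asarray(fitnesses, dtype=float), cfg)
    return int(rng.choice(len(fitnesses), p=p))


def select_parents(population, fitnesses, cfg: GAConfig, rng: np.random.Generator,
                   n_pairs: int | None = None) -> list:
    """Draw parent pairs for crossover with the configured operator."""
    if len(population) == 0:
        raise ValueError("empty population")
    if n_pairs is None:
        n_pairs = len(population) // 2
    fitnesses = np.asarray(fitnesses, dtype=float)
    return [
        (population[_select_one(fitnesses, cfg, rng)],
         population[_select_one(fitnesses, cfg, rng)])
        for _ in range(n_pairs)
    ]


def crossover(a: Individual, b: Individual, cfg: GAConfig,
              rng: np.random.Generator) -> tuple:
    """Single-point crossover: with probability p_crossover draw the cut
    point I uniformly in {2,...,L-1} and swap tails; otherwise (or when
    L < 3 leaves no interior cut) return copies of the parents."""
    L = len(a.mask)
    if len(b.mask) != L:
        raise ValueError("parent masks differ in length")
    if L < 3 or rng.random() >= cfg.p_crossover:
        return a.copy(), b.copy()
    cut = int(rng.integers(2, L))  # I in {2, ..., L-1}
    c1 = np.concatenate([a.mask[:cut], b.mask[cut:]])
    c2 = np.concatenate([b.mask[:cut], a.mask[cut:]])
    return Individual(mask=c1), Individual(mask=c2)


def mutate(ind: Individual, cfg: GAConfig, rng: np.random.Generator,
           force: bool = False) -> Individual:
    """With probability M = 1/population_size, flip ``n_mutated_digits``
    distinct uniformly chosen loci."""
    L = len(ind.mask)
    if cfg.n_mutated_digits > L:
        raise ValueError("n_mutated_digits exceeds mask length")
    if not force and rng.random() >= cfg.effective_mutation_rate:
        return ind.copy()
    loci = rng.choice(L, size=cfg.n_mutated_digits, replace=False)
    mask = ind.mask.copy()
    mask[loci] = 1 - mask[loci]
    return Individual(mask=mask)


@dataclass
class GAResult:
    best: Individual
    best_fitness_trace: list
    takeover_time: int | None
    n_evaluations: int
    generations_run: int


def optimize(fitness_fn, L: int, cfg: GAConfig) -> GAResult:
    """Minimise ``fitness_fn(mask)`` over one-hot masks of length L.

    Population initialised with i.i.d. Bernoulli(1/2) bits; iterates
    selection -> crossover -> mutation with elitism, stopping at
    ``max_generations`` or after ``patience`` generations without
    improvement of the best-ever fitness.
    """
    if L < 2:
        raise ValueError("need at least 2 base learners")
    rng = np.random.default_rng(cfg.seed)
    pop = [Individual(mask=rng.integers(0, 2, L).astype(np.uint8))
           for _ in range(cfg.population_size)]
    n_eval = 0

    def evaluate(ind: Individual) -> None:
        nonlocal n_eval
        if ind.fitness is None:
            ind.fitness = float(fitness_fn(ind.mask))
            n_eval += 1

    for ind in pop:
        evaluate(ind)
    best = min(pop, key=lambda i: i.fitness).copy()
    trace = [best.fitness]
    takeover = None
    stale = 0
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        fits = [i.fitness for i in pop]
        elite = sorted(pop, key=lambda i: i.fitness)[: cfg.elitism]
        children = [e.copy() for e in elite]
        while len(children) < cfg.population_size:
            (pa, pb) = select_parents(pop, fits, cfg, rng, n_pairs=1)[0]
            c1, c2 = crossover(pa, pb, cfg, rng)
            for c in (c1, c2):
                if len(children) < cfg.population_size:
                    children.append(mutate(c, cfg, rng))
        pop = children
        for ind in pop:
            evaluate(ind)
        gen_best = min(pop, key=lambda i: i.fitness)
        if gen_best.fitness < best.fitness - 1e-15:
            best = gen_best.copy()
            stale = 0
        else:
            stale += 1
        trace.append(best.fitness)
        if takeover is None and all(np.array_equal(i.mask, best.mask) for i in pop):
            takeover = gen
        if stale >= cfg.patience:
            break
    return GAResult(
        best=best,
        best_fitness_trace=trace,
        takeover_time=takeover,
        n_evaluations=n_eval,
        generations_run=gen,
    )


def run_ga(cv_results, train1_time, train1_event, cfg: GAConfig,
           nodesize: int = META_NODESIZE, ntree: int = META_NTREE) -> GAResult:
    """GA over the ranked base learners using their fold-averaged
    training-set-1 scores."""
    if len(cv_results) < 2:
        raise ValueError("need at least 2 base learners")
    scores = np.column_stack([r.train1_scores.to_numpy() for r in cv_results])
    fn = make_stacking_fitness(
        scores, train1_time, train1_event, seed=cfg.seed, nodesize=nodesize, ntree=ntree
    )
    return optimize(fn, L=len(cv_results), cfg=cfg)


# ---------------------------------------------------------------------------
# the final stacked model


@dataclass
class EnsembleModel:
    featureset: FeatureSet
    selected_labels: list
    selected_cv: list  # CVResult of the selected learners, with fold models
    meta_model: RandomSurvivalForest = field(repr=False, default=None)
    ga_history: dict = field(default_factory=dict)
    meta_nodesize: int = META_NODESIZE
    meta_ntree: int = META_NTREE

    def predict(self, cohort: ExpressionCohort) -> np.ndarray:
        """The full predict chain: frozen features -> fold-averaged base
        scores -> meta-forest risk.  Higher = worse prognosis."""
        feats = featurize(cohort, self.featureset)
        base = np.column_stack([cv.predict(feats) for cv in self.selected_cv])
        return self.meta_model.predict(base)

    def base_score_frame(self, cohort: ExpressionCohort) -> pd.DataFrame:
        feats = featurize(cohort, self.featureset)
        return pd.DataFrame(
            {cv.label or cv.spec.grid_id: cv.predict(feats) for cv in self.selected_cv},
            index=feats.index,
        )

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, out / "ensemble_model.joblib")
        summary = {
            "selected_labels": self.selected_labels,
            "selected_specs": [cv.spec.grid_id for cv in self.selected_cv],
            "featureset": self.featureset.to_dict(),
            "meta": {"nodesize": self.meta_nodesize, "ntree": self.meta_ntree},
            "ga_history": {
                k: v for k, v in self.ga_history.items() if k != "best_mask"
            } | {"best_mask": [int(x) for x in self.ga_history.get("best_mask", [])]},
        }
        (out / "ensemble_model.json").write_text(json.dumps(summary, indent=2, default=str))

    @classmethod
    def load(cls, out_dir) -> "EnsembleModel":
        return joblib.load(Path(out_dir) / "ensemble_model.joblib")


def fit_ensemble(best: Individual, cv_results, time1, event1,
                 featureset: FeatureSet, seed: int = 0,
                 nodesize: int = META_NODESIZE, ntree: int = META_NTREE,
                 ga_history: dict | None = None) -> EnsembleModel:
    """Train the final meta random-survival-forest on the selected learners'
    fold-averaged training-set-1 scores."""
    if best.n_selected < 2:
        raise ValueError("ensemble requires at least 2 selected learners")
    cols = np.flatnonzero(best.mask)
    selected = [cv_results[j] for j in cols]
    scores = np.column_stack([r.train1_scores.to_numpy() for r in selected])
    meta = _fit_meta_rsf(scores, time1, event1, seed, nodesize, ntree)
    history = dict(ga_history or {})
    history["best_mask"] = [int(x) for x in best.mask]
    return EnsembleModel(
        featureset=featureset,
        selected_labels=[r.label or r.spec.grid_id for r in selected],
        selected_cv=selected,
        meta_model=meta,
        ga_history=history,
        meta_nodesize=nodesize,
        meta_ntree=ntree,
    )


def ensemble_predict(model: EnsembleModel, cohort: ExpressionCohort) -> np.ndarray:
    """Risk scores for one cohort (the pipeline's final per-sample score)."""
    return model.predict(cohort)
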