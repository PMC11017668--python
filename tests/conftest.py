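import numpy as np
import pandas as pd
import pytest

import tristage as ts
from tristage.ga_ensemble import GAConfig
from tristage.learners import enumerate_grid
from tristage.pipeline import PipelineConfig

# a small but representative grid drawn from the printed hyperparameter
# grids, used wherever fitting all 47 learners would be wasteful
SMALL_GRID_IDS = {
    "cox_stepwise_directionboth",
    "rsf_nodesize5_ntree100",
    "rsf_nodesize15_ntree50",
    "coxboost_stepno100",
    "gbm_depth5_ntree100",
    "gbm_depth2_ntree20",
    "survsvm_gamma_mu1",
}


def small_grid():
    return [s for s in enumerate_grid() if s.grid_id in SMALL_GRID_IDS]


def make_cohort(expr_rows, genes, samples, time, event, cohort_id="toy"):
    return ts.ExpressionCohort(
        cohort_id=cohort_id,
        expr=pd.DataFrame(np.asarray(expr_rows, dtype=float), index=genes, columns=samples),
        time=np.asarray(time, dtype=float),
        event=np.asarray(event, dtype=int),
    )


def survival_data(n, beta=1.0, seed=0, censor_scale=None, p_features=1):
    """One-feature (or more) PH simulation: hazard 0.1 * exp(beta * x0)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p_features))
    eta = beta * X[:, 0]
    t_ev = rng.exponential(1.0 / (0.1 * np.exp(eta)))
    if censor_scale is None:
        return X, t_ev, np.ones(n, dtype=int)
    c = rng.exponential(censor_scale, n)
    return X, np.minimum(t_ev, c), (t_ev <= c).astype(int)


@pytest.fixture(scope="session")
def sim_cohorts():
    cfg = ts.SimConfig(n_cohorts=4, n_samples=200, n_genes=30, n_informative_pairs=3,
                       beta=1.5, seed=11, batch_model="per_sample_monotone")
    cohorts, gt = ts.simulate_multicohort(cfg)
    return cohorts, gt


@pytest.fixture(scope="session")
def fitted_pipeline(sim_cohorts):
    """One fitted three-stage pipeline on the reduced grid, shared across
    tests that only need *a* fitted ensemble."""
    cohorts, _ = sim_cohorts
    cfg = PipelineConfig(
        seed=11, grid=small_grid(),
        ga=GAConfig(seed=11, population_size=16, max_generations=12, patience=5),
    )
    return ts.run_pipeline(cohorts[0], cohorts[1], None, cfg)
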