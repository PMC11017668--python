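import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tristage.learners import (
    LearnerError,
    concordance_index,
    cross_validate,
    enumerate_grid,
    fit_basic_learner,
    node_cumulative_hazard,
    predict_risk,
    rank_learners,
)
from .conftest import survival_data


class TestGrid:
    def test_total_count(self):
        assert len(enumerate_grid()) == 47

    def test_family_subcounts(self):
        fams = pd.Series([s.family for s in enumerate_grid()]).value_counts()
        assert fams["cox_stepwise"] == 3
        assert fams["rsf"] == 16
        assert fams["coxboost"] == 6
        assert fams["gbm"] == 16
        assert fams["survsvm"] == 6

    def test_ids_unique_and_deterministic(self):
        ids = [s.grid_id for s in enumerate_grid()]
        assert len(set(ids)) == 47
        assert ids == [s.grid_id for s in enumerate_grid()]


def test_terminal_node_nelson_aalen_by_hand():
    """Node with events D=(1,2) and at-risk Y=(5,3) at its two event times:
    cumulative hazard at the second time is 1/5 + 2/3."""
    times = [1.0, 2.0, 2.0, 1.5, 3.0]  # at t=1: risk 5, 1 death; t=2: risk 3, 2 deaths
    events = [1, 1, 1, 0, 0]
    assert node_cumulative_hazard(times, events, at=2.0) == pytest.approx(1 / 5 + 2 / 3)
    assert node_cumulative_hazard(times, events, at=1.0) == pytest.approx(1 / 5)


@pytest.fixture(scope="module")
def strong_signal():
    # a very steep linear predictor: training concordance can only clear
    # 0.9 when the hazard ordering is nearly deterministic
    X, t, e = survival_data(300, beta=4.0, seed=10, censor_scale=200)
    feats = pd.DataFrame({"f0": X[:, 0]})
    return feats, t, e


@pytest.mark.parametrize("family_id", [
    "cox_stepwise_directionforward",
    "rsf_nodesize15_ntree100",
    "coxboost_stepno150",
    "gbm_depth2_ntree100",
    "survsvm_gamma_mu1",
])
def test_every_family_learns_orientation(strong_signal, family_id):
    """On single-feature data where the feature is the true linear
    predictor, every family's risk scores must order samples like the
    feature (training C-index > 0.9, higher score = higher hazard)."""
    feats, t, e = strong_signal
    spec = next(s for s in enumerate_grid() if s.grid_id == family_id)
    fitted = fit_basic_learner(spec, feats, t, e, seed=0)
    scores = predict_risk(fitted, feats)
    assert concordance_index(scores, t, e) > 0.9
    np.testing.assert_array_equal(scores, predict_risk(fitted, feats))  # deterministic


def test_coxboost_zero_steps_gives_constant_scores(strong_signal):
    feats, t, e = strong_signal
    spec = next(s for s in enumerate_grid() if s.family == "coxboost")
    from tristage.learners import _fit_coxboost

    model = _fit_coxboost(feats, t, e, stepno=0)
    assert np.all(model.beta == 0)
    assert np.ptp(model.predict(feats)) == 0


def test_cox_linear_predictor_scale(strong_signal):
    """A Cox model with beta=1 separates feature values 0 and 1 by exactly
    1.0 on the linear-predictor scale."""
    from tristage.learners import _StepwiseCox

    model = _StepwiseCox(features=["f0"], beta=np.array([1.0]))
    out = model.predict(pd.DataFrame({"f0": [0.0, 1.0]}))
    assert out[1] - out[0] == pytest.approx(1.0)


def test_refuses_degenerate_inputs(strong_signal):
    feats, t, e = strong_signal
    spec = enumerate_grid()[0]
    with pytest.raises(LearnerError, match="samples"):
        fit_basic_learner(spec, feats.iloc[:10], t[:10], e[:10])
    with pytest.raises(LearnerError, match="events"):
        fit_basic_learner(spec, feats, t, np.zeros_like(e))


def test_predict_rejects_column_mismatch(strong_signal):
    feats, t, e = strong_signal
    spec = next(s for s in enumerate_grid() if s.family == "coxboost")
    fitted = fit_basic_learner(spec, feats, t, e)
    with pytest.raises(LearnerError, match="columns"):
        fitted.predict(feats.rename(columns={"f0": "other"}))


class TestConcordance:
    @pytest.mark.parametrize("scores,time,event,expected", [
        ((0.9, 0.5, 0.1), (2, 4, 6), (1, 1, 1), 1.0),
        ((0.1, 0.5, 0.9), (2, 4, 6), (1, 1, 1), 0.0),
        ((0.9, 0.9, 0.1), (2, 4, 6), (1, 0, 1), 0.75),
    ])
    def test_examples(self, scores, time, event, expected):
        assert concordance_index(scores, time, event) == pytest.approx(expected)

    def test_brute_force_oracle(self):
        """200 random small instances against pairwise enumeration."""
        def brute(s, t, d):
            num = den = 0.0
            for i in range(len(s)):
                for j in range(len(s)):
                    if t[i] < t[j] and d[i] == 1:
                        den += 1
                        num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
            return num / den if den else None

        checked = 0
        for rep in range(200):
            rng = np.random.default_rng(rep)
            n = int(rng.integers(4, 13))
            t = rng.integers(1, 8, n).astype(float)
            d = rng.integers(0, 2, n)
            s = np.round(rng.normal(size=n), 1)  # rounded -> score ties occur
            expected = brute(s, t, d)
            if expected is None:
                with pytest.raises(ValueError):
                    concordance_index(s, t, d)
                continue
            assert concordance_index(s, t, d) == pytest.approx(expected, abs=1e-12)
            checked += 1
        assert checked > 150

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_complement_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        s = rng.normal(size=n)  # continuous, no ties
        t = rng.exponential(5, n) + 1e-3
        d = rng.integers(0, 2, n)
        d[rng.integers(0, n)] = 1
        t = np.round(t, 6)
        c = concordance_index(s, t, d)
        assert concordance_index(-s, t, d) == pytest.approx(1 - c, abs=1e-12)
        assert concordance_index(np.exp(2 * s), t, d) == pytest.approx(c, abs=1e-12)


@pytest.fixture(scope="module")
def cv_data():
    X2, t2, e2 = survival_data(200, beta=1.0, seed=20, censor_scale=25)
    X1, t1, e1 = survival_data(120, beta=1.0, seed=21, censor_scale=25)
    return (pd.DataFrame({"f0": X2[:, 0]}), t2, e2,
            pd.DataFrame({"f0": X1[:, 0]}), t1, e1)


class TestCrossValidate:
    def test_every_sample_scored_once_out_of_fold(self, cv_data):
        f2, t2, e2, f1, _, _ = cv_data
        spec = next(s for s in enumerate_grid() if s.family == "coxboost")
        res = cross_validate(spec, f2, t2, e2, f1, k=10, seed=0)
        assert len(res.oof_scores) == 200
        assert res.oof_scores.notna().all()
        assert len(res.train1_scores) == 120

    def test_cv_cindex_close_to_large_sample_truth(self, cv_data):
        """Monte-Carlo oracle: the large-sample C of the true predictor."""
        f2, t2, e2, f1, _, _ = cv_data
        rng = np.random.default_rng(99)
        n = 10_000
        x = rng.normal(size=n)
        t_ev = rng.exponential(1.0 / (0.1 * np.exp(x)))
        c = rng.exponential(25, n)
        tt, ee = np.minimum(t_ev, c), (t_ev <= c).astype(int)
        idx = rng.choice(n, 2500, replace=False)
        oracle = concordance_index(x[idx], tt[idx], ee[idx])
        spec = next(s for s in enumerate_grid() if s.grid_id == "coxboost_stepno300")
        res = cross_validate(spec, f2, t2, e2, f1, k=10, seed=1)
        assert res.cindex_mean == pytest.approx(oracle, abs=0.05)

    def test_null_data_cv_cindex_near_half(self):
        rng = np.random.default_rng(3)
        f2 = pd.DataFrame({"f0": rng.normal(size=200), "f1": rng.normal(size=200)})
        t2 = rng.exponential(10, 200)
        e2 = (rng.random(200) < 0.7).astype(int)
        spec = next(s for s in enumerate_grid() if s.grid_id == "rsf_nodesize15_ntree50")
        res = cross_validate(spec, f2, t2, e2, f2, k=10, seed=2)
        assert res.cindex_mean == pytest.approx(0.5, abs=0.06)


class TestRanking:
    def _mk(self, c, std):
        return type("R", (), {"cindex_mean": c, "cindex_std": std, "label": None})()

    def test_sorted_descending(self):
        rs = [self._mk(0.70, 0.01), self._mk(0.80, 0.01), self._mk(0.75, 0.01)]
        ranked = rank_learners(rs)
        assert [r.cindex_mean for r in ranked] == [0.80, 0.75, 0.70]
        assert [r.label for r in ranked] == ["m1", "m2", "m3"]

    def test_tie_broken_by_std(self):
        rs = [self._mk(0.7, 0.02), self._mk(0.7, 0.01)]
        ranked = rank_learners(rs)
        assert ranked[0].cindex_std == 0.01

    def test_bijective_labels_for_47(self):
        rs = [self._mk(0.5 + 0.001 * i, 0.01) for i in range(47)]
        labels = [r.label for r in rank_learners(rs)]
        assert labels == [f"m{i}" for i in range(1, 48)]
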