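import itertools

import numpy as np
import pytest

from tristage.ga_ensemble import (
    GAConfig,
    Individual,
    aggregate_oob,
    crossover,
    fitness,
    make_stacking_fitness,
    mutate,
    optimize,
    rsf_oob_risk,
    select_parents,
    _selection_probabilities,
)
from tristage.learners import concordance_index
from .conftest import survival_data


def rigged_fitness(seed, L=8):
    """Smooth seeded pseudo-fitness over masks: linear weights plus a few
    pairwise interactions, squashed into (0, 1)."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1, 1, L)
    pairs = rng.integers(0, L, size=(3, 2))
    coefs = rng.uniform(-0.5, 0.5, 3)

    def fn(mask):
        m = np.asarray(mask, dtype=float)
        v = w @ m + sum(c * m[i] * m[j] for (i, j), c in zip(pairs, coefs))
        return (1 + np.tanh(v)) / 2

    return fn


@pytest.fixture(scope="module")
def stacking_inputs():
    rng = np.random.default_rng(5)
    n, L = 150, 6
    eta = rng.normal(size=n)
    scores = eta[:, None] + rng.normal(scale=(0.5 + np.arange(L) * 0.5), size=(n, L))
    t_ev = rng.exponential(1.0 / (0.1 * np.exp(eta)))
    c = rng.exponential(25, n)
    return scores, np.minimum(t_ev, c), (t_ev <= c).astype(int)


class TestFitness:
    def test_below_two_learners_is_exactly_one(self, stacking_inputs):
        scores, t, e = stacking_inputs
        L = scores.shape[1]
        one_hot = np.zeros(L, dtype=np.uint8)
        one_hot[2] = 1
        assert fitness(Individual(mask=one_hot), scores, t, e) == 1.0
        assert fitness(Individual(mask=np.zeros(L, dtype=np.uint8)), scores, t, e) == 1.0

    def test_fitted_mask_is_one_minus_cindex(self, stacking_inputs):
        scores, t, e = stacking_inputs
        mask = np.array([1, 1, 1, 0, 0, 0], dtype=np.uint8)
        f = fitness(Individual(mask=mask), scores, t, e, seed=3)
        from tristage.ga_ensemble import _fit_meta_rsf

        forest = _fit_meta_rsf(scores[:, :3], t, e, seed=3)
        risk = rsf_oob_risk(forest, scores[:, :3])
        ok = np.isfinite(risk)
        c = concordance_index(risk[ok], t[ok], e[ok])
        assert abs(f - (1.0 - c)) <= 1e-12
        assert 0.0 < f < 1.0

    def test_branch_property(self, stacking_inputs):
        scores, t, e = stacking_inputs
        rng = np.random.default_rng(0)
        for _ in range(10):
            mask = rng.integers(0, 2, scores.shape[1]).astype(np.uint8)
            f = fitness(Individual(mask=mask), scores, t, e, seed=0)
            if f < 1.0:
                assert mask.sum() >= 2

    def test_column_misalignment_is_error(self, stacking_inputs):
        scores, t, e = stacking_inputs
        with pytest.raises(ValueError, match="mask length"):
            fitness(Individual(mask=np.ones(3, dtype=np.uint8)), scores, t, e)


class TestSelection:
    def test_roulette_probabilities_from_suitability(self):
        cfg = GAConfig(selection="roulette", seed=0)
        p = _selection_probabilities(np.array([0.5, 0.7, 0.8]), cfg)
        np.testing.assert_allclose(p, [0.5, 0.3, 0.2])

    def test_roulette_empirical_frequencies(self):
        cfg = GAConfig(selection="roulette", seed=0)
        rng = np.random.default_rng(0)
        fits = [0.5, 0.7, 0.8]
        pop = [Individual(mask=np.array([i], dtype=np.uint8)) for i in range(3)]
        draws = [select_parents(pop, fits, cfg, rng, n_pairs=1)[0][0].mask[0]
                 for _ in range(10_000)]
        freq = np.bincount(draws, minlength=3) / 10_000
        np.testing.assert_allclose(freq, [0.5, 0.3, 0.2], atol=0.02)

    def test_linear_rank_weights(self):
        cfg = GAConfig(selection="linear_rank", p_min=0.1, p_max=0.5, seed=0)
        p = _selection_probabilities(np.array([0.2, 0.5, 0.9]), cfg)
        # ascending suitability = descending fitness: raw (0.5, 0.3, 0.1)
        np.testing.assert_allclose(p, np.array([0.5, 0.3, 0.1]) / 0.9)

    def test_tournament_q2_selects_better_with_prob_three_quarters(self):
        """Best-of-2 with uniform draws with replacement: 1 - (1/2)^2."""
        cfg = GAConfig(selection="tournament", tournament_q=2, seed=0)
        rng = np.random.default_rng(0)
        pop = [Individual(mask=np.array([0], dtype=np.uint8)),
               Individual(mask=np.array([1], dtype=np.uint8))]
        wins = sum(
            select_parents(pop, [0.1, 0.9], cfg, rng, n_pairs=1)[0][0] is pop[0]
            for _ in range(10_000)
        )
        assert wins / 10_000 == pytest.approx(0.75, abs=0.02)

    def test_all_zero_suitability_falls_back_to_uniform(self):
        cfg = GAConfig(selection="roulette", seed=0)
        p = _selection_probabilities(np.array([1.0, 1.0]), cfg)
        np.testing.assert_allclose(p, [0.5, 0.5])


class TestCrossoverMutation:
    def test_single_point_definition(self):
        cfg = GAConfig(p_crossover=1.0, seed=0)
        a = Individual(mask=np.ones(6, dtype=np.uint8))
        b = Individual(mask=np.zeros(6, dtype=np.uint8))
        rng = np.random.default_rng(1)
        for _ in range(50):
            c1, c2 = crossover(a, b, cfg, rng)
            cut = int(np.argmin(c1.mask)) if c1.mask.min() == 0 else 6
            assert 2 <= cut <= 5  # I in {2, ..., L-1}
            np.testing.assert_array_equal(c1.mask, [1] * cut + [0] * (6 - cut))
            np.testing.assert_array_equal(c2.mask, [0] * cut + [1] * (6 - cut))

    def test_no_crossover_returns_copies(self):
        cfg = GAConfig(p_crossover=1e-12, seed=0)
        rng = np.random.default_rng(0)
        a = Individual(mask=np.array([1, 0, 1], dtype=np.uint8))
        b = Individual(mask=np.array([0, 1, 0], dtype=np.uint8))
        c1, c2 = crossover(a, b, cfg, rng)
        np.testing.assert_array_equal(c1.mask, a.mask)
        np.testing.assert_array_equal(c2.mask, b.mask)
        assert c1 is not a

    def test_no_bit_invented(self):
        cfg = GAConfig(p_crossover=1.0, seed=0)
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = Individual(mask=rng.integers(0, 2, 8).astype(np.uint8))
            b = Individual(mask=rng.integers(0, 2, 8).astype(np.uint8))
            c1, c2 = crossover(a, b, cfg, rng)
            for c in (c1, c2):
                ok = (c.mask == a.mask) | (c.mask == b.mask)
                assert ok.all()

    def test_mutation_rate_default_and_forced_flip(self):
        cfg = GAConfig(population_size=50)
        assert cfg.effective_mutation_rate == pytest.approx(0.02)
        ind = Individual(mask=np.array([0, 0, 1, 1, 0], dtype=np.uint8))
        rng = np.random.default_rng(0)
        out = mutate(ind, cfg, rng, force=True)
        assert int(np.sum(out.mask != ind.mask)) == 1

    def test_mutation_frequency_calibration(self):
        cfg = GAConfig(population_size=50, seed=0)
        rng = np.random.default_rng(1)
        base = Individual(mask=np.zeros(10, dtype=np.uint8))
        hits = sum(mutate(base, cfg, rng).mask.sum() > 0 for _ in range(10_000))
        se = np.sqrt(0.02 * 0.98 / 10_000)
        assert hits / 10_000 == pytest.approx(0.02, abs=4 * se)

    def test_nmg_exceeding_length_is_error(self):
        cfg = GAConfig(n_mutated_digits=9, seed=0)
        with pytest.raises(ValueError):
            mutate(Individual(mask=np.zeros(5, dtype=np.uint8)), cfg,
                   np.random.default_rng(0), force=True)


class TestOptimize:
    def test_finds_enumerated_optimum_on_small_problem(self):
        fn = rigged_fitness(123)
        best_true = min(
            (np.array(m, dtype=np.uint8) for m in itertools.product((0, 1), repeat=8)),
            key=fn,
        )
        res = optimize(fn, L=8, cfg=GAConfig(seed=0))
        assert res.best.fitness == pytest.approx(fn(best_true), abs=1e-12)

    def test_best_so_far_never_worsens(self):
        res = optimize(rigged_fitness(7), L=8, cfg=GAConfig(seed=1))
        trace = np.asarray(res.best_fitness_trace)
        assert (np.diff(trace) <= 1e-15).all()

    def test_population_of_clones_converges_immediately(self):
        calls = []

        def fn(mask):
            calls.append(tuple(mask))
            return 0.25

        cfg = GAConfig(seed=0, patience=1, population_size=4)
        res = optimize(fn, L=5, cfg=cfg)
        assert res.best.fitness == 0.25
        assert res.generations_run <= 2  # constant landscape: patience trips at once

    def test_memoised_stacking_fitness_caches(self, stacking_inputs):
        scores, t, e = stacking_inputs
        fn = make_stacking_fitness(scores, t, e, seed=0)
        mask = np.array([1, 0, 1, 1, 0, 0], dtype=np.uint8)
        v1 = fn(mask)
        v2 = fn(mask.copy())
        assert v1 == v2 and len(fn.cache) == 1


class TestOOBAggregation:
    def test_hand_computed_two_tree_example(self):
        """Two trees, two samples: sample 0 is in-bag for tree 0 only, so
        its OOB risk is tree 1's prediction; sample 1 is OOB for both."""
        tree_scores = np.array([[1.0, 2.0], [3.0, 4.0]])
        inbag = np.array([[True, False], [False, False]])
        out = aggregate_oob(tree_scores, inbag)
        np.testing.assert_allclose(out, [3.0, 3.0])

    def test_never_oob_sample_is_nan(self):
        out = aggregate_oob(np.array([[1.0], [2.0]]), np.array([[True], [True]]))
        assert np.isnan(out[0])

    def test_oob_risk_matches_manual_aggregation(self, stacking_inputs):
        scores, t, e = stacking_inputs
        from tristage.ga_ensemble import _fit_meta_rsf

        forest = _fit_meta_rsf(scores[:, :3], t, e, seed=0, ntree=25)
        X = scores[:, :3]
        risk = rsf_oob_risk(forest, X)
        inbag = np.zeros((25, len(X)), dtype=bool)
        for b, idx in enumerate(forest.estimators_samples_):
            inbag[b, idx] = True
        manual = aggregate_oob(np.stack([est.predict(X) for est in forest.estimators_]), inbag)
        np.testing.assert_allclose(risk, manual, equal_nan=True)
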