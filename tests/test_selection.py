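"""GA operators, selection procedures and PCA reduction."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ganospec.selection import (
    FitnessEvaluator,
    FitnessSpec,
    GAConfig,
    GAWavelengthSelector,
    InsufficientSignalError,
    IterativeGASelector,
    PCAReducer,
    VotingGASelector,
    fitness,
    iterative_select,
    mutate,
    pca_reduce,
    roulette_select,
    run_ga,
    single_point_crossover,
    top_k_by_votes,
    voting_select,
)

FAST = GAConfig(population_size=16, generations=12, seed=0)


class TestFitness:
    def test_informative_column_scores_near_perfect(self, easy_regression):
        X, y, _ = easy_regression
        # append the target itself as a column: a mask selecting it is an
        # (essentially) perfect predictor
        X2 = np.column_stack([X, y])
        mask = np.zeros(X2.shape[1], dtype=bool)
        mask[-1] = True
        assert fitness(mask, X2, y) > 0.99

    def test_pure_noise_target_scores_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 10))
        y = rng.normal(size=200)
        mask = np.ones(10, dtype=bool)
        assert fitness(mask, X, y) < 0.2

    def test_identity_mask_equals_full_model_cv(self, easy_regression):
        X, y, _ = easy_regression
        spec = FitnessSpec()
        ev = FitnessEvaluator(X, y, spec, seed=5)
        got = ev(np.ones(X.shape[1], dtype=bool))
        # independent recomputation of the CV score over the same folds
        from ganospec.models import ELMRegressor, r_squared
        from ganospec._rng import substream

        key = np.packbits(np.ones(X.shape[1], dtype=bool)).tobytes()
        scores = []
        for fold, (tr, va) in enumerate(ev._folds):
            model = ELMRegressor(
                n_hidden=spec.n_hidden, activation=spec.activation,
                random_state=substream(5, "fitness-elm", fold, key),
            ).fit(X[tr], y[tr])
            scores.append(r_squared(y[va], model.predict(X[va])))
        assert got == pytest.approx(np.mean(scores), rel=1e-12)

    def test_all_zero_mask_repaired_with_warning(self, easy_regression):
        X, y, _ = easy_regression
        with pytest.warns(UserWarning, match="repaired"):
            score = fitness(np.zeros(X.shape[1], dtype=bool), X, y)
        assert np.isfinite(score)

    def test_deterministic_per_mask(self, easy_regression):
        X, y, _ = easy_regression
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[[4, 12]] = True
        assert fitness(mask, X, y, seed=9) == fitness(mask, X, y, seed=9)


class TestRoulette:
    def test_pick_ratio_proportional_to_raw_positive_fitness(self):
        pop = np.array([[0], [1]])
        fits = np.array([1.0, 3.0])
        rng = np.random.default_rng(0)
        picks = [roulette_select(pop, fits, rng)[0][0] for _ in range(12000)]
        frac_second = np.mean(picks)
        # expected 0.75, binomial SE ~ 0.004
        assert abs(frac_second - 0.75) < 3 * np.sqrt(0.75 * 0.25 / 12000)

    def test_equal_fitness_uniform(self):
        pop = np.eye(3, dtype=bool)
        rng = np.random.default_rng(1)
        picks = [int(np.argmax(roulette_select(pop, np.zeros(3), rng)[0]))
                 for _ in range(9000)]
        counts = np.bincount(picks, minlength=3)
        assert counts.min() > 2700

    def test_dominant_fitness_nearly_always_picked(self):
        pop = np.array([[0], [1]])
        rng = np.random.default_rng(2)
        picks = [roulette_select(pop, np.array([1e-9, 1e6]), rng)[0][0]
                 for _ in range(500)]
        assert np.mean(picks) > 0.99

    def test_nonpositive_fitness_shift_preserves_order(self):
        pop = np.array([[0], [1], [2]])
        fits = np.array([-1.0, -0.5, 2.0])
        rng = np.random.default_rng(3)
        picks = [int(roulette_select(pop, fits, rng)[0][0]) for _ in range(9000)]
        counts = np.bincount(picks, minlength=3)
        assert counts[2] > counts[1] > counts[0]


class TestCrossover:
    def test_identical_parents_give_identical_children(self):
        rng = np.random.default_rng(0)
        a = np.array([1, 0, 1, 1, 0], dtype=bool)
        c1, c2 = single_point_crossover(a, a, rng)
        np.testing.assert_array_equal(c1, a)
        np.testing.assert_array_equal(c2, a)

    @given(st.integers(min_value=0, max_value=1000))
    def test_per_locus_bit_sum_conserved(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(12) < 0.5
        b = rng.random(12) < 0.5
        c1, c2 = single_point_crossover(a, b, rng)
        np.testing.assert_array_equal(
            c1.astype(int) + c2.astype(int), a.astype(int) + b.astype(int)
        )

    def test_length_two_forces_cut_at_one(self):
        a = np.array([True, False])
        b = np.array([False, True])
        rng = np.random.default_rng(4)
        c1, c2 = single_point_crossover(a, b, rng)
        np.testing.assert_array_equal(c1, [True, True])
        np.testing.assert_array_equal(c2, [False, False])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            single_point_crossover(np.ones(3, bool), np.ones(4, bool),
                                   np.random.default_rng(0))


class TestMutation:
    def test_p_zero_is_identity(self):
        m = np.array([1, 0, 1, 0, 1], dtype=bool)
        np.testing.assert_array_equal(mutate(m, 0.0, np.random.default_rng(0)), m)

    def test_p_one_is_complement(self):
        m = np.array([1, 0, 1, 0], dtype=bool)
        np.testing.assert_array_equal(
            mutate(m, 1.0, np.random.default_rng(0)), ~m
        )

    def test_all_zero_complement_repaired(self):
        m = np.ones(6, dtype=bool)
        out = mutate(m, 1.0, np.random.default_rng(1))
        assert out.sum() == 1  # complement is empty; one bit restored

    @given(st.integers(min_value=0, max_value=500))
    def test_length_preserved(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random(17) < 0.4
        assert mutate(m, 0.05, rng).size == 17


class TestRunGA:
    def test_population_of_one_single_generation(self, easy_regression):
        X, y, _ = easy_regression
        cfg = GAConfig(population_size=1, generations=1, mutation_prob=0.0,
                       crossover_prob=0.0, seed=3)
        res = run_ga(X, y, cfg)
        assert res.selected_indices.size >= 1
        assert np.isfinite(res.best_fitness)

    def test_seeded_determinism(self, easy_regression):
        X, y, _ = easy_regression
        a = run_ga(X, y, FAST)
        b = run_ga(X, y, FAST)
        np.testing.assert_array_equal(a.selected_indices, b.selected_indices)
        assert a.best_fitness == b.best_fitness
        np.testing.assert_array_equal(a.fitness_trace, b.fitness_trace)

    def test_trace_non_decreasing_with_elitism(self, easy_regression):
        X, y, _ = easy_regression
        res = run_ga(X, y, FAST)
        assert np.all(np.diff(res.fitness_trace) >= -1e-12)

    def test_matches_exhaustive_search_on_small_grid(self):
        # 8 wavelengths -> 255 non-empty masks; the GA with a generous budget
        # must find the same optimum the brute force finds
        rng = np.random.default_rng(12)
        X = 0.5 + 0.1 * rng.normal(size=(40, 8))
        y = 2.0 * X[:, 2] - 1.5 * X[:, 5] + 0.02 * rng.normal(size=40)
        cfg = GAConfig(population_size=40, generations=40, seed=5)
        from ganospec.selection import make_evaluator

        ev = make_evaluator(X, y, cfg)
        res = run_ga(X, y, cfg, evaluator=ev)
        brute_best = max(
            ev(np.array(bits, dtype=bool))
            for bits in itertools.product([0, 1], repeat=8)
            if any(bits)
        )
        assert res.best_fitness == pytest.approx(brute_best, abs=1e-9)


class TestIterative:
    def test_rounds_are_nested_and_counts_non_increasing(self, easy_regression):
        X, y, _ = easy_regression
        rounds = iterative_select(X, y, FAST, n_rounds=3)
        sets = [set(r.selected_indices.tolist()) for r in rounds]
        for earlier, later in zip(sets, sets[1:]):
            assert later <= earlier
        counts = [len(s) for s in sets]
        assert counts == sorted(counts, reverse=True)

    def test_stops_early_when_too_few_remain(self, easy_regression):
        X, y, _ = easy_regression
        cfg = GAConfig(population_size=10, generations=8, init_prob=0.05,
                       parsimony=2.0, seed=1)
        with pytest.warns(UserWarning, match="fewer than 2"):
            rounds = iterative_select(X, y, cfg, n_rounds=6, parsimony=2.0)
        assert len(rounds) < 6


class TestVoting:
    def test_tally_counts_qualifying_runs_and_is_deterministic(self, easy_regression):
        X, y, _ = easy_regression
        idx1, tally1 = voting_select(X, y, FAST, n_qualifying=8,
                                     r2_threshold=0.5, k=4)
        idx2, tally2 = voting_select(X, y, FAST, n_qualifying=8,
                                     r2_threshold=0.5, k=4)
        assert tally1.n_qualifying == 8
        assert tally1.counts.max() <= 8
        np.testing.assert_array_equal(idx1, idx2)
        np.testing.assert_array_equal(tally1.counts, tally2.counts)
        assert idx1.size == 4

    def test_unreachable_threshold_raises_with_partial_tally(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)  # no signal at all
        cfg = GAConfig(population_size=8, generations=4, seed=2)
        with pytest.raises(InsufficientSignalError) as err:
            voting_select(X, y, cfg, n_qualifying=5, r2_threshold=0.99,
                          k=2, max_runs=6)
        assert err.value.tally.n_runs_total == 6
        assert err.value.tally.n_qualifying < 5

    def test_top_k_ranking_and_tie_break(self):
        counts = np.array([2, 50, 49, 0, 49])
        np.testing.assert_array_equal(top_k_by_votes(counts, 2), [1, 2])
        # tie between indices 2 and 4 at rank 2: lower index wins
        np.testing.assert_array_equal(top_k_by_votes(counts, 3), [1, 2, 4])

    def test_tally_invariant_to_run_order(self, easy_regression):
        X, y, _ = easy_regression
        results = [run_ga(X, y, FAST, run_id=("vote", i)) for i in range(6)]
        forward = np.sum([r.mask for r in results], axis=0)
        backward = np.sum([r.mask for r in reversed(results)], axis=0)
        np.testing.assert_array_equal(forward, backward)
        np.testing.assert_array_equal(
            top_k_by_votes(forward, 3), top_k_by_votes(backward, 3)
        )


class TestPCA:
    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 6))
        _, _, explained = pca_reduce(X, 5)
        cov = np.cov(X, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(explained, eigvals[:5], atol=1e-10)

    def test_planar_data_has_two_meaningful_components(self):
        rng = np.random.default_rng(14)
        basis = rng.normal(size=(2, 7))
        X = rng.normal(size=(30, 2)) @ basis
        with pytest.warns(UserWarning, match="rank"):
            scores, loadings, explained = pca_reduce(X, 5)
        assert scores.shape[1] == 2

    def test_full_component_set_reconstructs_centered_data(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(9, 4))
        scores, loadings, _ = pca_reduce(X, 4)
        np.testing.assert_allclose(scores @ loadings, X - X.mean(axis=0),
                                   atol=1e-10)

    def test_sign_convention(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(12, 5))
        _, loadings, _ = pca_reduce(X, 3)
        for row in loadings:
            assert row[np.argmax(np.abs(row))] > 0


class TestEstimators:
    def test_selector_transform_matches_support(self, easy_regression):
        X, y, _ = easy_regression
        sel = GAWavelengthSelector(population_size=12, generations=8,
                                   random_state=0).fit(X, y)
        Xt = sel.transform(X)
        assert Xt.shape == (X.shape[0], sel.support_.sum())
        np.testing.assert_array_equal(sel.get_support(), sel.support_)

    def test_iterative_estimator_exposes_rounds(self, easy_regression):
        X, y, _ = easy_regression
        sel = IterativeGASelector(n_rounds=2, population_size=12, generations=8,
                                  random_state=0).fit(X, y)
        assert len(sel.results_) == 2
        assert sel.transform(X).shape[1] == sel.support_.sum()

    def test_voting_estimator_round_trip(self, easy_regression):
        X, y, _ = easy_regression
        sel = VotingGASelector(n_qualifying=5, r2_threshold=0.4, k=3,
                               population_size=12, generations=8,
                               random_state=0).fit(X, y)
        assert sel.tally_.n_qualifying == 5
        assert sel.transform(X).shape[1] == 3

    def test_estimators_are_cloneable(self, easy_regression):
        from sklearn.base import clone

        X, y, _ = easy_regression
        sel = GAWavelengthSelector(population_size=10, generations=5,
                                   random_state=1)
        cloned = clone(sel)
        a = sel.fit(X, y).support_
        b = cloned.fit(X, y).support_
        np.testing.assert_array_equal(a, b)

    def test_pca_reducer_transform(self, easy_regression):
        X, y, _ = easy_regression
        red = PCAReducer(n_components=3).fit(X)
        Z = red.transform(X)
        assert Z.shape == (X.shape[0], 3)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
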