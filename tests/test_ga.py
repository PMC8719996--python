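import numpy as np
import pytest

from obstruseg import bpnn, ga
from obstruseg.util import ValidationError


class TestRankSelect:
    def test_pressure_two_always_picks_best(self):
        pop = np.array([[0.0], [1.0]])
        fits = np.array([1.0, 5.0])
        sel = ga.rank_select(pop, fits, 50, pressure=2.0, seed=0)
        assert np.all(sel == 1.0)

    def test_equal_fitness_uniform(self):
        pop = np.arange(5, dtype=float)[:, None]
        fits = np.ones(5)
        sel = ga.rank_select(pop, fits, 10_000, pressure=1.8, seed=1)
        counts = np.array([(sel == v).sum() for v in range(5)])
        # multinomial 3-sigma check around 2000
        sd = np.sqrt(10_000 * 0.2 * 0.8)
        assert np.all(np.abs(counts - 2000) < 3 * sd)

    def test_probability_monotone_in_rank(self):
        for pressure in (1.1, 1.5, 2.0):
            probs = ga.selection_probabilities(10, pressure)
            assert np.all(np.diff(probs) >= 0)
            assert probs.sum() == pytest.approx(1.0)

    def test_formula_values_n2(self):
        probs = ga.selection_probabilities(2, 2.0)
        assert probs[0] == pytest.approx(0.0)
        assert probs[1] == pytest.approx(1.0)

    def test_tied_block_shares_rank_mass(self):
        # two tied at the top: each selected with the average of the top-two
        # rank probabilities
        pop = np.arange(4, dtype=float)[:, None]
        fits = np.array([0.0, 1.0, 5.0, 5.0])
        sel = ga.rank_select(pop, fits, 20_000, pressure=2.0, seed=2)
        probs = ga.selection_probabilities(4, 2.0)
        expected = (probs[2] + probs[3]) / 2
        frac2 = np.mean(sel == 2.0)
        sd = np.sqrt(expected * (1 - expected) / 20_000)
        assert abs(frac2 - expected) < 3 * sd

    def test_validation(self):
        with pytest.raises(ValidationError):
            ga.rank_select(np.zeros((3, 1)), np.zeros(2), 1)  # length mismatch
        with pytest.raises(ValidationError):
            ga.rank_select(np.zeros((3, 1)), np.zeros(3), 0)  # no parents


class TestGroupByFitness:
    def test_even_split(self):
        pop = np.arange(6, dtype=float)[:, None]
        groups = ga.group_by_fitness(pop, np.array([1.0, 2, 3, 4, 5, 6]), 3)
        assert [len(g) for g in groups] == [2, 2, 2]
        assert sorted(groups[0].ravel().tolist()) == [4.0, 5.0]  # two best

    def test_remainder_to_leading_groups(self):
        pop = np.arange(7, dtype=float)[:, None]
        groups = ga.group_by_fitness(pop, np.arange(7, dtype=float), 3)
        assert [len(g) for g in groups] == [3, 2, 2]

    def test_hand_case(self):
        pop = np.arange(5, dtype=float)[:, None]
        fits = np.array([5.0, 1.0, 4.0, 2.0, 3.0])
        groups = ga.group_by_fitness(pop, fits, 2)
        assert sorted(groups[0].ravel().tolist()) == [0.0, 2.0, 4.0]  # fits 5,4,3
        assert sorted(groups[1].ravel().tolist()) == [1.0, 3.0]  # fits 1,2

    def test_validation(self):
        with pytest.raises(ValidationError):
            ga.group_by_fitness(np.zeros((2, 1)), np.zeros(2), 3)


class TestGMMOffspring:
    def test_identical_pool_draws_near_point(self):
        c = np.array([0.3, -1.2, 0.7])
        pool = np.tile(c, (10, 1))
        draws = ga.gmm_offspring([pool], 20, n_components=1, seed=0)
        assert np.max(np.abs(draws - c)) < 1e-2  # covariance floor regime

    def test_two_cluster_frequencies(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.1, size=(40, 2))
        b = rng.normal(5.0, 0.1, size=(40, 2))
        draws = ga.gmm_offspring([a, b], 1000, n_components=2, seed=1)
        frac_a = np.mean(np.linalg.norm(draws, axis=1) < 2.5)
        sd = np.sqrt(0.5 * 0.5 / 1000)
        assert abs(frac_a - 0.5) < 3 * sd

    def test_determinism(self):
        rng = np.random.default_rng(2)
        pool = rng.normal(size=(12, 4))
        a = ga.gmm_offspring([pool], 8, n_components=2, seed=5)
        b = ga.gmm_offspring([pool], 8, n_components=2, seed=5)
        assert np.array_equal(a, b)

    def test_pool_too_small(self):
        with pytest.raises(ValidationError):
            ga.gmm_offspring([np.zeros((1, 3))], 5, n_components=2)


class TestCrossoverMutate:
    def test_rate_zero_identity(self, rng):
        p1, p2 = rng.normal(size=4), rng.normal(size=4)
        c1, c2 = ga.crossover(p1, p2, 0.0, seed=0)
        assert np.array_equal(c1, p1) and np.array_equal(c2, p2)
        assert np.array_equal(ga.mutate(p1, 0.0, 0.1, seed=0), p1)

    def test_rate_one_full_complementary_swap(self, rng):
        p1, p2 = rng.normal(size=6), rng.normal(size=6)
        c1, c2 = ga.crossover(p1, p2, 1.0, seed=0)
        assert np.array_equal(c1, p2) and np.array_equal(c2, p1)

    def test_complementarity_any_rate(self, rng):
        p1, p2 = rng.normal(size=50), rng.normal(size=50)
        c1, c2 = ga.crossover(p1, p2, 0.5, seed=3)
        swapped = c1 == p2
        assert np.array_equal(c2[swapped], p1[swapped])
        assert np.array_equal(c1[~swapped], p1[~swapped])

    def test_mutation_moment_check(self):
        c = np.zeros(10_000)
        out = ga.mutate(c, 1.0, 0.1, seed=4)
        assert abs(out.std() - 0.1) / 0.1 < 0.05


class TestEvolve:
    def test_plateau_tol_inf_stops_at_window(self):
        cfg = ga.GAConfig(
            population_size=8, max_generations=100, plateau_window=5, plateau_tol=np.inf, seed=0
        )
        _, hist = ga.evolve(lambda x: -np.sum(np.asarray(x) ** 2), 3, cfg)
        assert hist.stop_reason == "plateau"
        assert len(hist.best) == 5

    def test_best_trace_nondecreasing(self):
        cfg = ga.GAConfig(population_size=12, max_generations=40, plateau_tol=0.0, seed=1)
        _, hist = ga.evolve(lambda x: -np.sum(np.asarray(x) ** 2), 4, cfg)
        assert np.all(np.diff(hist.best) >= 0)

    def test_sphere_convergence_small(self):
        cfg = ga.GAConfig(population_size=30, max_generations=80, plateau_tol=0.0, seed=2)
        best, _ = ga.evolve(lambda x: -np.sum(np.asarray(x) ** 2), 3, cfg)
        assert np.linalg.norm(best) < 0.2

    def test_full_determinism(self):
        cfg = ga.GAConfig(population_size=10, max_generations=15, plateau_tol=0.0, seed=3)
        f = lambda x: -np.sum(np.asarray(x) ** 2)
        b1, h1 = ga.evolve(f, 4, cfg)
        b2, h2 = ga.evolve(f, 4, cfg)
        assert np.array_equal(b1, b2)
        assert h1.best == h2.best

    def test_nonfinite_fitness_names_generation(self):
        cfg = ga.GAConfig(population_size=6, max_generations=5, seed=0)
        with pytest.raises(ValidationError, match="generation 0"):
            ga.evolve(lambda x: np.nan, 2, cfg)


class TestCodec:
    def test_roundtrip_bit_identical(self):
        m = bpnn.init_network(6, 2, 4, seed=8)
        genes = ga.encode_model(m)
        m2 = ga.decode_chromosome(genes, (6, 2, 4))
        assert np.array_equal(ga.encode_model(m2), genes)

    def test_zero_chromosome_outputs_half(self):
        m = ga.decode_chromosome(np.zeros(26), (6, 2, 4))
        assert np.allclose(bpnn.forward(m, np.ones(6)), 0.5)

    def test_length_formula(self):
        assert ga.chromosome_length((6, 2, 4)) == 26
        with pytest.raises(ValidationError):
            ga.decode_chromosome(np.zeros(25), (6, 2, 4))


class TestOptimizeBPNN:
    def test_toy_pipeline_full_accuracy(self, toy_xy):
        X, y = toy_xy
        Y = np.eye(2)[y]
        ga_cfg = ga.GAConfig(population_size=20, max_generations=15, plateau_tol=0.0, seed=0)
        tr_cfg = bpnn.TrainConfig(learning_rate=1.0, max_epochs=2000, error_goal=1e-3, seed=0)
        model, ga_hist, tr_hist = ga.optimize_bpnn(X, Y, (2, 2, 2), ga_cfg, tr_cfg)
        assert np.array_equal(bpnn.predict_labels(model, X), y)
        assert np.all(np.diff(ga_hist.best) >= 0)

    def test_degenerate_ga_still_trains(self, toy_xy):
        X, y = toy_xy
        Y = np.eye(2)[y]
        ga_cfg = ga.GAConfig(population_size=4, max_generations=1, seed=0)
        tr_cfg = bpnn.TrainConfig(max_epochs=5, seed=0)
        model, _, hist = ga.optimize_bpnn(X, Y, (2, 3, 2), ga_cfg, tr_cfg)
        assert model.n_hidden == 3
        assert len(hist.mse) <= 5

    def test_ga_init_not_slower_than_random(self, toy_xy):
        """The motivating soft property: median epochs-to-goal with GA init
        <= median with random init, over matched seeds."""
        X, y = toy_xy
        Y = np.eye(2)[y]
        goal = 5e-3
        rand_epochs, ga_epochs = [], []
        for seed in range(10):
            tc = bpnn.TrainConfig(learning_rate=1.0, max_epochs=2000, error_goal=goal, seed=seed)
            m = bpnn.init_network(2, 2, 2, seed=seed)
            _, h = bpnn.train_backprop(m, X, Y, tc)
            rand_epochs.append(len(h.mse))
            gc = ga.GAConfig(population_size=20, max_generations=15, plateau_tol=0.0, seed=seed)
            _, _, th = ga.optimize_bpnn(X, Y, (2, 2, 2), gc, tc)
            ga_epochs.append(len(th.mse))
        assert np.median(ga_epochs) <= np.median(rand_epochs)
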