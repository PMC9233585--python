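"""Genetic-algorithm center initialization: operators, determinism, search."""

import numpy as np
import pytest

from gapfcm.fcm import squared_distances, update_memberships_fcm, fcm_objective
from gapfcm.ga import FITNESS_CAP, GaConfig, evolve, fitness, init_population, run_ga
from gapfcm.phantoms import halves_phantom
from gapfcm.spatial import run_pfcm


class TestInitPopulation:
    def test_identical_points_force_identical_centers(self, rng):
        data = np.full((3, 1), 4.2)
        pop = init_population(data, 2, 6, rng)
        np.testing.assert_allclose(pop, 4.2)

    def test_single_three_point_subset_gives_their_mean(self, rng):
        data = np.array([[0.0], [3.0], [6.0]])
        pop = init_population(data, 1, 4, rng)
        np.testing.assert_allclose(pop, 3.0)

    def test_deterministic_under_seed(self):
        data = np.random.default_rng(0).random((20, 2))
        pop1 = init_population(data, 3, 8, np.random.default_rng(7))
        pop2 = init_population(data, 3, 8, np.random.default_rng(7))
        np.testing.assert_array_equal(pop1, pop2)

    def test_centers_lie_in_data_hull(self, rng):
        data = rng.random((30, 2))
        pop = init_population(data, 3, 10, rng)
        for j in range(2):
            assert pop[..., j].min() >= data[:, j].min()
            assert pop[..., j].max() <= data[:, j].max()

    def test_too_few_points_raises(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            init_population(np.zeros((2, 1)), 1, 4, rng)


class TestFitness:
    def test_reciprocal_of_objective_without_geometry(self, rng):
        data = rng.random((10, 1))
        genome = np.array([[0.2], [0.8]])
        got = fitness(genome, data, None, sigma=0.0)
        d2 = squared_distances(data, genome)
        u = update_memberships_fcm(d2, 2.0)
        np.testing.assert_allclose(got, 1.0 / fcm_objective(d2, u, 2.0), atol=1e-12)

    def test_exact_centers_on_noiseless_phantom_hit_the_cap(self):
        # without the spatial penalty the objective vanishes exactly at the
        # generating means; with it, boundary pixels always pay a small
        # penalty, so the exact genome is merely the best, not capped
        ph = halves_phantom(8, 8, noise_sd=0.0)
        data = ph.image.reshape(-1, 1)
        genome = np.array([[0.2], [0.8]])
        assert fitness(genome, data, (8, 8), sigma=0.0) == FITNESS_CAP
        exact = fitness(genome, data, (8, 8), sigma=1.0)
        shifted = fitness(genome + 0.1, data, (8, 8), sigma=1.0)
        assert np.isfinite(exact) and exact > shifted

    def test_matches_brute_force_penalized_objective(self, rng):
        from _oracles import naive_pfcm_objective

        ph = halves_phantom(5, 2, noise_sd=0.2, seed=11)
        data = ph.image.reshape(-1, 1)
        genome = rng.random((2, 1))
        d2 = squared_distances(data, genome)
        u0 = update_memberships_fcm(d2, 2.0)
        from gapfcm.spatial import neighbor_prior, update_memberships_pfcm

        P = neighbor_prior(u0, 5, 2)
        u = update_memberships_pfcm(d2, P, 2.0, 1.0)
        expected = 1.0 / naive_pfcm_objective(d2, u, P, 2.0, 1.0)
        np.testing.assert_allclose(fitness(genome, data, (5, 2)), expected, rtol=1e-12)


class TestEvolve:
    def _setup(self, rng, n=6):
        data = rng.random((20, 1))
        cfg = GaConfig(pop_size=n, generations=5, seed=0)
        pop = init_population(data, 2, n, rng)
        fits = np.array([fitness(g, data, None, sigma=0.0) for g in pop])
        return data, cfg, pop, fits

    def test_no_variation_copies_parents(self, rng):
        data, _, pop, fits = self._setup(rng)
        cfg = GaConfig(pop_size=6, p_crossover=0.0, p_mutation=0.0)
        child = evolve(pop, fits, cfg, rng, data.min(0), data.max(0))
        pop_set = {tuple(g.ravel()) for g in pop}
        assert all(tuple(g.ravel()) in pop_set for g in child)

    def test_elitism_keeps_the_best(self, rng):
        data, cfg, pop, fits = self._setup(rng)
        child = evolve(pop, fits, cfg, rng, data.min(0), data.max(0))
        best = pop[int(np.argmax(fits))]
        np.testing.assert_array_equal(child[0], best)

    def test_mutation_respects_data_range(self, rng):
        data, _, pop, fits = self._setup(rng)
        cfg = GaConfig(pop_size=6, p_mutation=1.0, mutation_scale=5.0)
        child = evolve(pop, fits, cfg, rng, data.min(0), data.max(0))
        assert child.min() >= data.min() and child.max() <= data.max()


class TestRunGa:
    def test_recovers_blob_means_on_clean_data(self):
        r = np.random.default_rng(3)
        data = np.concatenate([np.full(20, 0.1), np.full(20, 0.9)]).reshape(-1, 1)
        cfg = GaConfig(generations=30, seed=5)
        centers = run_ga(data, 2, None, cfg, sigma=0.0)
        np.testing.assert_allclose(np.sort(centers.ravel()), [0.1, 0.9], atol=0.05)

    def test_deterministic_under_seed(self):
        ph = halves_phantom(10, 10, noise_sd=0.1, seed=0)
        data = ph.image.reshape(-1, 1)
        cfg = GaConfig(generations=5, seed=42)
        c1 = run_ga(data, 2, (10, 10), cfg)
        c2 = run_ga(data, 2, (10, 10), GaConfig(generations=5, seed=42))
        np.testing.assert_array_equal(c1, c2)

    def test_best_fitness_monotone_non_decreasing(self):
        ph = halves_phantom(10, 10, noise_sd=0.15, seed=1)
        log: list[float] = []
        run_ga(
            ph.image.reshape(-1, 1),
            2,
            (10, 10),
            GaConfig(generations=15, seed=2),
            fitness_log=log,
        )
        assert all(b >= a for a, b in zip(log, log[1:]))

    def test_single_generation_returns_best_individual(self):
        data = np.random.default_rng(0).random((12, 1))
        cfg = GaConfig(pop_size=4, generations=1, seed=0)
        centers = run_ga(data, 2, None, cfg, sigma=0.0)
        assert centers.shape == (2, 1)
        # elitism means the returned genome is at least as fit as any
        # freshly drawn population member
        f_best = fitness(centers, data, None, sigma=0.0)
        pop = init_population(data, 2, 4, np.random.default_rng(0))
        assert all(f_best >= fitness(g, data, None, sigma=0.0) for g in pop)

    def test_ga_init_final_objective_not_worse_than_random_init(self):
        # paired comparison over seeds; GA should find at least as good
        # a basin as picking random pixels
        total_ga, total_rand = 0.0, 0.0
        for seed in range(5):
            ph = halves_phantom(16, 16, noise_sd=0.1, seed=seed)
            data = ph.image.reshape(-1, 1)
            cfg = GaConfig(generations=15, seed=seed)
            init = run_ga(data, 2, (16, 16), cfg)
            r_ga = run_pfcm(ph.image, 2, init_centers=init)
            r_rand = run_pfcm(ph.image, 2, seed=seed)
            total_ga += r_ga.objective_trace[-1]
            total_rand += r_rand.objective_trace[-1]
        assert total_ga <= total_rand + 1e-9


class TestGaConfig:
    def test_odd_population_rejected(self):
        with pytest.raises(ValueError, match="even"):
            GaConfig(pop_size=5)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            GaConfig(p_mutation=1.5)
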