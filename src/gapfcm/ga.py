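"""Genetic-algorithm search for initial cluster centers.

FCM-type algorithms are sensitive to initialization: a bad starting
point can land the alternating minimization in a poor local optimum.
This module runs a small real-coded genetic algorithm over candidate
center sets before the clustering proper starts.

Encoding and fitness:

* each individual is an ``(a, b)`` float matrix — ``a`` cluster centers
  in ``b``-dimensional feature space;
* the initial population seeds every center with the mean of 3 data
  points drawn uniformly without replacement;
* fitness is the reciprocal ``1 / A(U, V)`` of the penalized clustering
  objective, evaluated with a single membership pass from the genome
  (capped at 1e12 when the objective vanishes).

Operators: tournament-2 selection, arithmetic (blend) crossover,
per-gene Gaussian mutation clipped to the data range, elitism of one.
All randomness flows from a single injected generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fcm import _check_data, squared_distances, update_memberships_fcm, fcm_objective
from .spatial import neighbor_prior, pfcm_objective, update_memberships_pfcm

__all__ = ["GaConfig", "init_population", "fitness", "evolve", "run_ga"]

FITNESS_CAP = 1e12


@dataclass
class GaConfig:
    """Knobs of the GA search.

    pop_size must be even (parents are paired for crossover);
    mutation_scale is a fraction of the per-feature data range;
    the run stops early after ``stagnation_patience`` generations
    without improvement of the best fitness.
    """

    pop_size: int = 20
    generations: int = 50
    p_crossover: float = 0.8
    p_mutation: float = 0.1
    mutation_scale: float = 0.1
    stagnation_patience: int = 10
    seed: int | np.random.Generator | None = None

    def __post_init__(self):
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.pop_size % 2:
            raise ValueError("pop_size must be even")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("operator probabilities must lie in [0, 1]")


def init_population(
    data: np.ndarray, n_clusters: int, pop_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Random initial population of shape (pop_size, n_clusters, b).

    Each center of each individual is the mean of 3 points sampled
    uniformly without replacement, so every genome row lies inside the
    data's coordinate-wise hull.
    """
    data = _check_data(data)
    m = data.shape[0]
    if m < 3:
        raise ValueError("need at least 3 data points to seed centers")
    pop = np.empty((pop_size, n_clusters, data.shape[1]))
    for n in range(pop_size):
        for i in range(n_clusters):
            idx = rng.choice(m, size=3, replace=False)
            pop[n, i] = data[idx].mean(axis=0)
    return pop


def fitness(
    genome: np.ndarray,
    data: np.ndarray,
    image_shape: tuple[int, int] | None = None,
    *,
    fuzzifier: float = 2.0,
    sigma: float = 1.0,
    connectivity: int = 8,
    penalty_exponent: float | None = None,
) -> float:
    """Reciprocal of the clustering objective at this candidate center set.

    A single membership pass (not a converged run) scores the genome:
    plain-FCM memberships give the neighbor prior, the penalized update
    gives U, and the penalized objective A is evaluated there.  Returns
    ``1 / A`` capped at 1e12.  Without image geometry the spatial term
    has no meaning and the plain FCM objective is used.
    """
    genome = np.asarray(genome, dtype=float)
    d2 = squared_distances(data, genome)
    if image_shape is None or sigma == 0.0:
        u = update_memberships_fcm(d2, fuzzifier)
        A = fcm_objective(d2, u, fuzzifier)
    else:
        H, W = image_shape
        u0 = update_memberships_fcm(d2, fuzzifier)
        P = neighbor_prior(u0, H, W, connectivity)
        u = update_memberships_pfcm(d2, P, fuzzifier, sigma, penalty_exponent)
        A = pfcm_objective(d2, u, P, fuzzifier, sigma, penalty_exponent)
    if A < 1e-12:
        return FITNESS_CAP
    return 1.0 / A


def _tournament(fits: np.ndarray, rng: np.random.Generator) -> int:
    a, b = rng.integers(0, fits.size, size=2)
    return int(a) if fits[a] >= fits[b] else int(b)


def evolve(
    population: np.ndarray,
    fits: np.ndarray,
    cfg: GaConfig,
    rng: np.random.Generator,
    data_min: np.ndarray,
    data_max: np.ndarray,
) -> np.ndarray:
    """One GA generation: selection, crossover, mutation, elitism.

    The single best individual of the incoming population survives
    unchanged (slot 0 of the offspring), so best fitness never drops.
    """
    n = population.shape[0]
    offspring = np.empty_like(population)
    parents = np.array([_tournament(fits, rng) for _ in range(n)])
    for j in range(0, n, 2):
        p1 = population[parents[j]].copy()
        p2 = population[parents[j + 1]].copy()
        if rng.random() < cfg.p_crossover:
            lam = rng.random()
            c1 = lam * p1 + (1.0 - lam) * p2
            c2 = lam * p2 + (1.0 - lam) * p1
            p1, p2 = c1, c2
        offspring[j], offspring[j + 1] = p1, p2
    span = data_max - data_min
    mask = rng.random(offspring.shape) < cfg.p_mutation
    noise = rng.normal(0.0, 1.0, size=offspring.shape) * (cfg.mutation_scale * span)
    offspring = np.where(mask, offspring + noise, offspring)
    np.clip(offspring, data_min, data_max, out=offspring)
    offspring[0] = population[int(np.argmax(fits))]
    return offspring


def run_ga(
    data: np.ndarray,
    n_clusters: int,
    image_shape: tuple[int, int] | None = None,
    cfg: GaConfig | None = None,
    *,
    fuzzifier: float = 2.0,
    sigma: float = 1.0,
    connectivity: int = 8,
    penalty_exponent: float | None = None,
    fitness_log: list[float] | None = None,
) -> np.ndarray:
    """Evolve center sets and return the best genome found.

    Runs up to ``cfg.generations`` generations, stopping early when the
    best fitness has not improved for ``cfg.stagnation_patience``
    generations.  Fully deterministic under ``cfg.seed``.  Appends the
    per-generation best fitness to ``fitness_log`` when given.
    """
    cfg = cfg or GaConfig()
    data = _check_data(data)
    rng = (
        cfg.seed
        if isinstance(cfg.seed, np.random.Generator)
        else np.random.default_rng(cfg.seed)
    )
    data_min = data.min(axis=0)
    data_max = data.max(axis=0)

    def score(pop: np.ndarray) -> np.ndarray:
        return np.array(
            [
                fitness(
                    g,
                    data,
                    image_shape,
                    fuzzifier=fuzzifier,
                    sigma=sigma,
                    connectivity=connectivity,
                    penalty_exponent=penalty_exponent,
                )
                for g in pop
            ]
        )

    pop = init_population(data, n_clusters, cfg.pop_size, rng)
    fits = score(pop)
    best_idx = int(np.argmax(fits))
    best_fit = float(fits[best_idx])
    best_genome = pop[best_idx].copy()
    if fitness_log is not None:
        fitness_log.append(best_fit)
    stagnant = 0
    for _ in range(cfg.generations):
        pop = evolve(pop, fits, cfg, rng, data_min, data_max)
        fits = score(pop)
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_genome = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        if fitness_log is not None:
            fitness_log.append(best_fit)
        if stagnant >= cfg.stagnation_patience:
            break
    return best_genome
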