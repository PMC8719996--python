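"""Real-valued genetic algorithm with sorting-based (linear-ranking)
selection, fitness grouping, and a Gaussian-mixture offspring channel, used
to find initial weights/thresholds for the backprop network.

Each individual ("chromosome") is the flat concatenation of W1, b1, W2, b2
in that order, so decoding is pure reshaping.  Per generation the loop is:
evaluate fitness -> carry elites -> linear-ranking selection of parents ->
uniform crossover + Gaussian mutation for part of the new pool, and draws
from a GMM fitted to the fitter half of the fitness groups for the rest.
It stops when the best fitness improves by less than ``plateau_tol`` over
``plateau_window`` generations, or at ``max_generations``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .bpnn import BPNNModel, TrainConfig, TrainHistory, mse, train_backprop
from .gmm import fit_gmm_em, sample_gmm
from .util import ValidationError, as_rng

__all__ = [
    "GAConfig",
    "GAHistory",
    "chromosome_length",
    "rank_select",
    "group_by_fitness",
    "gmm_offspring",
    "crossover",
    "mutate",
    "evolve",
    "decode_chromosome",
    "encode_model",
    "optimize_bpnn",
]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 40
    max_generations: int = 100
    n_fitness_groups: int = 4
    gmm_offspring_fraction: float = 0.3
    gmm_components: int = 2
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    mutation_sd: float = 0.1
    selection_pressure: float = 1.8
    plateau_window: int = 20
    plateau_tol: float = 1e-6
    elitism_count: int = 1
    init_low: float = -0.5
    init_high: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValidationError("population_size must be >= 4")
        if self.max_generations < 1:
            raise ValidationError("max_generations must be >= 1")
        if self.n_fitness_groups < 2:
            raise ValidationError("n_fitness_groups must be >= 2")
        if not (0.0 <= self.gmm_offspring_fraction <= 1.0):
            raise ValidationError("gmm_offspring_fraction must lie in [0, 1]")
        for r in (self.crossover_rate, self.mutation_rate):
            if not (0.0 <= r <= 1.0):
                raise ValidationError("rates must lie in [0, 1]")
        if self.mutation_sd <= 0:
            raise ValidationError("mutation_sd must be > 0")
        if not (1.0 < self.selection_pressure <= 2.0):
            raise ValidationError("selection_pressure must lie in (1, 2]")
        if self.plateau_window < 1 or self.plateau_tol < 0:
            raise ValidationError("invalid plateau settings")
        if self.elitism_count < 1:
            raise ValidationError("elitism_count must be >= 1")
        if self.init_high <= self.init_low:
            raise ValidationError("init_high must exceed init_low")


@dataclass
class GAHistory:
    best: list[float] = field(default_factory=list)
    mean: list[float] = field(default_factory=list)
    stop_reason: str = "max_generations"


def chromosome_length(topology: tuple[int, int, int]) -> int:
    n_in, n_h, n_out = topology
    return n_in * n_h + n_h + n_h * n_out + n_out


def rank_select(
    population: np.ndarray,
    fitnesses: np.ndarray,
    n_parents: int,
    pressure: float = 1.8,
    seed=0,
) -> np.ndarray:
    """Linear-ranking selection with replacement.

    With ranks r = 1 (worst) .. N (best), individual probability is
    (2 - pressure)/N + 2 (r - 1) (pressure - 1) / (N (N - 1)).
    Exactly tied fitnesses share their average rank, so equal-fitness
    individuals are selected uniformly.
    """
    from scipy.stats import rankdata

    population = np.asarray(population, dtype=np.float64)
    fitnesses = np.asarray(fitnesses, dtype=np.float64)
    N = len(population)
    if len(fitnesses) != N or N < 2:
        raise ValidationError("need |population| = |fitnesses| >= 2")
    if n_parents < 1:
        raise ValidationError("n_parents must be >= 1")
    rng = as_rng(seed)
    ranks = rankdata(fitnesses, method="average")  # 1 = worst
    probs = (2.0 - pressure) / N + 2.0 * (ranks - 1) * (pressure - 1.0) / (N * (N - 1))
    probs = probs / probs.sum()  # exact up to rounding
    idx = rng.choice(N, size=n_parents, replace=True, p=probs)
    return population[idx].copy()


def selection_probabilities(n: int, pressure: float) -> np.ndarray:
    """Rank -> probability table (rank 0 = worst), exposed for testing."""
    r = np.arange(1, n + 1, dtype=np.float64)
    return (2.0 - pressure) / n + 2.0 * (r - 1) * (pressure - 1.0) / (n * (n - 1))


def group_by_fitness(
    population: np.ndarray, fitnesses: np.ndarray, n_groups: int
) -> list[np.ndarray]:
    """Sort descending by fitness and split into contiguous groups whose
    sizes differ by at most one; group 0 holds the fittest."""
    population = np.asarray(population, dtype=np.float64)
    fitnesses = np.asarray(fitnesses, dtype=np.float64)
    N = len(population)
    if n_groups > N:
        raise ValidationError(f"n_groups={n_groups} exceeds population size {N}")
    order = np.argsort(-fitnesses, kind="stable")
    base, extra = divmod(N, n_groups)
    groups = []
    start = 0
    for g in range(n_groups):
        size = base + (1 if g < extra else 0)
        groups.append(population[order[start : start + size]].copy())
        start += size
    return groups


def gmm_offspring(
    elite_groups: list[np.ndarray], n_offspring: int, n_components: int = 2, seed=0
) -> np.ndarray:
    """Fit a GMM to the pooled elite gene vectors and sample new chromosomes."""
    pool = np.vstack(elite_groups)
    if len(pool) < n_components:
        raise ValidationError(f"pool of {len(pool)} < {n_components} mixture components")
    rng = as_rng(seed)
    fit_seed = int(rng.integers(0, 2**31 - 1))
    draw_seed = int(rng.integers(0, 2**31 - 1))
    params = fit_gmm_em(pool, n_components, seed=fit_seed, max_iter=50)
    return sample_gmm(params, n_offspring, seed=draw_seed)


def crossover(p1: np.ndarray, p2: np.ndarray, rate: float, seed=0):
    """Uniform crossover: each gene swaps between the children with
    probability ``rate`` (so the two children are complementary)."""
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    if p1.shape != p2.shape:
        raise ValidationError("parents have different lengths")
    rng = as_rng(seed)
    swap = rng.random(p1.shape) < rate
    c1 = np.where(swap, p2, p1)
    c2 = np.where(swap, p1, p2)
    return c1, c2


def mutate(c: np.ndarray, rate: float, sd: float, seed=0) -> np.ndarray:
    """Per-gene Gaussian perturbation with probability ``rate``."""
    c = np.asarray(c, dtype=np.float64)
    rng = as_rng(seed)
    hit = rng.random(c.shape) < rate
    noise = rng.normal(0.0, sd, size=c.shape)
    return c + hit * noise


def evolve(fitness_fn, chrom_length: int, cfg: GAConfig):
    """Run the full generation loop; returns (best chromosome, GAHistory)."""
    rng = as_rng(cfg.seed)
    pop = rng.uniform(cfg.init_low, cfg.init_high, size=(cfg.population_size, chrom_length))
    history = GAHistory()
    best_chrom = None
    best_fit = -np.inf
    n_top_groups = max(1, math.ceil(cfg.n_fitness_groups / 2))

    for gen in range(cfg.max_generations):
        fits = np.array([float(fitness_fn(ind)) for ind in pop])
        if not np.all(np.isfinite(fits)):
            raise ValidationError(f"non-finite fitness at generation {gen}")
        gbest = int(np.argmax(fits))
        if fits[gbest] > best_fit:
            best_fit = float(fits[gbest])
            best_chrom = pop[gbest].copy()
        history.best.append(best_fit)
        history.mean.append(float(fits.mean()))

        w = cfg.plateau_window
        if len(history.best) >= w and history.best[-1] - history.best[-w] < cfg.plateau_tol:
            history.stop_reason = "plateau"
            break
        if gen == cfg.max_generations - 1:
            history.stop_reason = "max_generations"
            break

        elite_idx = np.argsort(-fits, kind="stable")[: cfg.elitism_count]
        elites = pop[elite_idx].copy()
        n_rest = cfg.population_size - cfg.elitism_count
        n_gmm = int(round(cfg.gmm_offspring_fraction * n_rest))
        n_cx = n_rest - n_gmm

        children = []
        if n_cx > 0:
            parents = rank_select(
                pop, fits, n_cx + (n_cx % 2), pressure=cfg.selection_pressure, seed=rng
            )
            for i in range(0, len(parents), 2):
                c1, c2 = crossover(parents[i], parents[i + 1], cfg.crossover_rate, seed=rng)
                children.append(mutate(c1, cfg.mutation_rate, cfg.mutation_sd, seed=rng))
                children.append(mutate(c2, cfg.mutation_rate, cfg.mutation_sd, seed=rng))
            children = children[:n_cx]
        if n_gmm > 0:
            groups = group_by_fitness(pop, fits, cfg.n_fitness_groups)
            pool_groups = groups[:n_top_groups]
            n_comp = min(cfg.gmm_components, sum(len(g) for g in pool_groups))
            draws = gmm_offspring(pool_groups, n_gmm, n_components=n_comp, seed=rng)
            children.extend(draws)
        pop = np.vstack([elites] + [np.asarray(c)[None, :] for c in children])

    return best_chrom, history


def decode_chromosome(c: np.ndarray, topology: tuple[int, int, int]) -> BPNNModel:
    """Reshape a flat gene vector into network weights/thresholds."""
    c = np.asarray(c, dtype=np.float64)
    n_in, n_h, n_out = topology
    expected = chromosome_length(topology)
    if c.shape != (expected,):
        raise ValidationError(f"chromosome length {c.shape} != {expected} for {topology}")
    i = 0
    W1 = c[i : i + n_h * n_in].reshape(n_h, n_in)
    i += n_h * n_in
    b1 = c[i : i + n_h]
    i += n_h
    W2 = c[i : i + n_out * n_h].reshape(n_out, n_h)
    i += n_out * n_h
    b2 = c[i : i + n_out]
    return BPNNModel(W1=W1, b1=b1, W2=W2, b2=b2)


def encode_model(model: BPNNModel) -> np.ndarray:
    return np.concatenate(
        [model.W1.ravel(), model.b1, model.W2.ravel(), model.b2]
    )


def optimize_bpnn(
    X: np.ndarray,
    Y: np.ndarray,
    topology: tuple[int, int, int],
    ga_cfg: GAConfig,
    train_cfg: TrainConfig,
):
    """GA search for initial weights (fitness 1/(1+MSE)), then backprop
    fine-tuning of the decoded best chromosome."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if len(X) == 0:
        raise ValidationError("empty training set")

    def fitness(c):
        return 1.0 / (1.0 + mse(decode_chromosome(c, topology), X, Y))

    best, ga_hist = evolve(fitness, chromosome_length(topology), ga_cfg)
    model = decode_chromosome(best, topology)
    model, train_hist = train_backprop(model, X, Y, train_cfg)
    return model, ga_hist, train_hist
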