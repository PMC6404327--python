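"""Evolutionary algorithm for the emergence of genetic code structure.

A population of ambiguous code matrices evolves by per-row Gaussian
mutation and fitness-proportional selection, where each individual's
fitness is a single stochastic evaluation per generation: a fresh draw of
21 representative codons (one per label) followed by the forward fitness
computation under the chosen misreading neighbourhood model.

The population is held as an (n, 64, 21) float array; all operators are
vectorized across individuals.  A run is fully reproducible from its seed:
the master seed spawns one independent stream per replicate via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .code_space import N_CODONS, N_LABELS, random_population
from .metrics import population_entropy
from .neighbourhood import NeighbourhoodModel, population_fitness

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvolutionConfig:
    """Simulation parameters.

    The historical full-scale setting is ``population_size=1000``,
    ``generations=50_000``, ``replicates=50``; desk-scale experiments use
    a few hundred individuals over a few thousand generations.  The
    mutation operator perturbs ``mutation_rows_per_individual`` randomly
    chosen codon rows per individual per generation with Normal(0, sigma)
    noise, clips entries to ``probability_floor`` and renormalizes
    (``mutation_rows_per_individual=0`` disables mutation entirely).
    """

    model: NeighbourhoodModel
    population_size: int = 1000
    generations: int = 50_000
    replicates: int = 50
    mutation_sigma: float = 0.05
    mutation_rows_per_individual: int = 1
    probability_floor: float = 1e-6
    seed: int = 0
    log_every: int = 100

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.mutation_sigma <= 0:
            raise ValueError("mutation_sigma must be > 0")
        if not 0 < self.probability_floor < 1 / N_LABELS:
            raise ValueError("probability_floor must lie in (0, 1/21)")
        if self.mutation_rows_per_individual < 0:
            raise ValueError("mutation_rows_per_individual must be >= 0")
        if self.log_every < 1:
            raise ValueError("log_every must be >= 1")
        if isinstance(self.model, str):
            object.__setattr__(self, "model",
                               NeighbourhoodModel.from_name(self.model))


@dataclass
class Trajectory:
    """Logged statistics of one run plus the final population snapshot."""

    generations: np.ndarray   # logged generation indices
    h_av: np.ndarray          # mean population entropy at those generations
    f_best: np.ndarray        # best single-draw fitness
    f_mean: np.ndarray        # mean single-draw fitness
    final_population: np.ndarray  # (n, 64, 21)
    seed: int
    config: EvolutionConfig = field(repr=False)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "generation": self.generations,
            "H_av": self.h_av,
            "F_best": self.f_best,
            "F_mean": self.f_mean,
        })


def mutate(pop: np.ndarray, cfg: EvolutionConfig,
           rng: np.random.Generator) -> np.ndarray:
    """Gaussian row mutation, vectorized over the population.

    For each individual, ``mutation_rows_per_individual`` codon rows are
    chosen uniformly (with replacement across slots); each chosen row gets
    iid Normal(0, sigma) increments and is renormalized with a floor:
    negative entries are clipped to zero and the row is mapped to
    ``floor + (1 - 21*floor) * normalized``, so every mutated entry is
    >= probability_floor and the row sums to 1 exactly.  Returns a new
    array; the input is untouched.
    """
    pop = pop.copy()
    n = pop.shape[0]
    floor = cfg.probability_floor
    for _ in range(cfg.mutation_rows_per_individual):
        rows = rng.integers(0, N_CODONS, size=n)
        noise = rng.normal(0.0, cfg.mutation_sigma, size=(n, N_LABELS))
        idx = np.arange(n)
        perturbed = np.clip(pop[idx, rows] + noise, 0.0, None)
        total = perturbed.sum(axis=1, keepdims=True)
        dead = total[:, 0] == 0.0  # all mass clipped away: reset uniform
        perturbed[dead] = 1.0
        total[dead] = N_LABELS
        pop[idx, rows] = floor + (1 - N_LABELS * floor) * perturbed / total
    return pop


def select(pop: np.ndarray, fitnesses: np.ndarray,
           rng: np.random.Generator) -> np.ndarray:
    """Fitness-proportional resampling with replacement (roulette wheel).

    If every fitness is zero the next generation is resampled uniformly
    (logged as a warning) rather than failing.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    n = pop.shape[0]
    if len(fitnesses) != n:
        raise ValueError("fitness vector length must match population size")
    if (fitnesses < 0).any():
        raise ValueError("fitnesses must be non-negative")
    total = fitnesses.sum()
    if total <= 0.0:
        logger.warning("all fitnesses zero; falling back to uniform resampling")
        idx = rng.integers(0, n, size=n)
    else:
        idx = rng.choice(n, size=n, p=fitnesses / total)
    return pop[idx]


def run_evolution(cfg: EvolutionConfig,
                  rng: np.random.Generator | None = None) -> Trajectory:
    """One simulation run.

    Generation 0 is the freshly initialized random population (uniform-row
    normalization); each subsequent generation applies mutation, a fresh
    stochastic fitness evaluation of every individual, and proportional
    selection.  Statistics are logged at generation 0, every ``log_every``
    generations, and at the final generation (pre-selection state).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    pop = random_population(cfg.population_size, rng)
    gens, h_av, f_best, f_mean = [], [], [], []

    def log_stats(gen, fitness):
        gens.append(gen)
        h_av.append(float(population_entropy(pop).mean()))
        f_best.append(float(fitness.max()))
        f_mean.append(float(fitness.mean()))
        logger.info("gen %d: H_av=%.3f F_best=%.3g", gen, h_av[-1], f_best[-1])

    fitness = population_fitness(pop, cfg.model, rng)
    log_stats(0, fitness)
    for gen in range(1, cfg.generations + 1):
        if cfg.mutation_rows_per_individual:
            pop = mutate(pop, cfg, rng)
        fitness = population_fitness(pop, cfg.model, rng)
        if gen % cfg.log_every == 0 or gen == cfg.generations:
            log_stats(gen, fitness)
        pop = select(pop, fitness, rng)
    return Trajectory(
        generations=np.asarray(gens),
        h_av=np.asarray(h_av),
        f_best=np.asarray(f_best),
        f_mean=np.asarray(f_mean),
        final_population=pop,
        seed=cfg.seed,
        config=cfg,
    )


def run_replicates(cfg: EvolutionConfig) -> list:
    """Independent replicates; replicate i runs with seed ``cfg.seed + i``
    on its own spawned random stream."""
    if cfg.replicates < 1:
        raise ValueError("replicates must be >= 1")
    out = []
    for i in range(cfg.replicates):
        sub = replace(cfg, seed=cfg.seed + i)
        rng = np.random.default_rng(np.random.SeedSequence(sub.seed))
        out.append(run_evolution(sub, rng))
    return out


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean used to smooth trajectory plots."""
    if window < 1:
        raise ValueError("window must be >= 1")
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")
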