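"""Genetic optimization of the two linkage torsions.

The genome is the pair (phi, psi).  A population of 128 pairs is drawn
uniformly within the linkage ranges and evolved for up to eight
generations: the lower-fitness half become parents, children are produced
by gene-wise uniform crossover, each gene mutates with probability 0.2 by
resampling uniformly within its range, children replace the upper half,
and the single best individual always survives (elitism).  Because the
loss is zero exactly when no clash remains, the search stops early as
soon as any individual reaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from glycokit.core.linkage import TorsionRange


@dataclass
class GAConfig:
    population_size: int = 128
    generations: int = 8
    parent_fraction: float = 0.5
    mutation_rate: float = 0.2
    seed: int = 0
    early_exit_on_zero: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0.0 < self.parent_fraction < 1.0):
            raise ValueError("parent_fraction must be in (0, 1)")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass
class GAHistory:
    """Per-generation diagnostics; best_fitness is non-increasing."""

    best_fitness: list[float]
    population_sizes: list[int]
    evaluations: int


def ga_optimize(
    evaluate: Callable[[float, float], float],
    phi_range: TorsionRange,
    psi_range: TorsionRange,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float, GAHistory]:
    """Minimize ``evaluate(phi, psi)`` over the torsion box.

    Returns (phi_best, psi_best, fitness_best, history).  Generation 0 is
    the randomly initialized population; at most ``config.generations``
    populations are evaluated in total.
    """
    config = config or GAConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.population_size
    genomes = np.column_stack([phi_range.sample(rng, n), psi_range.sample(rng, n)])
    fitness = np.array([evaluate(p, s) for p, s in genomes])
    evaluations = n
    order = np.argsort(fitness, kind="stable")
    genomes, fitness = genomes[order], fitness[order]
    history = GAHistory(best_fitness=[float(fitness[0])],
                        population_sizes=[n], evaluations=evaluations)

    def best() -> tuple[float, float, float, GAHistory]:
        history.evaluations = evaluations
        return float(genomes[0, 0]), float(genomes[0, 1]), float(fitness[0]), history

    if config.early_exit_on_zero and fitness[0] == 0.0:
        return best()

    n_parents = max(2, int(round(n * config.parent_fraction)))
    ranges = (phi_range, psi_range)
    for _ in range(1, config.generations):
        parents = genomes[:n_parents]
        n_children = n - n_parents
        mothers = parents[rng.integers(0, n_parents, size=n_children)]
        fathers = parents[rng.integers(0, n_parents, size=n_children)]
        take_mother = rng.random((n_children, 2)) < 0.5
        children = np.where(take_mother, mothers, fathers)
        mutate = rng.random((n_children, 2)) < config.mutation_rate
        for gene in (0, 1):
            hits = np.flatnonzero(mutate[:, gene])
            if len(hits):
                children[hits, gene] = ranges[gene].sample(rng, len(hits))
        child_fitness = np.array([evaluate(p, s) for p, s in children])
        evaluations += n_children
        genomes = np.vstack([parents, children])
        fitness = np.concatenate([fitness[:n_parents], child_fitness])
        order = np.argsort(fitness, kind="stable")
        genomes, fitness = genomes[order], fitness[order]
        history.best_fitness.append(float(fitness[0]))
        history.population_sizes.append(n)
        if config.early_exit_on_zero and fitness[0] == 0.0:
            return best()
    return best()
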