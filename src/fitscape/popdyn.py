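"""Finite-population stochastic dynamics with a hard population cap.

Generations are non-overlapping (Wright-Fisher style).  Each generation:

1. every individual with genotype s leaves Poisson(F(s)) offspring;
2. each offspring gene flips independently with probability p_mut;
3. if the progeny pool exceeds N_popmax, each individual is killed
   independently with probability 1 - N_popmax / N' (the "massacre"), a
   genotype-blind thinning whose expected survivor count is exactly N_popmax.

Mutation acts on offspring: a mutant's fitness only matters from the next
generation on, since its parent's fitness set its birth count.  As
N_popmax grows and p_mut shrinks, one-generation frequency changes converge
to the deterministic replicator update X' = X F / Fbar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpmap import Environment, TraitModel, fitness, trait_expression
from .regulation import adapted_count

__all__ = [
    "Population",
    "SimConfig",
    "SimTrace",
    "mutate",
    "offspring_count",
    "massacre",
    "generation_step",
    "run_simulation",
]


class Population:
    """Multiset of genotypes with integer counts."""

    def __init__(self, genotypes=(), counts=None):
        self._index: dict[bytes, int] = {}
        self.genotypes: list[np.ndarray] = []
        self._counts: list[int] = []
        if counts is None:
            counts = [1] * len(genotypes)
        for g, c in zip(genotypes, counts):
            self.add(g, c)

    def add(self, genotype, count: int = 1) -> None:
        if count < 0:
            raise ValueError("count must be nonnegative")
        if count == 0:
            return
        g = np.asarray(genotype, dtype=np.int8)
        key = g.tobytes()
        if key in self._index:
            self._counts[self._index[key]] += count
        else:
            self._index[key] = len(self.genotypes)
            self.genotypes.append(g)
            self._counts.append(count)

    @property
    def counts(self) -> np.ndarray:
        return np.asarray(self._counts, dtype=np.int64)

    @property
    def size(self) -> int:
        return int(sum(self._counts))

    @property
    def extinct(self) -> bool:
        """Terminal flag: an empty population cannot recover."""
        return self.size == 0

    def count_of(self, genotype) -> int:
        key = np.asarray(genotype, dtype=np.int8).tobytes()
        i = self._index.get(key)
        return 0 if i is None else self._counts[i]

    def frequencies(self) -> np.ndarray:
        n = self.size
        if n == 0:
            raise ValueError("empty population has no frequencies")
        return self.counts / n

    def frequency_of(self, genotype) -> float:
        return self.count_of(genotype) / self.size

    def as_matrix(self) -> np.ndarray:
        return np.stack(self.genotypes) if self.genotypes else np.empty((0, 0), np.int8)


@dataclass
class SimConfig:
    """Configuration of a finite-population simulation."""

    p_mut: float = 0.0
    n_popmax: int = 1000
    n_generations: int = 100
    report_floor: float = 0.01

    def __post_init__(self):
        if not 0 <= self.p_mut <= 1:
            raise ValueError("p_mut must lie in [0, 1]")
        if self.n_popmax < 1:
            raise ValueError("n_popmax must be at least 1")


@dataclass
class SimTrace:
    """Per-generation records of a simulation run."""

    records: pd.DataFrame
    frequencies: list[dict[str, float]]
    final: Population
    extinct: bool = False


def mutate(s, p_mut: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each gene of ``s`` independently with probability p_mut."""
    if not 0 <= p_mut <= 1:
        raise ValueError("p_mut must lie in [0, 1]")
    s = np.asarray(s, dtype=np.int8)
    flips = rng.random(s.shape[0]) < p_mut
    out = s.copy()
    out[flips] = 1 - out[flips]
    return out


def offspring_count(F: float, rng: np.random.Generator) -> int:
    """Poisson-distributed progeny number with mean F."""
    if not (np.isfinite(F) and F > 0):
        raise ValueError("fitness must be finite and positive")
    return int(rng.poisson(F))


def massacre(pool: Population, n_popmax: int, rng: np.random.Generator) -> Population:
    """Cap the progeny pool: i.i.d. survival with probability N_popmax / N'.

    Pools already within the cap are returned unchanged.  The thinning is
    genotype-blind, so expected post-massacre frequencies equal pre-massacre
    frequencies and the expected survivor count is exactly N_popmax.
    """
    n = pool.size
    if n <= n_popmax:
        return pool
    p_survive = n_popmax / n
    out = Population()
    for g, c in zip(pool.genotypes, pool.counts):
        out.add(g, int(rng.binomial(c, p_survive)))
    return out


def generation_step(
    pop: Population,
    model: TraitModel,
    env: Environment,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Population:
    """One generation: Poisson reproduction, offspring mutation, massacre."""
    if pop.extinct:
        return pop
    pool = Population()
    for g, c in zip(pop.genotypes, pop.counts):
        n_off = int(rng.poisson(fitness(g, model, env) * c))  # sum of c iid Poissons
        if n_off == 0:
            continue
        if cfg.p_mut == 0:
            pool.add(g, n_off)
            continue
        flips = rng.random((n_off, g.shape[0])) < cfg.p_mut
        untouched = ~flips.any(axis=1)
        pool.add(g, int(untouched.sum()))
        if (~untouched).any():
            mutants = np.where(flips[~untouched], 1 - g, g).astype(np.int8)
            uniq, counts = np.unique(mutants, axis=0, return_counts=True)
            for m, c_m in zip(uniq, counts):
                pool.add(m, int(c_m))
    return massacre(pool, cfg.n_popmax, rng)


def run_simulation(
    model: TraitModel,
    env: Environment,
    cfg: SimConfig,
    initial: Population,
    rng=None,
) -> SimTrace:
    """Iterate ``generation_step`` for n_generations, recording a trace.

    Records population size, mean fitness, the population-mean adapted-trait
    count, and the frequencies of all genotypes above ``cfg.report_floor``.
    An extinction terminates the run and is flagged on the trace.
    """
    from .gpmap import genotype_to_string

    rng = np.random.default_rng(rng)
    pop = initial
    records, freq_records = [], []

    def snapshot(t):
        fits = np.array([fitness(g, model, env) for g in pop.genotypes])
        x = pop.frequencies()
        adapted = [
            adapted_count(trait_expression(g, model), env) for g in pop.genotypes
        ]
        records.append(
            {
                "generation": t,
                "pop_size": pop.size,
                "mean_fitness": float(x @ fits),
                "mean_adapted": float(x @ np.asarray(adapted, dtype=float)),
            }
        )
        freq_records.append(
            {
                genotype_to_string(g): float(f)
                for g, f in zip(pop.genotypes, x)
                if f >= cfg.report_floor
            }
        )

    snapshot(0)
    for t in range(1, cfg.n_generations + 1):
        pop = generation_step(pop, model, env, cfg, rng)
        if pop.extinct:
            records.append(
                {
                    "generation": t,
                    "pop_size": 0,
                    "mean_fitness": np.nan,
                    "mean_adapted": np.nan,
                }
            )
            freq_records.append({})
            return SimTrace(
                pd.DataFrame.from_records(records), freq_records, pop, extinct=True
            )
        snapshot(t)
    return SimTrace(pd.DataFrame.from_records(records), freq_records, pop)
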