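"""Wright-Fisher evolution of group investment strategies.

A population of ``population_size`` groups, each a clonal cluster of
``group_size`` cells on a shared interaction topology, evolves in
discrete generations at constant population size:

1. each group independently has a ``mutation_probability`` chance of a
   mutation to its developmental program: its whole investment vector
   is redrawn from a truncated Gaussian centered on the current vector
   with per-component standard deviation ``mutation_sd_fraction * v``
   (so a component at exactly 0 is pinned);
2. group fitness is recomputed from the sharing model;
3. groups are ranked by fitness (ties share averaged ranks) and the
   next generation is a multinomial sample of ``population_size``
   groups with probability proportional to rank (worst rank 1, best
   rank population_size).

There is no within-group variation, so selection acts purely on
group-level fitness differences.

Two modes are supported.  ``fixed_sharing`` uses one interaction
strength ``beta`` for every cell throughout.  ``evolving_sharing``
starts with no sharing at all (all per-cell beta = 0) and lets sharing
itself evolve: with the same per-group mutation probability, one
uniformly chosen cell's beta is redrawn from a truncated Gaussian
centered on its current value with sd
``max(mutation_sd_fraction * beta, beta_sd_floor)``.  The floor keeps
beta = 0 from being absorbing (a proportional-sd kernel centered at
zero could otherwise never leave it); set it to 0 for the strict
proportional kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .sharing import build_sharing, group_fitness, group_fitness_population
from .topology import Topology

__all__ = [
    "EvolutionConfig",
    "PopulationState",
    "initialize_population",
    "mutate_strategy",
    "mutate_beta",
    "selection_probabilities",
    "select_offspring",
    "run_evolution",
]

MODES = ("fixed_sharing", "evolving_sharing")


@dataclass
class EvolutionConfig:
    """Parameters of one evolutionary run (defaults follow the standard protocol)."""

    population_size: int = 1000
    group_size: int = 10
    generations: int = 1000
    mutation_probability: float = 0.02
    mutation_sd_fraction: float = 0.1
    mode: str = "fixed_sharing"
    alpha: float = 1.0
    beta: float = 1.0
    beta_sd_floor: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.group_size < 1 or self.generations < 0:
            raise ValueError("counts must be positive")
        for name in ("mutation_probability", "beta"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_sd_fraction < 0 or self.beta_sd_floor < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PopulationState:
    """Strategies (and per-cell betas in evolving mode) of every group."""

    strategies: np.ndarray                 # (population_size, group_size)
    fitnesses: np.ndarray                  # (population_size,)
    generation: int = 0
    cell_betas: np.ndarray | None = None   # (population_size, group_size) or None


def initialize_population(cfg: EvolutionConfig, rng: np.random.Generator) -> PopulationState:
    """Uniform-random strategies; all-zero per-cell betas in evolving mode."""
    strategies = rng.uniform(0.0, 1.0, size=(cfg.population_size, cfg.group_size))
    betas = None
    if cfg.mode == "evolving_sharing":
        betas = np.zeros((cfg.population_size, cfg.group_size))
    return PopulationState(
        strategies=strategies,
        fitnesses=np.zeros(cfg.population_size),
        generation=0,
        cell_betas=betas,
    )


def _truncated_gaussian(center: np.ndarray, sd: np.ndarray,
                        rng: np.random.Generator, max_tries: int = 100) -> np.ndarray:
    """Componentwise Gaussian truncated to [0, 1]: rejection then clamp."""
    x = rng.normal(center, sd)
    out = (x < 0.0) | (x > 1.0)
    tries = 0
    while out.any() and tries < max_tries:
        x = np.where(out, rng.normal(center, sd), x)
        out = (x < 0.0) | (x > 1.0)
        tries += 1
    return np.clip(x, 0.0, 1.0)


def mutate_strategy(v: np.ndarray, sd_fraction: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Redraw a whole strategy from a truncated Gaussian with sd proportional to v."""
    v = np.asarray(v, dtype=float)
    return _truncated_gaussian(v, sd_fraction * v, rng)


def mutate_beta(betas: np.ndarray, sd_fraction: float, rng: np.random.Generator,
                sd_floor: float = 0.01) -> np.ndarray:
    """Perturb exactly one uniformly chosen cell's interaction strength."""
    betas = np.asarray(betas, dtype=float).copy()
    k = int(rng.integers(betas.size))
    sd = max(sd_fraction * betas[k], sd_floor)
    betas[k] = _truncated_gaussian(np.array([betas[k]]), np.array([sd]), rng)[0]
    return betas


def selection_probabilities(fitnesses: np.ndarray) -> np.ndarray:
    """Rank-proportional selection weights (ties share averaged ranks)."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if np.any(fitnesses < 0):
        raise ValueError("fitnesses must be nonnegative")
    ranks = rankdata(fitnesses, method="average")
    return ranks / ranks.sum()


def select_offspring(fitnesses: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multinomial sample (with replacement) of parent indices, rank-weighted."""
    p = selection_probabilities(fitnesses)
    return rng.choice(p.size, size=p.size, p=p)


def _fitness_one(v: np.ndarray, t: Topology, betas: np.ndarray, alpha: float) -> float:
    return group_fitness(v, build_sharing(t, betas), alpha)


def run_evolution(cfg: EvolutionConfig, t: Topology) -> tuple[PopulationState, pd.DataFrame]:
    """Run the full mutation/selection loop; reproducible from cfg.seed.

    Returns the final population and a per-generation trajectory frame
    (generation, mean_fitness, max_fitness, mean_specialization,
    mean_beta) of length generations + 1 including the initial state.
    Fitness is only recomputed for groups whose strategy or sharing
    mutated; offspring inherit their parent's cached fitness.
    """
    if t.n_cells != cfg.group_size:
        raise ValueError(
            f"topology has {t.n_cells} cells but config group_size is {cfg.group_size}"
        )
    rng = np.random.default_rng(cfg.seed)
    state = initialize_population(cfg, rng)
    evolving = cfg.mode == "evolving_sharing"
    c_fixed = None if evolving else build_sharing(t, cfg.beta)

    if evolving:
        state.fitnesses = np.array([
            _fitness_one(state.strategies[g], t, state.cell_betas[g], cfg.alpha)
            for g in range(cfg.population_size)
        ])
    else:
        state.fitnesses = group_fitness_population(state.strategies, c_fixed, cfg.alpha)

    n_rec = cfg.generations + 1
    rec = {
        "generation": np.arange(n_rec),
        "mean_fitness": np.empty(n_rec),
        "max_fitness": np.empty(n_rec),
        "mean_specialization": np.empty(n_rec),
        "mean_beta": np.empty(n_rec),
    }

    def record(gen: int) -> None:
        rec["mean_fitness"][gen] = state.fitnesses.mean()
        rec["max_fitness"][gen] = state.fitnesses.max()
        rec["mean_specialization"][gen] = np.mean(np.abs(2.0 * state.strategies - 1.0))
        rec["mean_beta"][gen] = (
            state.cell_betas.mean() if evolving else cfg.beta
        )

    record(0)
    for gen in range(1, cfg.generations + 1):
        # mutation: whole-strategy redraw; in evolving mode the sharing
        # program mutates independently with the same per-group probability
        mut_v = np.flatnonzero(rng.random(cfg.population_size) < cfg.mutation_probability)
        for g in mut_v:
            state.strategies[g] = mutate_strategy(
                state.strategies[g], cfg.mutation_sd_fraction, rng
            )
        touched = set(mut_v.tolist())
        if evolving:
            mut_b = np.flatnonzero(
                rng.random(cfg.population_size) < cfg.mutation_probability
            )
            for g in mut_b:
                state.cell_betas[g] = mutate_beta(
                    state.cell_betas[g], cfg.mutation_sd_fraction, rng,
                    sd_floor=cfg.beta_sd_floor,
                )
            touched |= set(mut_b.tolist())

        if touched:
            idx = np.array(sorted(touched))
            if evolving:
                for g in idx:
                    state.fitnesses[g] = _fitness_one(
                        state.strategies[g], t, state.cell_betas[g], cfg.alpha
                    )
            else:
                state.fitnesses[idx] = group_fitness_population(
                    state.strategies[idx], c_fixed, cfg.alpha
                )

        parents = select_offspring(state.fitnesses, rng)
        state.strategies = state.strategies[parents]
        state.fitnesses = state.fitnesses[parents]
        if evolving:
            state.cell_betas = state.cell_betas[parents]
        state.generation = gen
        record(gen)

    return state, pd.DataFrame(rec)
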