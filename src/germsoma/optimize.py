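"""Numerical maximization of group fitness and parameter sweeps.

Fitness optima frequently sit on the boundary of the strategy cube
(complete specialists, v in {0, 1}) where the gradient diverges for
alpha < 1.  The search therefore combines three ingredients:

* multi-start bounded L-BFGS-B with the analytic gradient, strategies
  clamped to [eps, 1-eps] during the search;
* exact evaluation of boundary candidates: each local optimum rounded
  coordinate-wise to {0, 1}, the generalist, alternating specialist
  patterns and (where the graph is bipartite) the two-coloring
  specialist assignments;
* a single-coordinate flip hill climb on the best binary candidate.

The generalist is always among the candidates, so the reported optimum
never falls below the generalist fitness.

Specialization of a strategy is scored as
S = (2/N) sum_i (max(v_i, 1-v_i) - 1/2), i.e. the mean of |2 v - 1|:
0 for all-generalists, 1 for complete specialists.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .sharing import as_strategy, build_sharing, fitness_gradient, group_fitness
from .topology import Topology, make_topology

__all__ = [
    "specialization_score",
    "OptimizationResult",
    "maximize_fitness",
    "sparsity_sweep",
    "phase_map",
]

_EPS = 1e-9


def specialization_score(v) -> float:
    """Mean distance of investments from 1/2, scaled to [0, 1]."""
    v = as_strategy(v)
    return float(np.mean(np.abs(2.0 * v - 1.0)))


@dataclass(frozen=True)
class OptimizationResult:
    best_strategy: np.ndarray
    best_fitness: float
    specialization: float
    n_restarts: int
    converged: bool


def _boundary_candidates(t: Topology) -> list[np.ndarray]:
    """Exact specialist patterns worth testing on any topology."""
    n = t.n_cells
    cands = [np.full(n, 0.5)]
    alt = (np.arange(n) % 2).astype(float)
    cands += [alt, 1.0 - alt]
    g = t.to_networkx()
    if n > 1 and nx.is_bipartite(g):
        color = nx.algorithms.bipartite.color(g)
        side = np.array([color[i] for i in range(n)], dtype=float)
        cands += [side, 1.0 - side]
    return cands


def _flip_hill_climb(v: np.ndarray, c: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Greedy single-coordinate {0,1}-flip ascent from a binary strategy."""
    v = v.copy()
    w = group_fitness(v, c, alpha)
    improved = True
    while improved:
        improved = False
        for k in range(v.size):
            trial = v.copy()
            trial[k] = 1.0 - trial[k]
            wt = group_fitness(trial, c, alpha)
            if wt > w + 1e-12:
                v, w = trial, wt
                improved = True
    return v, w


def maximize_fitness(t: Topology, alpha: float, beta: float, restarts: int = 20,
                     seed: int | None = None) -> OptimizationResult:
    """Numerically maximize group fitness over strategies in [0, 1]^N.

    Deterministic given ``seed``.  ``restarts`` uniform-random interior
    starts are used in addition to the generalist and one random binary
    strategy; boundary roundings of every local optimum are evaluated
    exactly and a binary flip hill climb refines the best one.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    n = t.n_cells
    c = build_sharing(t, beta)
    bounds = [(_EPS, 1.0 - _EPS)] * n

    starts = [np.full(n, 0.5)]
    starts += [rng.uniform(0.0, 1.0, size=n) for _ in range(restarts)]
    starts.append(rng.integers(0, 2, size=n).astype(float))

    candidates: list[np.ndarray] = list(_boundary_candidates(t))
    converged = False
    for x0 in starts:
        res = minimize(
            lambda v: -group_fitness(v, c, alpha),
            np.clip(x0, _EPS, 1.0 - _EPS),
            jac=lambda v: -fitness_gradient(v, c, alpha),
            method="L-BFGS-B",
            bounds=bounds,
        )
        converged = converged or bool(res.success)
        candidates.append(res.x)
        candidates.append(np.round(res.x))  # exact boundary version

    best_v, best_w = None, -np.inf
    for v in candidates:
        w = group_fitness(v, c, alpha)
        if w > best_w:
            best_v, best_w = v, w

    # refine the best binary rounding by coordinate flips
    vb, wb = _flip_hill_climb(np.round(best_v), c, alpha)
    if wb > best_w:
        best_v, best_w = vb, wb

    return OptimizationResult(
        best_strategy=best_v.copy(),
        best_fitness=float(best_w),
        specialization=specialization_score(best_v),
        n_restarts=restarts,
        converged=converged,
    )


def sparsity_sweep(n: int, connection_fractions, alphas, replicates: int = 10,
                   seed: int | None = None, beta: float = 1.0,
                   restarts: int = 20) -> pd.DataFrame:
    """Mean specialization of the fitness optimum on random graphs.

    For each (connection fraction, alpha) grid cell, ``replicates``
    Erdős–Rényi graphs are drawn with edge probability equal to the
    fraction of possible connections present, fitness is maximized at
    the given beta, and the specialization of each optimum is recorded.
    Disconnected realizations are kept, not resampled.  Returns a tidy
    frame with one row per grid cell: fraction, alpha, mean_S, mean_W,
    replicates.
    """
    fractions = list(connection_fractions)
    alphas = list(alphas)
    if not fractions or not alphas:
        raise ValueError("grids must be nonempty")
    ss = np.random.SeedSequence(seed)
    rows = []
    for frac in fractions:
        for alpha in alphas:
            child = ss.spawn(1)[0]
            sub_seeds = child.generate_state(2 * replicates, dtype=np.uint32)
            s_vals, w_vals = [], []
            for r in range(replicates):
                g = make_topology("erdos_renyi", n, p=float(frac),
                                  seed=int(sub_seeds[2 * r]))
                res = maximize_fitness(g, alpha, beta, restarts=restarts,
                                       seed=int(sub_seeds[2 * r + 1]))
                s_vals.append(res.specialization)
                w_vals.append(res.best_fitness)
            rows.append({
                "fraction": frac,
                "alpha": alpha,
                "mean_S": float(np.mean(s_vals)),
                "mean_W": float(np.mean(w_vals)),
                "replicates": replicates,
            })
    return pd.DataFrame(rows)


def phase_map(t: Topology, alphas, betas, mode: str = "optimize",
              seed: int | None = None, restarts: int = 20,
              evolution_overrides: dict | None = None) -> pd.DataFrame:
    """Specialization over an (alpha, beta) grid on a fixed topology.

    ``mode='optimize'`` records the specialization of the numerically
    maximized strategy per cell; ``mode='evolve'`` runs a Wright-Fisher
    simulation per cell and records the final population-mean
    specialization (``evolution_overrides`` tunes population size,
    generations, etc.).  Returns a tidy frame: alpha, beta, mean_S,
    mean_W.
    """
    alphas = list(alphas)
    betas = list(betas)
    if not alphas or not betas:
        raise ValueError("grids must be nonempty")
    if mode not in ("optimize", "evolve"):
        raise ValueError(f"unknown phase-map mode {mode!r}")
    ss = np.random.SeedSequence(seed)
    rows = []
    for beta in betas:
        for alpha in alphas:
            cell_seed = int(ss.spawn(1)[0].generate_state(1, dtype=np.uint32)[0])
            if mode == "optimize":
                res = maximize_fitness(t, alpha, beta, restarts=restarts,
                                       seed=cell_seed)
                mean_s, mean_w = res.specialization, res.best_fitness
            else:
                from .wright_fisher import EvolutionConfig, run_evolution

                overrides = dict(evolution_overrides or {})
                for fixed in ("group_size", "alpha", "beta", "seed"):
                    overrides.pop(fixed, None)
                cfg = EvolutionConfig(
                    group_size=t.n_cells, alpha=alpha, beta=beta,
                    seed=cell_seed, **overrides,
                )
                state, _ = run_evolution(cfg, t)
                mean_s = float(np.mean(np.abs(2.0 * state.strategies - 1.0)))
                mean_w = float(np.mean(state.fitnesses))
            rows.append({"alpha": alpha, "beta": beta,
                         "mean_S": mean_s, "mean_W": mean_w})
    return pd.DataFrame(rows)
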