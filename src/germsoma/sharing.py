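"""Viability sharing and group fitness.

Each cell in a group of N cells splits a unit budget between viability
(v) and fecundity (b = 1 - v).  Returns on investment are the powers
v**alpha and b**alpha; alpha > 1 gives accelerating (convex) returns,
alpha < 1 saturating (concave) returns.  Viability returns can be
shared with network neighbors: a cell passes a fraction beta of its
viability returns equally to itself and its graph neighbors and keeps
the rest, so the giver-by-receiver sharing matrix ``c`` has

    c[i, i] = 1 - beta_i + beta_i / n_i
    c[i, j] = beta_i / n_i      if i and j are connected, else 0

with n_i the neighbor count including the cell itself.  Rows sum to 1:
a cell distributes exactly what it produced.  Fecundity returns cannot
be shared.  Group fitness is the summed product of each cell's own
fecundity returns with the viability returns it ends up holding,

    W = sum_i (1 - v_i)**alpha * sum_j v_j**alpha c[j, i],

the group-level reproduction rate.  This module provides the sharing
matrix, the fitness, its analytic gradient and Hessian, closed forms
for named configurations, and a two-good generalization in which
fecundity is also shared through its own matrix.

The convention 0**alpha = 0 (alpha > 0) keeps pure specialists
well-defined on the boundary of the strategy space even for alpha < 1.
At the boundary the gradient and Hessian of W diverge for alpha < 1;
they are returned with signed-infinite entries rather than raising.
"""

from __future__ import annotations

import numpy as np

from .topology import Topology

__all__ = [
    "build_sharing",
    "as_strategy",
    "viability_returns",
    "group_fitness",
    "group_fitness_population",
    "closed_form_fitness",
    "fitness_gradient",
    "fitness_hessian",
    "group_fitness_two_goods",
]


def build_sharing(t: Topology, beta) -> np.ndarray:
    """Build the giver-by-receiver sharing matrix from a topology.

    ``beta`` may be a scalar (every cell shares the same fraction) or a
    length-N vector of per-cell interaction strengths in [0, 1]; the
    vector form supports simulations in which sharing itself evolves.
    """
    n = t.n_cells
    beta = np.broadcast_to(np.asarray(beta, dtype=float), (n,)).copy()
    if np.any(beta < 0.0) or np.any(beta > 1.0):
        raise ValueError("beta must lie in [0, 1]")
    n_self = t.degrees_with_self().astype(float)
    share = beta / n_self
    c = t.adjacency.astype(float) * share[:, None]
    np.fill_diagonal(c, 1.0 - beta + share)
    return c


def as_strategy(v, n_cells: int | None = None) -> np.ndarray:
    """Validate a per-cell viability-investment vector (components in [0, 1])."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("a strategy must be a 1-D vector")
    if n_cells is not None and v.shape[0] != n_cells:
        raise ValueError(f"strategy has {v.shape[0]} cells, expected {n_cells}")
    if np.any(v < 0.0) or np.any(v > 1.0):
        raise ValueError("strategy components must lie in [0, 1]")
    return v


def viability_returns(v, c: np.ndarray, alpha: float) -> np.ndarray:
    """Incoming viability returns per cell: component i is sum_j v_j**alpha c[j, i]."""
    v = as_strategy(v, c.shape[0])
    return np.power(v, alpha) @ c


def group_fitness(v, c: np.ndarray, alpha: float) -> float:
    """Group fitness W = sum_i (1 - v_i)**alpha * (incoming viability)_i."""
    v = as_strategy(v, c.shape[0])
    return float(np.power(1.0 - v, alpha) @ (np.power(v, alpha) @ c))


def group_fitness_population(strategies: np.ndarray, c: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized group fitness for a (n_groups, N) array of strategies."""
    va = np.power(strategies, alpha)
    ba = np.power(1.0 - strategies, alpha)
    return np.einsum("gi,gi->g", ba, va @ c)


def closed_form_fitness(kind: str, n: int, alpha: float | None = None,
                        beta: float | None = None) -> float:
    """Closed-form group fitness for named reference configurations.

    ``ring_specialist``: alternating complete specialists on an even
    ring, W = beta * n / 3.  ``ring_generalist``: all cells at v = 1/2
    on a ring, W = n * (1/2)**(2 alpha).  ``disconnected_optimum``: the
    best a group of isolated cells can do, also n * (1/2)**(2 alpha).
    """
    if kind == "ring_specialist":
        if n % 2 != 0:
            raise ValueError("ring_specialist requires even n (alternating pattern)")
        if beta is None:
            raise ValueError("ring_specialist requires beta")
        return beta * n / 3.0
    if kind in ("ring_generalist", "disconnected_optimum"):
        if alpha is None:
            raise ValueError(f"{kind} requires alpha")
        return n * 0.5 ** (2.0 * alpha)
    raise ValueError(f"unknown closed form {kind!r}")


def fitness_gradient(v, c: np.ndarray, alpha: float) -> np.ndarray:
    """Analytic gradient of W with respect to the investment vector.

    Component k is
    alpha * (v_k**(a-1) sum_j c[k,j] (1-v_j)**a - (1-v_k)**(a-1) sum_j c[j,k] v_j**a).
    For alpha < 1 it diverges at v_k in {0, 1}; divergent components
    come back as signed infinities.
    """
    v = as_strategy(v, c.shape[0])
    b = 1.0 - v
    with np.errstate(divide="ignore", invalid="ignore"):
        va, ba = np.power(v, alpha), np.power(b, alpha)
        va1, ba1 = np.power(v, alpha - 1.0), np.power(b, alpha - 1.0)
        grad = alpha * (va1 * (c @ ba) - ba1 * (c.T @ va))
    return grad


def fitness_hessian(v, c: np.ndarray, alpha: float) -> np.ndarray:
    """Analytic Hessian of W; symmetric, validated against finite differences.

    Off-diagonal (k, l):
        -alpha**2 * (v_k**(a-1) c[k,l] (1-v_l)**(a-1)
                     + (1-v_k)**(a-1) c[l,k] v_l**(a-1))
    Diagonal (k, k):
        alpha (alpha-1) (v_k**(a-2) sum_j c[k,j](1-v_j)**a
                         + (1-v_k)**(a-2) sum_j c[j,k] v_j**a)
        - 2 alpha**2 c[k,k] v_k**(a-1) (1-v_k)**(a-1)
    """
    v = as_strategy(v, c.shape[0])
    b = 1.0 - v
    a = alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        va, ba = np.power(v, a), np.power(b, a)
        va1, ba1 = np.power(v, a - 1.0), np.power(b, a - 1.0)
        va2, ba2 = np.power(v, a - 2.0), np.power(b, a - 2.0)
        h = -(a * a) * (np.outer(va1, ba1) * c + np.outer(ba1, va1) * c.T)
        diag = a * (a - 1.0) * (va2 * (c @ ba) + ba2 * (c.T @ va)) \
            - 2.0 * a * a * np.diag(c) * va1 * ba1
        np.fill_diagonal(h, diag)
    return h


def group_fitness_two_goods(v, c_viability: np.ndarray, c_fecundity: np.ndarray,
                            alpha: float) -> float:
    """Group fitness when fecundity returns are shared as well.

    W = sum_i (sum_j (1-v_j)**alpha c_fec[j, i]) (sum_j v_j**alpha c_via[j, i]).
    With an identity fecundity matrix this reduces exactly to
    :func:`group_fitness`; with asymmetric sharing of the two goods,
    specialization can remain adaptive under saturating returns.
    """
    if c_viability.shape != c_fecundity.shape:
        raise ValueError("the two sharing matrices must have the same shape")
    v = as_strategy(v, c_viability.shape[0])
    va = np.power(v, alpha)
    ba = np.power(1.0 - v, alpha)
    return float((ba @ c_fecundity) @ (va @ c_viability))
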