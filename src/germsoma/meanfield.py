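"""Mean-field theory of specialist versus generalist fitness.

Idealized large group of N cells, each connected to z others, analyzed
at alpha = 1 and beta = 1 (the linear-returns, full-sharing corner: if
specialists beat generalists here, they also do for some alpha < 1).
Generalists (all v = 1/2) have W_G = N/4.  With a fraction X of cells
as fecundity specialists (v = 0) and the rest viability specialists
(v = 1), each viability specialist shares 1/(z+1) with each neighbor,
and the assortment f — the mean fraction of a fecundity specialist's
neighbors that are viability specialists — determines what arrives:

    W_S = z f X N / (z + 1)

Specialists are favored (strictly) when W_S / W_G > 1, i.e. when
f > 1/(4X) + 1/(4Xz); at the balanced split X = 1/2 this is
f > 1/2 + 1/(2z).  Since f <= 1, specialization under saturating
returns further requires X > 1/4 + 1/(4z): it is impossible when fewer
than a quarter of cells (in the z -> inf limit) are fecundity
specialists.  A fully connected graph with a half/half split has
f = 1/2, which never exceeds the threshold — the classical result that
well-mixed groups need accelerating returns.

``measure_f`` evaluates the assortment on a concrete labeled graph;
on irregular graphs each fecundity cell's own degree replaces z (a
natural extension of the mean-field definition, flagged as such).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .topology import Topology

__all__ = [
    "MeanFieldParams",
    "generalist_fitness_mf",
    "specialist_fitness_mf",
    "f_threshold",
    "min_fecundity_fraction",
    "specialists_favored_mf",
    "measure_f",
]

LABELS = ("viability", "fecundity")


@dataclass(frozen=True)
class MeanFieldParams:
    """N cells, z neighbors each, assortment f, fecundity-specialist fraction X."""

    n: int
    z: int
    f: float
    x: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.z < 0:
            raise ValueError("z must be >= 0")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("f must lie in [0, 1]")
        if not (0.0 <= self.x <= 1.0):
            raise ValueError("x must lie in [0, 1]")


def generalist_fitness_mf(n: int) -> float:
    """Group fitness of all-generalists: W_G = N/4 (v = b = 1/2 everywhere)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n / 4.0


def specialist_fitness_mf(p: MeanFieldParams) -> float:
    """Mean-field specialist fitness W_S = z f X N / (z + 1)."""
    return p.z * p.f * p.x * p.n / (p.z + 1.0)


def f_threshold(z: int, x: float = 0.5) -> float:
    """Assortment needed for specialists to beat generalists: 1/(4X) + 1/(4Xz)."""
    if z < 1:
        raise ValueError("z must be >= 1")
    if not (0.0 < x <= 1.0):
        raise ValueError("x must lie in (0, 1]")
    return 1.0 / (4.0 * x) + 1.0 / (4.0 * x * z)


def min_fecundity_fraction(z: int) -> float:
    """Smallest fecundity-specialist fraction admitting specialization: 1/4 + 1/(4z)."""
    if z < 1:
        raise ValueError("z must be >= 1")
    return 0.25 + 1.0 / (4.0 * z)


def specialists_favored_mf(p: MeanFieldParams) -> bool:
    """True iff W_S strictly exceeds W_G (equivalently f > f_threshold)."""
    return specialist_fitness_mf(p) > generalist_fitness_mf(p.n)


def measure_f(t: Topology, labels) -> float:
    """Empirical assortment on a labeled graph.

    ``labels`` assigns each cell 'viability' or 'fecundity'.  Returns
    the mean, over fecundity cells of degree >= 1, of the fraction of
    their neighbors labeled viability.  Fecundity cells with no
    neighbors are excluded with a warning; it is an error if no
    eligible cell remains.
    """
    labels = list(labels)
    if len(labels) != t.n_cells:
        raise ValueError(f"expected {t.n_cells} labels, got {len(labels)}")
    bad = sorted(set(labels) - set(LABELS))
    if bad:
        raise ValueError(f"unknown labels {bad}; expected {LABELS}")
    adj = t.adjacency
    is_v = np.array([lab == "viability" for lab in labels])
    fractions = []
    skipped = 0
    for i in range(t.n_cells):
        if is_v[i]:
            continue
        deg = int(adj[i].sum())
        if deg == 0:
            skipped += 1
            continue
        fractions.append(adj[i][is_v].sum() / deg)
    if skipped:
        warnings.warn(
            f"excluded {skipped} isolated fecundity cell(s) from the assortment mean",
            stacklevel=2,
        )
    if not fractions:
        raise ValueError("no fecundity-labeled cell with degree >= 1")
    return float(np.mean(fractions))
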