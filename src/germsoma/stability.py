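"""Stability analysis of the generalist strategy.

The complete generalist strategy (every cell at v = 1/2) is a critical
point of group fitness whenever the sharing matrix is symmetric.  Its
character is decided by the Hessian H* of W evaluated there: if H* is
negative definite the generalists sit at a fitness maximum; once the
largest eigenvalue crosses zero, complete generalization cannot
maximize group fitness and some degree of specialization must.

For the complete, ring (nearest-neighbor) and balanced bipartite
networks the largest eigenvalue has printed closed forms

    alpha (1/2)**(2 alpha - 3) * (-1 + alpha beta)            complete
    alpha (1/2)**(2 alpha - 3) * (-1 + (4/3) alpha beta)      ring
    alpha (1/2)**(2 alpha - 3) * (-1 + (2N/(N+2)) alpha beta) bipartite

so generalists destabilize at the critical products alpha*beta of 1,
3/4 and (N+2)/(2N) respectively.

alpha* is the value of alpha at which the largest eigenvalue of H*
crosses zero at beta = 1.  It depends only on topology and serves as a
proxy for how amenable a network is to specialization under saturating
returns: the smaller alpha*, the more readily specialization is
favored.  For irregular networks (c != c^T) the generalist is not even
a critical point, but alpha* computed the same way remains a useful
proxy; reports carry a warning flag in that case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq

from .sharing import build_sharing, fitness_hessian
from .topology import Topology

__all__ = [
    "StabilityReport",
    "hessian_at_generalist",
    "largest_eigenvalue_at_generalist",
    "generalist_is_optimal",
    "alpha_star",
    "analytic_threshold",
    "stability_report",
]

#: critical value of the product alpha*beta beyond which generalists destabilize
_THRESHOLD_KINDS = ("complete", "ring", "balanced_bipartite")


@dataclass(frozen=True)
class StabilityReport:
    """Spectrum summary of the generalist-strategy Hessian for one topology."""

    largest_eigenvalue: float
    negative_definite: bool
    alpha: float
    beta: float
    alpha_star: float | None
    symmetric_sharing: bool

    def to_dict(self) -> dict:
        return asdict(self)


def hessian_at_generalist(t: Topology, alpha: float, beta: float) -> np.ndarray:
    """Hessian of group fitness at the all-1/2 generalist strategy."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    c = build_sharing(t, beta)
    v = np.full(t.n_cells, 0.5)
    return fitness_hessian(v, c, alpha)


def largest_eigenvalue_at_generalist(t: Topology, alpha: float, beta: float) -> float:
    h = hessian_at_generalist(t, alpha, beta)
    return float(np.linalg.eigvalsh(h)[-1])


def generalist_is_optimal(t: Topology, alpha: float, beta: float,
                          tol: float | None = None) -> bool:
    """Whether the generalist strategy is a strict fitness maximum.

    True iff every eigenvalue of H* is below ``-tol`` (default
    1e-10 * N).  Exact only when the sharing matrix is symmetric
    (uniform beta on a degree-regular graph); otherwise the generalist
    is not a critical point and the answer is advisory — a warning is
    emitted.
    """
    if tol is None:
        tol = 1e-10 * t.n_cells
    c = build_sharing(t, beta)
    if not np.allclose(c, c.T):
        warnings.warn(
            "sharing matrix is not symmetric: the generalist strategy is not "
            "a critical point and this stability verdict is only advisory",
            stacklevel=2,
        )
    h = hessian_at_generalist(t, alpha, beta)
    return bool(np.all(np.linalg.eigvalsh(h) < -tol))


def alpha_star(t: Topology, bracket: tuple[float, float] = (0.01, 3.0),
               tol: float = 1e-6) -> float | None:
    """alpha at which the top Hessian eigenvalue at v=1/2, beta=1 crosses zero.

    Found by bisection (Brent) on the largest eigenvalue over
    ``bracket``; returns None when the eigenvalue does not change sign
    there (e.g. fully disconnected cells, for which generalists are
    stable at every alpha).
    """
    lo, hi = bracket

    def lam(a: float) -> float:
        return largest_eigenvalue_at_generalist(t, a, 1.0)

    f_lo, f_hi = lam(lo), lam(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        return None
    return float(brentq(lam, lo, hi, xtol=tol))


def analytic_threshold(kind: str, n: int | None = None) -> float:
    """Critical product (alpha*beta)* destabilizing generalists, closed form.

    1 for the complete graph, 3/4 for the ring, (N+2)/(2N) for the
    balanced bipartite network on N cells.
    """
    if kind == "complete":
        return 1.0
    if kind == "ring":
        return 0.75
    if kind == "balanced_bipartite":
        if n is None or n % 2 != 0:
            raise ValueError("balanced_bipartite threshold requires an even n")
        return (n + 2) / (2.0 * n)
    raise ValueError(f"unknown threshold kind {kind!r}; expected one of {_THRESHOLD_KINDS}")


def stability_report(t: Topology, alpha: float, beta: float,
                     tol: float | None = None) -> StabilityReport:
    """Full stability summary at one (alpha, beta), including alpha*."""
    if tol is None:
        tol = 1e-10 * t.n_cells
    c = build_sharing(t, beta)
    symmetric = bool(np.allclose(c, c.T))
    eigs = np.linalg.eigvalsh(hessian_at_generalist(t, alpha, beta))
    lam_max = float(eigs[-1])
    return StabilityReport(
        largest_eigenvalue=lam_max,
        negative_definite=bool(np.all(eigs < -tol)),
        alpha=alpha,
        beta=beta,
        alpha_star=alpha_star(t),
        symmetric_sharing=symmetric,
    )
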