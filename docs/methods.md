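# Methods

## Model

A multicellular group is N clonal cells on an undirected interaction
graph.  Cell i invests vᵢ ∈ [0, 1] in viability and bᵢ = 1 − vᵢ in
fecundity; returns are vᵢ^α and bᵢ^α.  Viability returns are shared:
with interaction strength β ∈ [0, 1], cell i distributes a fraction β
of its returns equally among itself and its neighbors (nᵢ = degree + 1
shares) and keeps the rest, so the giver-by-receiver matrix c has
c_ii = 1 − β + β/nᵢ and c_ij = β/nᵢ on edges.  Rows sum to one: cells
cannot give away more than they produce, and always keep a positive
share (c_ii > 0).  Fecundity is intrinsically unsharable.  Group
fitness is W = Σᵢ bᵢ^α Σⱼ vⱼ^α c_ji — selection acts on groups, not on
cells, and there is no within-group variation.

Assumptions worth keeping in mind: cells are identical apart from
their investments (no positional effects); the graph is fixed during a
group's life; per-cell output is the product of fecundity returns and
*received* viability returns, so a cell with either factor zero
contributes nothing.

Boundary convention: 0^α = 0 for all α > 0, so complete specialists
are well-defined even with concave returns.  The gradient and Hessian
of W diverge on the boundary for α < 1; they are returned with
signed-infinite entries rather than raising, and the optimizer works
on a clamped interior (below).

## Analytics

The gradient of W is zero at the generalist strategy v = ½·1 whenever
c = cᵀ (uniform β on a degree-regular graph).  The Hessian there
decides stability.  We differentiate W directly:

* off-diagonal (k, ℓ):
  −α² [v_k^{α−1} c_kℓ (1−v_ℓ)^{α−1} + (1−v_k)^{α−1} c_ℓk v_ℓ^{α−1}]
* diagonal (k, k):
  α(α−1) [v_k^{α−2} Σⱼ c_kj (1−v_j)^α + (1−v_k)^{α−2} Σⱼ c_jk v_j^α]
  − 2α² c_kk v_k^{α−1} (1−v_k)^{α−1}

At v = ½·1 with uniform β this reduces to
α (½)^{2α−3} [(α−1) I − α (c + cᵀ)/2], whose top eigenvalue reproduces
the closed forms α(½)^{2α−3}(−1 + αβ), (−1 + (4/3)αβ) and
(−1 + (2N/(N+2))αβ) for the complete, ring and balanced bipartite
networks; the test suite verifies this to 1e-8 relative over an
(α, β) grid and checks the general formulas against central finite
differences at random interior strategies.  The all-ones vector is
always an eigenvector with negative eigenvalue when c = cᵀ, so the
generalist point is never a minimum — only a maximum or a saddle.

α* is the root in α of the top Hessian eigenvalue at v = ½·1, β = 1.
It is found by Brent's method on the bracket (0.01, 3.0) with xtol
1e-6 (the eigenvalue is continuous in α; topologies with no sign
change in the bracket, e.g. fully disconnected cells, get a None
sentinel).  Negative-definiteness uses the tolerance eigenvalue <
−1e-10·N.  For irregular graphs c ≠ cᵀ: the generalist is then not a
critical point, the stability verdict is advisory and carries a
warning, but α* is still computed the same way as an amenability
proxy.  Note one internal tension in the source material for the
fully connected case: the eigenvalue formula puts its α* at 1 (at
β = 1), and that is what the implementation returns.

## Numerical optimization

`maximize_fitness` runs L-BFGS-B (scipy) with the analytic gradient
from 20 uniform-random starts plus the generalist and one random
binary strategy, with box bounds [1e-9, 1 − 1e-9] because the gradient
is singular on the boundary for α < 1.  Because optima often sit
exactly on the boundary, each local optimum is also rounded
coordinate-wise to {0, 1} and evaluated exactly; alternating and (for
bipartite graphs) two-coloring specialist patterns are evaluated as
well, and a greedy single-coordinate flip hill climb refines the best
binary candidate.  The generalist is always a candidate, so the result
never falls below generalist fitness.  Ties break first-found.  No
global-optimality certificate is claimed.

Sweeps parameterize Erdős–Rényi sparsity as the fraction of the
N(N−1)/2 possible edges present; disconnected realizations are kept.
Per-cell seeds are spawned from a SeedSequence so grids are
reproducible and embarrassingly parallel in principle.

## Wright–Fisher simulation

Defaults: 1000 groups of 10 cells, 1000 generations, per-group
mutation probability 0.02 per generation.  A mutation redraws the
whole investment vector from a componentwise Gaussian centered on the
current vector with sd = 0.1·vᵢ, truncated to [0, 1] (rejection
sampling capped at 100 redraws, then clamped).  The proportional sd
pins components at exactly 0 — initial uniform strategies almost
surely avoid that point, so no floor is applied to strategy mutation.
Selection: groups are ranked by fitness (ties get averaged ranks) and
the next generation is a multinomial sample with probability
proportional to rank; with two groups the weights are (1/3, 2/3), and
the top-ranked of 𝒩 groups expects 2𝒩/(𝒩+1) offspring.  Linear rank
weights are the simplest reading of rank-weighted selection.

In evolving-sharing mode every cell carries its own β, all starting at
0, and an independent 2%-per-group process redraws one uniformly
chosen cell's β from a truncated Gaussian with
sd = max(0.1·β, sd_floor).  A proportional kernel centered at 0 can
never leave 0, so the floor (default 0.01, configurable down to 0)
is what lets sharing arise at all; strategy mutation continues in this
mode, since specialization and sharing must co-evolve for specialists
to be selected.  Fitness is cached per group and recomputed only on
mutation; offspring inherit the parent's value, which makes long runs
cheap without changing the dynamics.

## Mean field

For N ≫ 1 cells with z neighbors each, at α = β = 1: generalists give
W_G = N/4; with a fraction X of fecundity specialists and assortment f
(mean fraction of a fecundity specialist's neighbors that are
viability specialists), W_S = zfXN/(z+1).  Specialists win strictly
iff f > 1/(4X) + 1/(4Xz) (at X = ½: f > ½ + 1/(2z)), which requires
X > ¼ + 1/(4z).  `measure_f` evaluates f on concrete labeled graphs;
on irregular graphs each cell's own degree replaces z — a natural
extension of the definition, flagged as such, since the mean-field z
is undefined there.  Constructing graphs that achieve a prescribed
(f, z, X) is a graph-coloring problem and out of scope.

## What the simulations do and do not show

All experiments are self-contained: graphs are generated
programmatically and strategies are synthetic.  The model abstracts
away cell growth, death, spatial embedding, positional heterogeneity
and within-group mutation; passing tests show the mathematical model
behaves as derived, not that any particular organism does.  The
two-good fitness variant is provided as a hook (it reduces exactly to
the one-good model with an identity fecundity matrix) but asymmetric
two-good parameter studies are not reproduced here.

Test problem sizes are chosen for quick desk runs: phase maps by
evolution use populations of 200 for 200 generations on 10-cell
topologies over the 11×11 (α, β) grid — enough for ≥90% of cells at
αβ-distance ≥ 0.1 from the analytic boundary to classify correctly —
and sparsity sweeps use 10 replicates of N = 10 graphs.  Full-scale
runs (𝒩 = 1000, 1000 generations, denser grids) use the same code
paths via the defaults and the CLI.  A caveat observed in the phase
maps: just below the local-stability boundary of the complete graph at
large α, boundary (specialist) optima can already beat generalists, so
classification by the Hessian boundary is conservative there.

## Known limitations

* Odd rings: the nearest-neighbor eigenvalue formula (−1 + (4/3)αβ) is
  exact for even cycles; odd cycles differ by O(1/n²) through the
  graph spectrum.
* α* bracketing assumes a single sign change in (0.01, 3.0); exotic
  topologies with multiple crossings would need a custom bracket.
* The Wright–Fisher trajectory records final-generation population
  means; time-averaged summaries can be computed from the trajectory
  frame if needed.
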