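# Methods

## Model

`routewalk` models communication on a weighted undirected network as a
target-absorbing Markov chain. Edge weights are *proximities* (larger =
stronger connection, e.g. streamline density between brain parcels). They
are first mapped onto the open unit interval by the unique affine function
sending the smallest nonzero weight to ϵ and the largest to 1 − ϵ:

    w̄ = ((1 − 2ϵ)·w + (2ϵ − 1)·MIN(w)) / (MAX(w) − MIN(w)) + ϵ ,  0 < ϵ < 0.5

with ϵ = MIN(w) by default. Proximities become additive distances through
`d_ij = −ln(w̄_ij)`. The natural-log base is forced by the λ = 0 identity:
only with base *e* does `exp(−d_ij) = w̄_ij`, making the zero-bias walk the
weight-proportional unbiased walk `w̄_ij / s_i` exactly.

For bias strength λ ≥ 0 and target *t*, the transition probability from *i*
to neighbor *j* is

    P_λ(j | i, t) = exp(−(λ·(d_ij + g_jt) + d_ij)) / Z_it

where `g_jt` is the geodesic distance from *j* to *t* and `Z_it` normalizes
the row. `d_ij` is the walker's local information; `d_ij + g_jt` — the length
of the best route to the target through *j* — is global information whose
influence λ controls. The target row is absorbing. Expected visit counts
before absorption come from the fundamental matrix `n = (I − Q)⁻¹` of the
absorbing chain, computed by one dense LU factorization per target (never an
explicit inverse); a singular system is reported as an unreachable-target
error, not patched.

Costs:

- immediate transmission cost `c^trans(i,t) = Σ_j P(j|i,t)·d_ij`;
  pairwise cost `C^trans(i,t) = Σ_k n(i,k)·c^trans(k,t)` — the mean walk
  length. It is bounded below by the geodesic and reaches it at λ = ∞,
  where the matrix also becomes symmetric.
- immediate informational cost `c^info(i,t) = KL(P_λ(·|i,t) ‖ P_ref(·|i,t))`
  in bits (base-2 log); pairwise cost is the visit-frequency-weighted
  average `Σ_k (n(i,k)/Σ_r n(i,r))·c^info(k,t)`. It is 0 at λ = 0 and
  non-negative everywhere. Distances stay in natural-log units; the two
  scales are never mixed arithmetically.

Nodal source/target averages divide by N with the zero self term included
(`C→(i) = (1/N)Σ_t C(i,t)`), exactly as the formulas are written rather
than by N − 1. Grand means likewise run over all N² ordered pairs; self
pairs contribute 0. This inflates nothing but scales all averages by
(N−1)/N relative to the self-pair-excluding convention.

## λ → ∞ limit and degenerate paths

The shortest-path limit is a distinct symbolic branch, never a large float
pushed through the finite-λ formula: at each node, probability mass is
restricted to the set S of neighbors lying on some shortest path to the
target and split within S proportionally to `exp(−d_ij)` (uniform when all
admissible distances are equal). Membership in S uses the tolerance
`|d_ij + g_jt − g_it| ≤ 1e−9 · max(1, g_it)`; the tolerance is a numerical
choice for floating-point geodesics, with no empirical significance. Finite-λ
rows are computed with a per-row max-shift before exponentiation so large
λ·(d+g) terms cannot underflow a row to zero.

Convergence of finite λ to this limit is tested at λ = 50 on fixtures whose
competing path lengths differ by ≥ 0.4 nats; on graphs with near-ties
(common in random weighted graphs) λ = 50 is not yet converged, which is a
property of the model, not an error.

## λ grid and trade-off areas

The default grid has 60 points uniform in ln λ on [−6, 3.2], plus the λ = 0
point and optionally a terminal λ = ∞. Trade-off curves normalize the mean
transmission cost by its λ = 0 value (decaying from 1) and the mean
informational cost by its value at the largest finite grid λ (growing to 1).
Areas under the normalized curves use the trapezoid rule over ln λ across
the finite positive grid points; λ = 0 cannot appear in a ln-λ integral and
serves only as the normalizer. Monotonicity of the two mean curves in λ is
an observed property of the shipped fixture networks, asserted with
tolerance 1e−9, not a theorem.

## Null ensembles

Each null member preserves the binary degree sequence (Maslov–Sneppen
double-edge swaps; swaps that would disconnect the graph or create
self-/multi-edges are rejected and retried, with a logged warning if the
swap quota — default 10 per edge — is unreachable within 100× attempts),
the exact nonzero-weight multiset (weights are shuffled onto the rewired
edges), and approximately the strength sequence: simulated annealing
minimizes `C = Σ_i |s_i − r_i|` by proposing weight-pair swaps with
Metropolis acceptance `exp(−ΔC/T)`. The schedule is 123 temperature stages
from t₀ = 100 cooled geometrically by 0.125 per stage — which reaches
effectively zero temperature within ~10 stages, so most of the schedule is
greedy — with `⌈E·ln E⌉` proposals per stage (E = edge count; the per-stage
proposal count is a design choice balancing mixing against runtime). Both
the cooling factor and the proposal count are configurable.

Strength matching quality depends on the richness of the weight multiset:
at connectome-like density (≈300 edges on 48–64 nodes) the worst per-node
discrepancy is ~1–3% of mean strength, while on very sparse toy graphs
(tens of edges) the discrete multiset cannot fine-tune node sums and the
residual can exceed 5%. Connectivity of every member is enforced (the
absorbing-chain machinery requires irreducibility).

Empirical cost curves are normalized by the ensemble mean (`‖C‖` ratios;
values < 1 mark regimes where the empirical network out-performs its
randomized counterparts) and nodal costs are z-scored per node, per λ, per
measure against the ensemble distributions, with a two-sided significance
mask at α = 0.01 by default. Nodes with zero ensemble SD get NaN z-scores,
masked and logged.

## Privileged routing

A privileged set holds the top `round(fraction·N)` nodes of a centrality
ranking — geodesic betweenness, strength, shortest-path closeness (inverse
mean geodesic), random-walk closeness (inverse mean first-passage time in
steps to the node as target under the unbiased walk), or a seeded random
draw — with ties broken by ascending node index. In a hybrid strategy only
privileged rows receive the λ bias; all other rows equal the reference, so
their informational cost is exactly 0.

Stretch is defined per source node as the mean over targets (divisor N,
self term 0, mirroring the C→ convention) of
`|C^trans_hybrid(i,t) − g_it|` at λ = ∞. Because non-privileged motion is
stochastic, only the *expected* hybrid walk length is well defined, and
that is what the stretch uses; aggregation over sources rather than targets
is a design choice for symmetry with the source-closeness measure.

## Synthetic networks

`synth_connectome` draws a modular graph (balanced round-robin module
assignment; default 64 nodes, 4 modules, intra/inter edge densities
0.35/0.05) with edge weights `w̄ = exp(−X)`, X log-normal (default
logmean 0, logsd 0.5, capped at 36 to keep w̄ in (0, 1)), so edge distances
are log-normal by construction — the distributional signature reported for
cortical connection strengths. Hubs (default 4, spread across modules)
receive both a connection-probability boost (×3, capped at 0.95) and
shortened incident distances (÷√3), the rich-club signature that makes hub
strengths dominate robustly; with hubs present the distance distribution is
therefore a lognormal mixture, and the pure-lognormal goodness-of-fit
property holds for hub-free configurations. Disconnected draws are retried
with an incremented sub-seed (≤ 20 attempts). Everything is fully
determined by the seed.

What these generators do *not* emulate: empirical degree sequences of any
specific parcellation, spatial embedding and distance-dependent wiring
costs, inter-subject variability, or measurement noise in tractography.
Tests passing on them show internal consistency of the machinery and the
qualitative cost phenomenology (spectrum shape, hub asymmetry), not
quantitative claims about real connectomes.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: spectra on
64-node networks over the 61-point default grid, 20-member null ensembles
on 48-node networks, 5 × 10⁴–10⁵ simulated walks per Monte-Carlo check.
Row-stochasticity is enforced to 1e−12; symmetry tolerance for input
adjacency matrices is relative 1e−8 (beyond it the input is rejected, not
silently symmetrized); `0·log(0/q)` is treated as 0 in KL terms, and mass
outside the reference support raises an error rather than returning
infinity. All randomness flows through explicitly seeded PCG64 generators;
no global RNG state is used, and results are independent of the degree of
parallelism (computation is sequential per target).

## Known limitations

- λ is a single global attribute (or a binary privileged/non-privileged
  split); continuously node-varying λ(i) is out of scope.
- No congestion or traffic-capacity modelling; costs are upper bounds under
  the all-pairs-equally-salient assumption.
- First-order walks only: transition probabilities do not condition on
  visited history.
- The literal annealing schedule is effectively greedy after ~10 stages;
  a slower cooling factor can be configured where deeper optimization of
  the strength match is wanted.
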