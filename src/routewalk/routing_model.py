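"""λ-biased routing strategies and their absorbing-chain analysis.

A routing strategy for target ``t`` is a row-stochastic matrix whose row ``i``
gives the probability of a walker at ``i`` stepping to each neighbor ``j``:

    P_λ(j | i, t)  ∝  exp(−(λ·(d_ij + g_jt) + d_ij))

``d_ij`` is local information (the edge distance) and ``d_ij + g_jt`` is
global information (the shortest route to the target through ``j``).  λ = 0
recovers the unbiased walk ``w̄_ij / s_i`` (the reference strategy); λ → ∞
concentrates all mass on shortest-path edges, with degenerate ties split in
proportion to ``exp(−d_ij)``.  The target row is absorbing, making each
strategy an absorbing Markov chain whose fundamental matrix
``(I − Q)⁻¹`` yields expected visit counts before absorption.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, LinAlgWarning, lu_factor, lu_solve

from .graph_core import DEGENERACY_RTOL, DistanceGraph, WeightedNetwork

#: symbolic λ value selecting the exact shortest-path limit.
INF = math.inf


class RoutingModelError(ValueError):
    """Invalid routing-model parameters."""


class AbsorptionError(RuntimeError):
    """The target cannot be reached from some state under the strategy."""


@dataclass
class RoutingStrategy:
    """Target-conditioned transition matrix for one bias strength λ.

    ``trans[i, j]`` is the probability of stepping from ``i`` to ``j``; the
    target row is absorbing.  ``edge_dist`` is kept so that walks can be
    scored by accumulated distance.
    """

    lam: float
    target: int
    trans: np.ndarray
    support: np.ndarray
    edge_dist: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.trans.shape[0]


@dataclass
class AbsorbingChain:
    """Fundamental-matrix view of a strategy with the target absorbing.

    ``visits[i, k]`` is the expected number of times a walker from source
    ``i`` occupies node ``k`` before absorption; both indices run over the
    full node set but the target row/column are zero by construction (the
    fundamental matrix is over non-absorbing states only).
    """

    target: int
    Q: np.ndarray
    visits: np.ndarray


def _finite_lambda_rows(dist: np.ndarray, g_t: np.ndarray, lam: float) -> np.ndarray:
    """Row-normalized exp(−(λ(d+g)+d)) with a per-row max-shift.

    The shift (log-sum-exp trick) keeps rows from underflowing to zero when
    λ·(d+g) is large.
    """
    n = dist.shape[0]
    trans = np.zeros((n, n))
    for i in range(n):
        nbrs = np.flatnonzero(np.isfinite(dist[i]))
        expo = -(lam * (dist[i, nbrs] + g_t[nbrs]) + dist[i, nbrs])
        expo -= expo.max()
        p = np.exp(expo)
        trans[i, nbrs] = p / p.sum()
    return trans


def build_strategy(
    net: WeightedNetwork, dg: DistanceGraph, lam: float, target: int
) -> RoutingStrategy:
    """Construct the finite-λ biased strategy for one target.

    At λ = 0 this reduces to ``trans[i, j] = w̄_ij / s_i`` for every
    non-target row; pass ``lam=INF`` through :func:`make_strategy` (or call
    :func:`shortest_path_limit_strategy`) for the exact λ → ∞ limb.
    """
    if not 0 <= lam < math.inf:
        raise RoutingModelError(
            f"lam must be finite and nonnegative, got {lam}; "
            "use shortest_path_limit_strategy for the λ→∞ limit"
        )
    if dg.geodesic is None:
        raise RoutingModelError("geodesics not computed on the distance graph")
    _check_target(net, target)
    trans = _finite_lambda_rows(dg.edge_dist, dg.geodesic[:, target], lam)
    _make_absorbing(trans, target)
    return RoutingStrategy(
        lam=float(lam),
        target=target,
        trans=trans,
        support=np.isfinite(dg.edge_dist),
        edge_dist=dg.edge_dist,
    )


def shortest_path_limit_strategy(
    net: WeightedNetwork, dg: DistanceGraph, target: int
) -> RoutingStrategy:
    """The exact λ → ∞ strategy: mass only on shortest-path edges.

    At each node the admissible set S holds the neighbors on some shortest
    path to the target (degenerate ties included, tolerance
    ``DEGENERACY_RTOL``); within S mass is split ∝ exp(−d_ij), which is
    uniform when all admissible edge distances are equal.
    """
    if dg.geodesic is None:
        raise RoutingModelError("geodesics not computed on the distance graph")
    _check_target(net, target)
    n = net.n_nodes
    trans = np.zeros((n, n))
    preds = dg.predecessors(target)
    for i in range(n):
        if i == target:
            continue
        S = preds[i]
        if not S:
            raise AbsorptionError(
                f"no shortest-path neighbor from node {i} to target {target}"
            )
        p = np.exp(-dg.edge_dist[i, S])
        trans[i, S] = p / p.sum()
    _make_absorbing(trans, target)
    return RoutingStrategy(
        lam=INF,
        target=target,
        trans=trans,
        support=np.isfinite(dg.edge_dist),
        edge_dist=dg.edge_dist,
    )


def make_strategy(
    net: WeightedNetwork, dg: DistanceGraph, lam: float, target: int
) -> RoutingStrategy:
    """Dispatch between the finite-λ formula and the symbolic λ=INF limb."""
    if lam == INF:
        return shortest_path_limit_strategy(net, dg, target)
    return build_strategy(net, dg, lam, target)


def reference_strategy(net: WeightedNetwork, target: int) -> RoutingStrategy:
    """The unbiased walk P^ref: transitions ∝ normalized weight, λ = 0.

    Rows do not depend on the target except for the absorbing target row.
    """
    _check_target(net, target)
    trans = net.norm_weights / net.strengths[:, None]
    _make_absorbing(trans, target)
    mask = net.norm_weights != 0
    dist = np.full_like(net.norm_weights, np.inf)
    dist[mask] = -np.log(net.norm_weights[mask])
    return RoutingStrategy(
        lam=0.0, target=target, trans=trans, support=mask, edge_dist=dist
    )


def _make_absorbing(trans: np.ndarray, target: int) -> None:
    trans[target, :] = 0.0
    trans[target, target] = 1.0


def _check_target(net: WeightedNetwork, target: int) -> None:
    if not 0 <= target < net.n_nodes:
        raise RoutingModelError(f"target {target} out of range")


def fundamental_matrix(strategy: RoutingStrategy) -> AbsorbingChain:
    """Expected visit counts before absorption: solve (I − Q)·N = I.

    One dense LU factorization per target serves every source.  A singular
    system means the target is unreachable from some state under the
    strategy's support and raises :class:`AbsorptionError`.
    """
    t = strategy.target
    n = strategy.n_nodes
    keep = np.array([i for i in range(n) if i != t])
    Q = strategy.trans[np.ix_(keep, keep)]
    A = np.eye(n - 1) - Q
    try:
        with warnings.catch_warnings():
            # near-singularity is diagnosed explicitly below
            warnings.simplefilter("ignore", LinAlgWarning)
            lu, piv = lu_factor(A)
    except LinAlgError as exc:  # pragma: no cover - lu_factor rarely raises
        raise AbsorptionError("target unreachable under the strategy") from exc
    # lu_factor does not signal exact singularity; check the diagonal of U.
    udiag = np.abs(np.diag(lu))
    if udiag.size and udiag.min() < 1e-12 * max(1.0, udiag.max()):
        raise AbsorptionError(
            f"(I - Q) singular: target {t} unreachable from some state"
        )
    nfund = lu_solve((lu, piv), np.eye(n - 1))
    if not np.all(np.isfinite(nfund)) or np.any(nfund < -1e-9):
        raise AbsorptionError("invalid expected visit counts; chain not absorbing")
    visits = np.zeros((n, n))
    visits[np.ix_(keep, keep)] = nfund
    return AbsorbingChain(target=t, Q=Q, visits=visits)


# ---------------------------------------------------------------------------
# Monte-Carlo walk simulation (test oracle)
# ---------------------------------------------------------------------------

@dataclass
class WalkRecord:
    nodes: list[int]
    distance: float
    truncated: bool


def simulate_walk(
    strategy: RoutingStrategy, source: int, rng_seed: int, max_steps: int = 10_000
) -> WalkRecord:
    """Sample one walk from ``source`` until absorption or ``max_steps``.

    Fully determined by ``rng_seed`` (a fresh PCG64 generator per call).
    """
    if max_steps <= 0:
        raise RoutingModelError("max_steps must be positive")
    _check_source(strategy, source)
    rng = np.random.default_rng(rng_seed)
    t = strategy.target
    nodes = [source]
    dist = 0.0
    cur = source
    for _ in range(max_steps):
        if cur == t:
            break
        nxt = int(rng.choice(strategy.n_nodes, p=strategy.trans[cur]))
        dist += strategy.edge_dist[cur, nxt]
        nodes.append(nxt)
        cur = nxt
    if source == t:
        return WalkRecord(nodes=[], distance=0.0, truncated=False)
    return WalkRecord(nodes=nodes, distance=dist, truncated=cur != t)


def simulate_walks(
    strategy: RoutingStrategy,
    source: int,
    n_walks: int,
    rng: np.random.Generator,
    max_steps: int = 100_000,
):
    """Vectorized walk ensemble: (mean distance, SE, visit means, visit SEs).

    Visit counts include the starting occupation of ``source`` and exclude
    the target, matching the fundamental-matrix convention.
    """
    _check_source(strategy, source)
    t = strategy.target
    n = strategy.n_nodes
    cum = np.cumsum(strategy.trans, axis=1)
    cur = np.full(n_walks, source, dtype=np.int64)
    dist = np.zeros(n_walks)
    visits = np.zeros((n_walks, n))
    visits[:, source] = 1.0
    active = cur != t
    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        u = rng.random(idx.size)
        nxt = np.empty(idx.size, dtype=np.int64)
        for node in np.unique(cur[idx]):
            sel = cur[idx] == node
            nxt[sel] = np.searchsorted(cum[node], u[sel], side="right")
        dist[idx] += strategy.edge_dist[cur[idx], nxt]
        cur[idx] = nxt
        arrived = nxt == t
        live = idx[~arrived]
        visits[live, cur[live]] += 1.0
        active[idx[arrived]] = False
    mean = float(dist.mean())
    se = float(dist.std(ddof=1) / math.sqrt(n_walks))
    visit_se = visits.std(axis=0, ddof=1) / math.sqrt(n_walks)
    return mean, se, visits.mean(axis=0), visit_se


def _check_source(strategy: RoutingStrategy, source: int) -> None:
    if not 0 <= source < strategy.n_nodes:
        raise RoutingModelError(f"source {source} out of range")


def write_strategy(strategy: RoutingStrategy, path) -> None:
    """Export the dense transition matrix as CSV for inspection."""
    header = f"lambda={strategy.lam},target={strategy.target}"
    np.savetxt(path, strategy.trans, delimiter=",", header=header, fmt="%.12g")
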