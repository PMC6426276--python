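"""Transmission and informational cost of λ-biased routing.

Two competing costs characterize a routing strategy.  The *transmission
cost* ``C^trans_λ(i, t)`` is the mean walk length (total edge distance) from
source to target — it falls toward the geodesic as the bias λ grows.  The
*informational cost* ``C^info_λ(i, t)`` is the visit-frequency-weighted
Kullback–Leibler divergence (in bits) of the strategy from the unbiased
reference walk — it grows with λ, quantifying how much global information
is baked into the dynamics.  Both are assembled per target from the
absorbing chain's expected visit counts:

    C^trans_λ(i,t) = Σ_k n^t_λ(i,k) · c^trans_λ(k,t)
    C^info_λ(i,t)  = Σ_k n^t_λ(i,k)/Σ_r n^t_λ(i,r) · c^info_λ(k,t)

Nodal source/target averages of either matrix act as dynamic closeness
centralities; λ-grid curves and normalized areas under them summarize where
a network sits on the diffusion ↔ shortest-path spectrum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_core import DistanceGraph, WeightedNetwork
from .routing_model import (
    INF,
    AbsorbingChain,
    RoutingModelError,
    RoutingStrategy,
    fundamental_matrix,
    make_strategy,
    reference_strategy,
)


class CostError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Immediate (per-node) costs
# ---------------------------------------------------------------------------

def immediate_transmission_cost(strategy: RoutingStrategy, node: int) -> float:
    """Expected distance of the next hop from ``node``: Σ_j P(j|node,t)·d.

    Zero at the target (the walk has ended).
    """
    if node == strategy.target:
        return 0.0
    p = strategy.trans[node]
    nbrs = np.flatnonzero(p > 0)
    return float(np.dot(p[nbrs], strategy.edge_dist[node, nbrs]))


def node_informational_cost(
    strategy: RoutingStrategy, reference: RoutingStrategy, node: int
) -> float:
    """KL(P_λ(·|node,t) ‖ P^ref(·|node,t)) in bits; 0·log(0/q) = 0."""
    if node == strategy.target:
        return 0.0
    p = strategy.trans[node]
    q = reference.trans[node]
    nz = p > 0
    if np.any(q[nz] <= 0):
        raise CostError(
            f"strategy puts mass outside the reference support at node {node}"
        )
    return float(np.sum(p[nz] * np.log2(p[nz] / q[nz])))


def _immediate_trans_vec(strategy: RoutingStrategy) -> np.ndarray:
    n = strategy.n_nodes
    return np.array([immediate_transmission_cost(strategy, i) for i in range(n)])


def _info_vec(strategy: RoutingStrategy, reference: RoutingStrategy) -> np.ndarray:
    n = strategy.n_nodes
    return np.array(
        [node_informational_cost(strategy, reference, i) for i in range(n)]
    )


# ---------------------------------------------------------------------------
# Pairwise costs for one target
# ---------------------------------------------------------------------------

def pairwise_transmission_cost(
    chain: AbsorbingChain, strategy: RoutingStrategy, dg: DistanceGraph
) -> np.ndarray:
    """Mean walk length from every source to the chain's target.

    ``C(i,t) = Σ_k n(i,k)·c^trans(k,t)``; entry at the target itself is 0.
    """
    _check_shared_target(chain, strategy)
    c = _immediate_trans_vec(strategy)
    out = chain.visits @ c
    out[strategy.target] = 0.0
    return out


def pairwise_informational_cost(
    chain: AbsorbingChain, strategy: RoutingStrategy, reference: RoutingStrategy
) -> np.ndarray:
    """Visit-frequency-weighted KL cost from every source to the target."""
    _check_shared_target(chain, strategy)
    c = _info_vec(strategy, reference)
    t = strategy.target
    totals = chain.visits.sum(axis=1)
    out = np.zeros(strategy.n_nodes)
    src = np.array([i for i in range(strategy.n_nodes) if i != t])
    out[src] = (chain.visits[src] @ c) / totals[src]
    return out


def _check_shared_target(chain: AbsorbingChain, strategy: RoutingStrategy) -> None:
    if chain.target != strategy.target:
        raise CostError(
            f"chain target {chain.target} != strategy target {strategy.target}"
        )


def nodal_averages(cost: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Source and target averages of a pairwise cost matrix.

    ``C→(i) = (1/N)Σ_t C(i,t)`` and ``C←(t) = (1/N)Σ_i C(i,t)``; the divisor
    is N exactly as printed, the zero self term included.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise CostError("cost matrix must be square")
    n = cost.shape[0]
    return cost.sum(axis=1) / n, cost.sum(axis=0) / n


# ---------------------------------------------------------------------------
# λ-grid curves
# ---------------------------------------------------------------------------

def default_lambda_grid(
    n_points: int = 60,
    min_ln: float = -6.0,
    max_ln: float = 3.2,
    include_zero: bool = True,
    include_inf: bool = False,
) -> np.ndarray:
    """λ values uniform in ln λ, optionally bracketed by 0 and INF."""
    grid = list(np.exp(np.linspace(min_ln, max_ln, n_points)))
    if include_zero:
        grid = [0.0] + grid
    if include_inf:
        grid = grid + [INF]
    return np.array(grid)


@dataclass
class CostProfile:
    """Pairwise and nodal costs over a λ grid.

    ``trans_cost``/``info_cost`` have shape (L, N, N), entry [l, i, t] is the
    source-i → target-t cost at grid point l.  Nodal vectors (L, N) and grand
    means (L,) average over all ordered pairs with the 1/N convention.
    """

    lam_grid: np.ndarray
    trans_cost: np.ndarray
    info_cost: np.ndarray
    src_trans: np.ndarray
    tgt_trans: np.ndarray
    src_info: np.ndarray
    tgt_info: np.ndarray
    mean_trans: np.ndarray
    mean_info: np.ndarray


def cost_curves(
    net: WeightedNetwork,
    dg: DistanceGraph,
    lam_grid,
    strategy_factory=None,
) -> CostProfile:
    """Full cost profile: one strategy and absorbing chain per (λ, target).

    ``strategy_factory(lam, target) -> RoutingStrategy`` may replace the
    default fully biased model (used for privileged-node hybrids).  Grand
    means average the pairwise matrices over all N² ordered pairs (self
    pairs contribute 0).
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.ndim != 1 or lam_grid.size == 0:
        raise CostError("lam_grid must be a nonempty 1-D sequence")
    finite_part = lam_grid[np.isfinite(lam_grid)]
    if np.any(np.diff(lam_grid) <= 0):
        raise CostError("lam_grid must be strictly increasing")
    if np.any(~np.isfinite(lam_grid[:-1])):
        raise CostError("INF allowed only as the final grid element")
    if np.any(finite_part < 0):
        raise CostError("lambda values must be nonnegative")
    if strategy_factory is None:
        strategy_factory = lambda lam, t: make_strategy(net, dg, lam, t)

    n = net.n_nodes
    L = lam_grid.size
    trans = np.zeros((L, n, n))
    info = np.zeros((L, n, n))
    refs = [reference_strategy(net, t) for t in range(n)]
    for li, lam in enumerate(lam_grid):
        for t in range(n):
            try:
                strat = strategy_factory(lam, t)
                chain = fundamental_matrix(strat)
            except (RoutingModelError, CostError) as exc:
                raise type(exc)(f"at lambda={lam}, target={t}: {exc}") from exc
            trans[li, :, t] = pairwise_transmission_cost(chain, strat, dg)
            info[li, :, t] = pairwise_informational_cost(chain, strat, refs[t])

    src_trans = trans.sum(axis=2) / n
    tgt_trans = trans.sum(axis=1) / n
    src_info = info.sum(axis=2) / n
    tgt_info = info.sum(axis=1) / n
    return CostProfile(
        lam_grid=lam_grid,
        trans_cost=trans,
        info_cost=info,
        src_trans=src_trans,
        tgt_trans=tgt_trans,
        src_info=src_info,
        tgt_info=tgt_info,
        mean_trans=trans.reshape(L, -1).mean(axis=1),
        mean_info=info.reshape(L, -1).mean(axis=1),
    )


# ---------------------------------------------------------------------------
# Trade-off summary
# ---------------------------------------------------------------------------

@dataclass
class TradeoffSummary:
    """Normalized cost curves and areas under them over ln λ.

    The transmission curve is normalized by its value at λ = 0 (decaying from
    1); the informational curve by its value at the largest finite grid λ
    (growing to 1).  Areas use the trapezoid rule over ln λ on the finite
    positive grid points; λ = 0 only anchors the normalization.
    """

    lam_grid: np.ndarray
    norm_trans_curve: np.ndarray
    norm_info_curve: np.ndarray
    auc_trans: float
    auc_info: float


def tradeoff_summary(profile: CostProfile) -> TradeoffSummary:
    grid = profile.lam_grid
    if grid[0] != 0.0:
        raise CostError("grid must contain lambda = 0 to normalize C_trans")
    finite_pos = np.flatnonzero(np.isfinite(grid) & (grid > 0))
    if finite_pos.size < 2:
        raise CostError("grid needs at least two finite positive lambda points")
    t0 = profile.mean_trans[0]
    imax = finite_pos[-1]
    iref = profile.mean_info[imax]
    if t0 <= 0 or iref <= 0:
        raise CostError("degenerate cost curves cannot be normalized")
    norm_trans = profile.mean_trans / t0
    norm_info = profile.mean_info / iref
    x = np.log(grid[finite_pos])
    auc_t = float(np.trapezoid(norm_trans[finite_pos], x))
    auc_i = float(np.trapezoid(norm_info[finite_pos], x))
    return TradeoffSummary(
        lam_grid=grid,
        norm_trans_curve=norm_trans,
        norm_info_curve=norm_info,
        auc_trans=auc_t,
        auc_info=auc_i,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def profile_to_frame(profile: CostProfile) -> pd.DataFrame:
    """Tidy long-format table: lambda, source, target, trans_cost, info_cost."""
    L, n, _ = profile.trans_cost.shape
    lam = np.repeat(profile.lam_grid, n * n)
    src = np.tile(np.repeat(np.arange(n), n), L)
    tgt = np.tile(np.arange(n), L * n)
    return pd.DataFrame(
        {
            "lambda": lam,
            "source": src,
            "target": tgt,
            "trans_cost": profile.trans_cost.ravel(),
            "info_cost": profile.info_cost.ravel(),
        }
    )


def summary_to_json(profile: CostProfile, summary: TradeoffSummary | None = None) -> str:
    """Grand means, grid, and (optionally) normalized-curve areas as JSON."""
    payload = {
        "lam_grid": [None if math.isinf(x) else x for x in profile.lam_grid],
        "mean_trans": list(profile.mean_trans),
        "mean_info": list(profile.mean_info),
    }
    if summary is not None:
        payload["auc_trans"] = summary.auc_trans
        payload["auc_info"] = summary.auc_info
    return json.dumps(payload, indent=2)
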