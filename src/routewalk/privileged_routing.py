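"""Hybrid routing where only a privileged subset of nodes is biased.

Global information is expensive; a cheaper regime lets only the top-ranked
nodes under some centrality (betweenness, strength, shortest-path closeness,
random-walk closeness, or a random draw) reshape their transition rows with
the λ bias while every other node keeps the unbiased reference row.  The
*stretch* of a node measures how much expected walk length is lost relative
to fully informed shortest-path routing when only the privileged set is
informed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .cost_measures import CostProfile, cost_curves, pairwise_transmission_cost
from .graph_core import DistanceGraph, WeightedNetwork
from .routing_model import (
    INF,
    RoutingStrategy,
    fundamental_matrix,
    make_strategy,
    reference_strategy,
)

RANKINGS = ("betweenness", "strength", "sp_closeness", "rw_closeness", "random")


class PrivilegedError(ValueError):
    pass


@dataclass(frozen=True)
class PrivilegedSet:
    members: frozenset[int]
    ranking: str
    fraction: float
    rng_seed: int | None = None


def rank_nodes(net: WeightedNetwork, dg: DistanceGraph, method: str) -> list[int]:
    """Nodes in descending centrality order; ties broken by ascending index.

    betweenness: geodesic betweenness on edge distances.  strength: Σ_j w̄.
    sp_closeness: inverse mean geodesic distance to all other nodes.
    rw_closeness: inverse mean first-passage time (in steps) from all other
    nodes to the node under the unbiased walk — a target closeness.
    """
    if dg.geodesic is None:
        raise PrivilegedError("geodesics not computed")
    n = net.n_nodes
    if method == "betweenness":
        G = nx.from_numpy_array(np.where(np.isfinite(dg.edge_dist), dg.edge_dist, 0.0))
        bc = nx.betweenness_centrality(G, weight="weight", normalized=False)
        score = np.array([bc[i] for i in range(n)])
    elif method == "strength":
        score = net.strengths.copy()
    elif method == "sp_closeness":
        mean_g = (dg.geodesic.sum(axis=1)) / (n - 1)
        score = 1.0 / mean_g
    elif method == "rw_closeness":
        mfpt = np.zeros(n)
        for t in range(n):
            chain = fundamental_matrix(reference_strategy(net, t))
            steps = chain.visits.sum(axis=1)  # expected steps to absorption
            mfpt[t] = steps[np.arange(n) != t].mean()
        score = 1.0 / mfpt
    else:
        raise PrivilegedError(
            f"unknown ranking {method!r}; choose from {RANKINGS[:-1]}"
        )
    order = sorted(range(n), key=lambda i: (-score[i], i))
    return order


def select_privileged(
    net: WeightedNetwork,
    dg: DistanceGraph,
    ranking: str,
    fraction: float,
    rng_seed: int | None = None,
) -> PrivilegedSet:
    """Top ``round(fraction · N)`` nodes of a centrality ranking."""
    if not 0.0 <= fraction <= 1.0:
        raise PrivilegedError(f"fraction must lie in [0, 1], got {fraction}")
    n = net.n_nodes
    k = int(round(fraction * n))
    if ranking == "random":
        if rng_seed is None:
            raise PrivilegedError("random ranking requires rng_seed")
        order = list(np.random.default_rng(rng_seed).permutation(n))
    else:
        order = rank_nodes(net, dg, ranking)
    return PrivilegedSet(
        members=frozenset(int(i) for i in order[:k]),
        ranking=ranking,
        fraction=fraction,
        rng_seed=rng_seed,
    )


def hybrid_strategy(
    net: WeightedNetwork,
    dg: DistanceGraph,
    privileged: PrivilegedSet,
    lam: float,
    target: int,
) -> RoutingStrategy:
    """Biased rows for privileged nodes, reference rows elsewhere."""
    biased = make_strategy(net, dg, lam, target)
    ref = reference_strategy(net, target)
    trans = ref.trans.copy()
    for i in privileged.members:
        trans[i] = biased.trans[i]
    trans[target] = biased.trans[target]  # absorbing row
    return RoutingStrategy(
        lam=biased.lam,
        target=target,
        trans=trans,
        support=biased.support,
        edge_dist=biased.edge_dist,
    )


@dataclass
class StretchResult:
    """Per-node expected-walk-length excess over the geodesic.

    ``per_node_stretch[i]`` averages ``|C^trans_hybrid(i,t) − g_it|`` over
    targets (divisor N, self term 0).  The all-privileged set gives zeros.
    """

    per_node_stretch: np.ndarray
    median: float
    q1: float
    q3: float


def node_stretch(
    net: WeightedNetwork,
    dg: DistanceGraph,
    privileged: PrivilegedSet,
    lam: float = INF,
) -> StretchResult:
    if dg.geodesic is None:
        raise PrivilegedError("geodesics not computed")
    n = net.n_nodes
    diff = np.zeros((n, n))  # |C_hybrid(i,t) - g_it|
    for t in range(n):
        strat = hybrid_strategy(net, dg, privileged, lam, t)
        chain = fundamental_matrix(strat)
        c = pairwise_transmission_cost(chain, strat, dg)
        diff[:, t] = np.abs(c - dg.geodesic[:, t])
    stretch = diff.sum(axis=1) / n
    q1, med, q3 = np.percentile(stretch, [25, 50, 75])
    return StretchResult(
        per_node_stretch=stretch, median=float(med), q1=float(q1), q3=float(q3)
    )


def privileged_cost_curves(
    net: WeightedNetwork,
    dg: DistanceGraph,
    privileged: PrivilegedSet,
    lam_grid,
) -> CostProfile:
    """Cost curves under the hybrid model.

    Non-privileged rows equal the reference, so their node-level
    informational cost is exactly 0 by construction.
    """
    factory = lambda lam, t: hybrid_strategy(net, dg, privileged, lam, t)
    return cost_curves(net, dg, lam_grid, strategy_factory=factory)
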