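"""Degree-, strength-, and weight-distribution-preserving network nulls.

A null member is built in three steps: (1) Maslov–Sneppen double-edge swaps
on the binarized network, rejecting swaps that disconnect it, so the exact
binary degree sequence survives; (2) the empirical weight multiset is
shuffled onto the rewired edges; (3) simulated annealing permutes weight
assignments to minimize the strength mismatch ``C = Σ_i |s_i − r_i|``
against the empirical strength sequence, with Metropolis acceptance
``exp(−ΔC/T)`` and a geometric temperature schedule.  Empirical cost curves
are then normalized against the ensemble (``‖C‖`` ratios) and nodal costs
are z-scored against the ensemble's nodal distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import norm as _normal

from .cost_measures import CostProfile
from .graph_core import WeightedNetwork

logger = logging.getLogger("routewalk")


@dataclass
class AnnealConfig:
    """Annealing schedule for strength matching.

    Defaults follow the reference schedule: 123 temperature stages starting
    at ``t0 = 100`` and cooled geometrically by 0.125 per stage (effectively
    greedy after the first ~10 stages).  ``proposals_per_stage`` defaults to
    ``ceil(E·ln E)`` weight-swap proposals, E the edge count.
    """

    iterations: int = 123
    t0: float = 100.0
    cooling: float = 0.125
    proposals_per_stage: int | None = None


@dataclass
class NullConfig:
    n_swap_per_edge: int = 10
    anneal: AnnealConfig = field(default_factory=AnnealConfig)


@dataclass
class NullEnsemble:
    networks: list[WeightedNetwork]
    seed: int
    swap_count: list[int]
    anneal_config: AnnealConfig
    final_energies: list[float]


def _is_connected_adj(adj: np.ndarray) -> bool:
    return connected_components(csr_matrix(adj), directed=False)[0] == 1


def rewire_binary(
    net: WeightedNetwork, n_swap_per_edge: int, rng_seed: int
) -> tuple[np.ndarray, int]:
    """Maslov–Sneppen rewiring of the binarized network.

    Repeatedly swaps edge pairs {a,b},{c,d} → {a,d},{c,b}, rejecting any swap
    that would create a self-loop or multi-edge or disconnect the graph, so
    the binary degree sequence is preserved exactly and the output stays
    connected.  Returns (boolean adjacency, achieved swap count); if the
    quota ``n_swap_per_edge · E`` is unreachable within the retry bound a
    partial-randomization warning is logged.
    """
    rng = np.random.default_rng(rng_seed)
    adj = (net.norm_weights != 0).copy()
    edges = [tuple(e) for e in np.argwhere(np.triu(adj, k=1))]
    n_edges = len(edges)
    target = n_swap_per_edge * n_edges
    max_attempts = 100 * max(target, 1)
    swaps = 0
    attempts = 0
    while swaps < target and attempts < max_attempts:
        attempts += 1
        ia, ib = rng.integers(0, n_edges, size=2)
        if ia == ib:
            continue
        a, b = edges[ia]
        c, d = edges[ib]
        if rng.random() < 0.5:
            c, d = d, c
        # propose {a,b},{c,d} -> {a,d},{c,b}
        if len({a, b, c, d}) < 4:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        if not _is_connected_adj(adj):
            adj[a, d] = adj[d, a] = False
            adj[c, b] = adj[b, c] = False
            adj[a, b] = adj[b, a] = True
            adj[c, d] = adj[d, c] = True
            continue
        edges[ia] = (a, d)
        edges[ib] = (c, b)
        swaps += 1
    if swaps < target:
        logger.warning(
            "partial randomization: achieved %d of %d swaps", swaps, target
        )
    return adj, swaps


def anneal_weights(
    adj: np.ndarray,
    weight_multiset: np.ndarray,
    target_strengths: np.ndarray,
    config: AnnealConfig,
    rng_seed: int,
) -> tuple[WeightedNetwork, float]:
    """Assign a permutation of the weight multiset minimizing strength error.

    Energy ``C = Σ_i |s_i − r_i|`` where ``s`` is the target strength
    sequence and ``r`` the current one.  At stage k the temperature is
    ``t0 · cooling^k``; each stage proposes pair swaps of edge weights with
    Metropolis acceptance.
    """
    rng = np.random.default_rng(rng_seed)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    n_edges = iu.size
    weights = np.sort(np.asarray(weight_multiset, dtype=float))
    if weights.size != n_edges:
        raise ValueError(
            f"weight multiset size {weights.size} != edge count {n_edges}"
        )
    assign = rng.permutation(weights)
    n = adj.shape[0]
    r = np.zeros(n)
    np.add.at(r, iu, assign)
    np.add.at(r, ju, assign)
    s = np.asarray(target_strengths, dtype=float)
    resid = np.abs(s - r)
    energy = float(resid.sum())

    n_prop = config.proposals_per_stage
    if n_prop is None:
        n_prop = max(int(math.ceil(n_edges * math.log(max(n_edges, 2)))), 1)

    for stage in range(config.iterations):
        if n_edges < 2 or energy == 0.0:
            break
        temp = config.t0 * config.cooling**stage
        ea = rng.integers(0, n_edges, size=n_prop)
        eb = rng.integers(0, n_edges, size=n_prop)
        accept_u = rng.random(n_prop)
        for k in range(n_prop):
            a, b = int(ea[k]), int(eb[k])
            if a == b:
                continue
            wa, wb = assign[a], assign[b]
            if wa == wb:
                continue
            delta = wb - wa
            # net strength change per affected node (edges may share a node)
            change: dict[int, float] = {}
            for u in (iu[a], ju[a]):
                change[u] = change.get(u, 0.0) + delta
            for u in (iu[b], ju[b]):
                change[u] = change.get(u, 0.0) - delta
            dE = sum(
                abs(s[u] - (r[u] + dv)) - abs(s[u] - r[u])
                for u, dv in change.items()
            )
            if dE <= 0 or (temp > 0 and accept_u[k] < math.exp(-dE / temp)):
                assign[a], assign[b] = wb, wa
                r[iu[a]] += delta
                r[ju[a]] += delta
                r[iu[b]] -= delta
                r[ju[b]] -= delta
                energy += dE
    # guard against float drift in the incremental energy
    r = np.zeros(n)
    np.add.at(r, iu, assign)
    np.add.at(r, ju, assign)
    energy = float(np.abs(s - r).sum())

    mat = np.zeros((n, n))
    mat[iu, ju] = assign
    mat[ju, iu] = assign
    out = WeightedNetwork.from_normalized(mat)
    return out, energy


def randomize_network(
    net: WeightedNetwork, config: NullConfig | None = None, rng_seed: int = 0
) -> tuple[WeightedNetwork, float, int]:
    """One null member: rewire, shuffle weights onto edges, anneal strengths.

    Returns (network, final annealing energy, achieved swap count).  The
    output preserves the binary degree sequence and the exact nonzero-weight
    multiset of ``net``; strengths are matched approximately.
    """
    if config is None:
        config = NullConfig()
    adj, swaps = rewire_binary(net, config.n_swap_per_edge, rng_seed)
    w = net.norm_weights
    multiset = w[np.triu(w, k=1) != 0]
    null, energy = anneal_weights(
        adj, multiset, net.strengths, config.anneal, rng_seed + 1
    )
    return null, energy, swaps


def build_ensemble(
    net: WeightedNetwork, size: int, seed: int, config: NullConfig | None = None
) -> NullEnsemble:
    """Generate ``size`` independent null members from one master seed."""
    if config is None:
        config = NullConfig()
    networks, energies, swapcounts = [], [], []
    for k in range(size):
        member, energy, swaps = randomize_network(
            net, config, rng_seed=seed + 7919 * (k + 1)
        )
        networks.append(member)
        energies.append(energy)
        swapcounts.append(swaps)
    return NullEnsemble(
        networks=networks,
        seed=seed,
        swap_count=swapcounts,
        anneal_config=config.anneal,
        final_energies=energies,
    )


# ---------------------------------------------------------------------------
# Normalization against the ensemble
# ---------------------------------------------------------------------------

@dataclass
class NormalizedCosts:
    """Empirical costs relative to a null ensemble.

    ``norm_trans``/``norm_info`` are the per-λ ratios ‖C‖ of the empirical
    grand mean to the ensemble-average grand mean; values < 1 flag regimes
    where the empirical network out-performs its randomized counterparts.
    ``z_*`` arrays (L, N) standardize nodal costs against the ensemble's
    nodal distributions; ``sig_*`` are two-sided threshold masks at ``alpha``.
    Nodes with zero ensemble SD have undefined z (NaN, masked False).
    """

    lam_grid: np.ndarray
    norm_trans: np.ndarray
    norm_info: np.ndarray
    z_src_trans: np.ndarray
    z_tgt_trans: np.ndarray
    z_src_info: np.ndarray
    z_tgt_info: np.ndarray
    sig_src_trans: np.ndarray
    sig_tgt_trans: np.ndarray
    sig_src_info: np.ndarray
    sig_tgt_info: np.ndarray
    alpha: float


def _zscore(emp: np.ndarray, members: np.ndarray) -> np.ndarray:
    mean = members.mean(axis=0)
    sd = members.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (emp - mean) / sd
    bad = ~np.isfinite(z)
    if bad.any():
        logger.warning("z undefined (zero ensemble SD) at %d entries", bad.sum())
        z[bad] = np.nan
    return z


def ensemble_costs(
    empirical: CostProfile, ensemble: list[CostProfile], alpha: float = 0.01
) -> NormalizedCosts:
    """Normalize an empirical cost profile against ensemble profiles.

    All profiles must share the λ grid.  The informational ratio is NaN
    wherever the ensemble mean is 0 (the λ = 0 point, where every strategy
    equals its own reference).
    """
    if not ensemble:
        raise ValueError("ensemble must contain at least one profile")
    grid = empirical.lam_grid
    for p in ensemble:
        if p.lam_grid.shape != grid.shape or not np.allclose(
            p.lam_grid, grid, equal_nan=True
        ):
            raise ValueError("ensemble profiles must share the empirical λ grid")

    ens_trans = np.array([p.mean_trans for p in ensemble])
    ens_info = np.array([p.mean_info for p in ensemble])
    with np.errstate(divide="ignore", invalid="ignore"):
        norm_trans = empirical.mean_trans / ens_trans.mean(axis=0)
        norm_info = empirical.mean_info / ens_info.mean(axis=0)

    z = {}
    for name in ("src_trans", "tgt_trans", "src_info", "tgt_info"):
        members = np.array([getattr(p, name) for p in ensemble])
        z[name] = _zscore(getattr(empirical, name), members)
    zcrit = float(_normal.ppf(1 - alpha / 2))
    sig = {k: np.abs(v) > zcrit for k, v in z.items()}
    for k in sig:
        sig[k][~np.isfinite(z[k])] = False
    return NormalizedCosts(
        lam_grid=grid,
        norm_trans=norm_trans,
        norm_info=norm_info,
        z_src_trans=z["src_trans"],
        z_tgt_trans=z["tgt_trans"],
        z_src_info=z["src_info"],
        z_tgt_info=z["tgt_info"],
        sig_src_trans=sig["src_trans"],
        sig_tgt_trans=sig["tgt_trans"],
        sig_src_info=sig["src_info"],
        sig_tgt_info=sig["tgt_info"],
        alpha=alpha,
    )
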