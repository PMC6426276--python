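"""Deterministic test networks: canonical toys and synthetic connectomes.

Canonical graphs are constructed directly on the normalized-weight scale so
their edge distances are exact (e.g. ``path_3_unit`` has both weights at
``e^{-1}``, hence unit distances).  The synthetic connectome generator
emulates the statistical signature of structural brain networks: sparse,
community-structured, with a few high-strength hubs and edge distances
``−ln w̄`` that are approximately log-normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph_core import DisconnectedNetworkError, NetworkError, WeightedNetwork

_E1 = math.exp(-1.0)


def canonical_graph(name: str, n: int | None = None, weight: float = _E1) -> WeightedNetwork:
    """Small exactly specified networks.

    ``path_n`` / ``ring_n`` / ``star_n`` take the node count ``n`` (or parse
    it from a suffixed name such as ``"path_3"``); every edge carries
    ``weight`` (default ``e^{-1}``, i.e. unit distance).  ``path_3_unit`` is
    an alias for the 3-node unit-distance path.  ``toy_fig1`` is a small
    weighted graph with hubs and a community, handy for illustrating how the
    bias reshapes transition rows.
    """
    if name == "path_3_unit":
        return canonical_graph("path", 3)
    if name == "toy_fig1":
        return _toy_graph()
    base, _, suffix = name.partition("_")
    if suffix and n is None:
        try:
            n = int(suffix)
        except ValueError:
            raise NetworkError(f"unknown canonical graph {name!r}") from None
    if base not in ("path", "ring", "star"):
        raise NetworkError(f"unknown canonical graph {name!r}")
    if n is None or n < 2:
        raise NetworkError("canonical graphs need n >= 2")
    if not 0.0 < weight < 1.0:
        raise NetworkError("edge weight must lie in (0, 1)")
    mat = np.zeros((n, n))
    if base == "path":
        for i in range(n - 1):
            mat[i, i + 1] = mat[i + 1, i] = weight
    elif base == "ring":
        if n < 3:
            raise NetworkError("rings need n >= 3")
        for i in range(n):
            j = (i + 1) % n
            mat[i, j] = mat[j, i] = weight
    else:  # star with node 0 at the center
        mat[0, 1:] = weight
        mat[1:, 0] = weight
    return WeightedNetwork.from_normalized(mat)


def _toy_graph() -> WeightedNetwork:
    # 8 nodes: a well-connected core (0-3) and a peripheral chain (4-7),
    # with heterogeneous weights so shortest paths are non-trivial.
    edges = [
        (0, 1, 0.80), (0, 2, 0.60), (1, 2, 0.70), (1, 3, 0.50),
        (2, 3, 0.65), (3, 4, 0.40), (4, 5, 0.55), (5, 6, 0.35),
        (6, 7, 0.45), (3, 6, 0.20), (0, 4, 0.25),
    ]
    mat = np.zeros((8, 8))
    for i, j, w in edges:
        mat[i, j] = mat[j, i] = w
    return WeightedNetwork.from_normalized(mat)


@dataclass
class SynthConfig:
    """Parameters of the synthetic connectome generator.

    Weights are drawn as ``w̄ = exp(−X)`` with X log-normal
    ``(weight_logmean, weight_logsd)``, so edge distances are log-normal by
    construction.  ``hub_boost`` multiplies the connection probability of
    hub-incident pairs and additionally shortens hub-incident distances by
    ``√hub_boost`` (hubs carry both more and stronger connections, the
    rich-club signature), so hub strengths dominate robustly.
    """

    n_nodes: int = 64
    n_modules: int = 4
    intra_density: float = 0.35
    inter_density: float = 0.05
    weight_logmean: float = 0.0
    weight_logsd: float = 0.5
    hub_count: int = 4
    hub_boost: float = 3.0
    seed: int = 0


def synth_connectome(cfg: SynthConfig) -> WeightedNetwork:
    """Sample a connected modular hub network, fully determined by the seed.

    Module membership is balanced round-robin; hubs are spread evenly across
    modules (nodes 0, 1, …, hub_count−1 land in distinct modules under the
    round-robin assignment).  Disconnected draws are retried with an
    incremented sub-seed, up to 20 attempts.
    """
    _validate_config(cfg)
    for attempt in range(20):
        rng = np.random.default_rng((cfg.seed + 1_000_003 * attempt) % 2**31)
        mat = _sample_once(cfg, rng)
        if not mat.any():  # an empty draw counts as a failed (disconnected) draw
            continue
        try:
            return WeightedNetwork.from_normalized(mat)
        except DisconnectedNetworkError:
            continue
    raise DisconnectedNetworkError(
        "could not sample a connected network in 20 attempts; "
        "increase the densities"
    )


def _validate_config(cfg: SynthConfig) -> None:
    if cfg.n_nodes < 2 or cfg.n_modules < 1 or cfg.hub_count < 0:
        raise NetworkError("invalid synthetic-network size parameters")
    for dens in (cfg.intra_density, cfg.inter_density):
        if not 0.0 < dens <= 1.0:
            raise NetworkError("densities must lie in (0, 1]")
    if cfg.hub_boost < 1.0:
        raise NetworkError("hub_boost must be >= 1")
    if cfg.weight_logsd <= 0:
        raise NetworkError("weight_logsd must be positive")


def _sample_once(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_nodes
    module = np.arange(n) % cfg.n_modules  # balanced round-robin
    hubs = np.zeros(n, dtype=bool)
    hubs[: cfg.hub_count] = True  # first hub_count nodes sit in distinct modules
    prob = np.where(
        module[:, None] == module[None, :], cfg.intra_density, cfg.inter_density
    ).astype(float)
    boost = np.where(hubs[:, None] | hubs[None, :], cfg.hub_boost, 1.0)
    prob = np.minimum(prob * boost, 0.95)
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < prob[iu, ju]
    # distances X ~ lognormal; cap to keep w = exp(-X) strictly inside (0, 1)
    x = rng.lognormal(cfg.weight_logmean, cfg.weight_logsd, size=iu.size)
    hub_pair = hubs[iu] | hubs[ju]
    x[hub_pair] /= math.sqrt(cfg.hub_boost)
    x = np.clip(x, 1e-9, 36.0)
    w = np.exp(-x)
    mat = np.zeros((n, n))
    mat[iu[present], ju[present]] = w[present]
    mat[ju[present], iu[present]] = w[present]
    return mat
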