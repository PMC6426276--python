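"""Network representation, weight normalization, distances, and file I/O.

Edge weights are *proximities*: larger means more strongly connected, as in
streamline-count or fiber-density connectomes.  All dynamics in this package
run on normalized proximities ``w̄`` in the open unit interval, obtained from
the raw weights by the unique affine map sending the smallest nonzero weight
to ``ϵ`` and the largest to ``1 − ϵ``.  Proximities become additive edge
distances through ``d = −ln(w̄)``, so that at zero bias a walker's transition
probabilities are exactly ``w̄ / strength`` (the unbiased random walk).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

logger = logging.getLogger("routewalk")

#: relative tolerance under which a near-symmetric input adjacency is
#: symmetrized by averaging; beyond it the input is rejected.
SYMMETRY_RTOL = 1e-8

#: relative tolerance for membership of a neighbor in the shortest-path
#: predecessor set: |d_ij + g_jt - g_it| <= DEGENERACY_RTOL * max(1, g_it).
DEGENERACY_RTOL = 1e-9


class NetworkError(ValueError):
    """Base class for invalid network inputs."""


class DegenerateWeightRangeError(NetworkError):
    """All nonzero weights are equal; the affine normalization is undefined."""


class InvalidOffsetError(NetworkError):
    """Normalization offset ϵ outside (0, 0.5)."""


class DisconnectedNetworkError(NetworkError):
    """The network is not a single connected component."""


class FormatError(NetworkError):
    """A network file violates the expected on-disk format."""


def _check_square_symmetric(mat: np.ndarray, name: str = "weights") -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise NetworkError(f"{name} must be a square matrix, got shape {mat.shape}")
    scale = max(np.abs(mat).max(), 1.0)
    if not np.allclose(mat, mat.T, rtol=0.0, atol=SYMMETRY_RTOL * scale):
        i, j = np.unravel_index(np.abs(mat - mat.T).argmax(), mat.shape)
        raise FormatError(
            f"{name} asymmetric beyond tolerance at entry ({i},{j}): "
            f"{mat[i, j]!r} vs {mat[j, i]!r}"
        )
    if not np.array_equal(mat, mat.T):
        logger.warning("near-symmetric %s symmetrized by averaging", name)
        mat = 0.5 * (mat + mat.T)
    if np.any(mat < 0):
        raise NetworkError(f"{name} must be nonnegative")
    return mat


def _require_connected(adj: np.ndarray) -> None:
    n_comp, labels = connected_components(csr_matrix(adj != 0), directed=False)
    if n_comp > 1:
        a = int(np.flatnonzero(labels == 0)[0])
        b = int(np.flatnonzero(labels != labels[a])[0])
        raise DisconnectedNetworkError(
            f"network is disconnected: no path between nodes {a} and {b}"
        )


def normalize_weights(raw: np.ndarray, epsilon: float | str = "auto") -> np.ndarray:
    """Map raw nonzero weights affinely onto (0, 1).

    The map is the unique affine function sending ``MIN(w) → ϵ`` and
    ``MAX(w) → 1 − ϵ``:

        w̄ = ((1 − 2ϵ)·w + (2ϵ − 1)·MIN) / (MAX − MIN) + ϵ

    Zeros (absent edges) stay zero and the rank order of edges is preserved.

    Parameters
    ----------
    raw
        Square symmetric nonnegative matrix with zero diagonal.
    epsilon
        Offset in (0, 0.5); ``"auto"`` uses ``MIN(w)`` over the nonzero
        weights (clipped below 0.5).
    """
    raw = _check_square_symmetric(raw, "raw weights")
    if np.any(np.diag(raw) != 0):
        raise NetworkError("raw weights must have a zero diagonal")
    mask = raw != 0
    if not mask.any():
        raise NetworkError("network has no edges")
    wmin = raw[mask].min()
    wmax = raw[mask].max()
    if wmax == wmin:
        raise DegenerateWeightRangeError(
            "all nonzero weights are equal; affine normalization undefined"
        )
    if epsilon == "auto":
        eps = float(min(wmin, 0.5 - 1e-12))
    else:
        eps = float(epsilon)
    if not 0.0 < eps < 0.5:
        raise InvalidOffsetError(f"epsilon must lie in (0, 0.5), got {eps}")
    out = np.zeros_like(raw)
    out[mask] = ((1 - 2 * eps) * raw[mask] + (2 * eps - 1) * wmin) / (wmax - wmin) + eps
    return out


@dataclass
class WeightedNetwork:
    """A connected, undirected network of proximity weights.

    Attributes
    ----------
    weights
        Raw symmetric proximity matrix (0 = no edge).
    norm_weights
        Affinely normalized proximities, nonzero entries strictly in (0, 1).
    strengths
        Node strengths ``s_i = Σ_j w̄_ij`` of the normalized weights.
    epsilon
        The normalization offset actually applied.
    """

    weights: np.ndarray
    norm_weights: np.ndarray
    strengths: np.ndarray
    epsilon: float
    node_labels: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def edges(self) -> np.ndarray:
        """Upper-triangular (i, j) index pairs of the edge support."""
        iu, ju = np.nonzero(np.triu(self.norm_weights, k=1))
        return np.column_stack([iu, ju])

    @classmethod
    def from_weights(
        cls,
        raw: np.ndarray,
        epsilon: float | str = "auto",
        node_labels=None,
    ) -> "WeightedNetwork":
        """Validate raw proximities and normalize them onto (0, 1)."""
        raw = _check_square_symmetric(raw, "raw weights")
        if np.any(np.diag(raw) != 0):
            logger.warning("self-loops stripped from input weights")
            raw = raw.copy()
            np.fill_diagonal(raw, 0.0)
        _require_connected(raw)
        norm = normalize_weights(raw, epsilon)
        eps = float(norm[norm != 0].min())
        return cls(
            weights=raw,
            norm_weights=norm,
            strengths=norm.sum(axis=1),
            epsilon=eps,
            node_labels=_make_labels(raw.shape[0], node_labels),
        )

    @classmethod
    def from_normalized(
        cls,
        norm: np.ndarray,
        epsilon: float | None = None,
        node_labels=None,
    ) -> "WeightedNetwork":
        """Wrap weights that already lie in (0, 1), skipping the affine map.

        Used for canonical toy graphs and null-model members whose weights
        are constructed directly on the normalized scale.
        """
        norm = _check_square_symmetric(norm, "normalized weights")
        if np.any(np.diag(norm) != 0):
            raise NetworkError("normalized weights must have a zero diagonal")
        mask = norm != 0
        if not mask.any():
            raise NetworkError("network has no edges")
        if norm[mask].min() <= 0.0 or norm[mask].max() >= 1.0:
            raise NetworkError("normalized weights must lie strictly in (0, 1)")
        _require_connected(norm)
        eps = float(norm[mask].min()) if epsilon is None else float(epsilon)
        return cls(
            weights=norm.copy(),
            norm_weights=norm,
            strengths=norm.sum(axis=1),
            epsilon=eps,
            node_labels=_make_labels(norm.shape[0], node_labels),
        )


def _make_labels(n: int, labels) -> tuple[str, ...]:
    if labels is None:
        return tuple(str(i) for i in range(n))
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise NetworkError(f"expected {n} node labels, got {len(labels)}")
    return labels


@dataclass
class DistanceGraph:
    """Edge distances and all-pairs geodesics of a network.

    ``edge_dist[i, j] = −ln(w̄_ij)`` on edges, ``inf`` on non-edges (an
    explicit unreachable sentinel, never a large finite number).  ``geodesic``
    is filled by :func:`geodesic_distances` and is ``None`` before that.
    """

    edge_dist: np.ndarray
    geodesic: np.ndarray | None = None
    _pred_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.edge_dist.shape[0]

    def predecessors(self, target: int) -> dict[int, list[int]]:
        """Neighbors of each node lying on some shortest path to ``target``.

        Membership uses the degenerate-path tolerance
        ``|d_ij + g_jt − g_it| ≤ DEGENERACY_RTOL · max(1, g_it)``.
        """
        if self.geodesic is None:
            raise NetworkError("geodesics not computed; call geodesic_distances first")
        if target in self._pred_cache:
            return self._pred_cache[target]
        d = self.edge_dist
        g = self.geodesic[:, target]
        preds: dict[int, list[int]] = {}
        for i in range(self.n_nodes):
            if i == target:
                preds[i] = []
                continue
            nbrs = np.flatnonzero(np.isfinite(d[i]))
            tol = DEGENERACY_RTOL * max(1.0, g[i])
            on_sp = [int(j) for j in nbrs if abs(d[i, j] + g[j] - g[i]) <= tol]
            preds[i] = on_sp
        self._pred_cache[target] = preds
        return preds


def weights_to_distances(net: WeightedNetwork) -> DistanceGraph:
    """Apply the proximity-to-distance map ``d_ij = −ln(w̄_ij)``."""
    w = net.norm_weights
    mask = w != 0
    if mask.any() and (w[mask].min() <= 0.0 or w[mask].max() >= 1.0):
        raise NetworkError("normalized weights must lie strictly in (0, 1)")
    dist = np.full_like(w, np.inf)
    dist[mask] = -np.log(w[mask])
    np.fill_diagonal(dist, np.inf)  # no self-loops
    return DistanceGraph(edge_dist=dist)


def geodesic_distances(dg: DistanceGraph) -> DistanceGraph:
    """Fill all-pairs shortest-path distances via Dijkstra.

    Raises :class:`DisconnectedNetworkError` naming an unreachable pair if the
    network is not connected.
    """
    d = dg.edge_dist
    finite = np.isfinite(d)
    graph = csr_matrix(np.where(finite, d, 0.0))
    g = dijkstra(graph, directed=False)
    np.fill_diagonal(g, 0.0)
    if not np.all(np.isfinite(g)):
        i, j = np.argwhere(~np.isfinite(g))[0]
        raise DisconnectedNetworkError(
            f"no path between nodes {int(i)} and {int(j)}"
        )
    dg.geodesic = g
    dg._pred_cache.clear()
    return dg


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_network(path, format: str = "adjacency_csv", epsilon="auto") -> WeightedNetwork:
    """Read a weighted undirected network from disk.

    ``adjacency_csv``: dense square CSV; a header row plus an index column of
    node labels is optional (auto-detected).  ``edgelist_tsv``: tab-separated
    ``label_a  label_b  weight``, one undirected edge per line.
    """
    if format == "adjacency_csv":
        head = pd.read_csv(path, header=None, nrows=1)
        first = head.iloc[0, 0]
        # a labelled adjacency has an empty corner cell or non-numeric labels
        labelled = (isinstance(first, float) and math.isnan(first)) or any(
            isinstance(v, str) and not _is_number(v) for v in head.iloc[0, :]
        )
        if labelled:
            df = pd.read_csv(path, index_col=0)
            labels = [str(x) for x in df.index]
            mat = df.to_numpy(dtype=float)
        else:
            mat = pd.read_csv(path, header=None).to_numpy(dtype=float)
            labels = None
        return WeightedNetwork.from_weights(mat, epsilon=epsilon, node_labels=labels)
    if format == "edgelist_tsv":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] != 3:
            raise FormatError(
                f"edge list must have 3 columns, got {df.shape[1]}"
            )
        labels = sorted(set(df[0].astype(str)) | set(df[1].astype(str)))
        index = {lab: k for k, lab in enumerate(labels)}
        n = len(labels)
        mat = np.zeros((n, n))
        for a, b, w in df.itertuples(index=False):
            w = float(w)
            if w < 0:
                raise NetworkError(f"negative weight on edge ({a}, {b})")
            i, j = index[str(a)], index[str(b)]
            if i == j:
                logger.warning("self-loop on node %s stripped", a)
                continue
            mat[i, j] = w
            mat[j, i] = w
        return WeightedNetwork.from_weights(mat, epsilon=epsilon, node_labels=labels)
    raise FormatError(f"unknown format {format!r}")


def write_network(net: WeightedNetwork, path, format: str = "adjacency_csv") -> None:
    """Write the raw weight matrix; a write→read round trip reproduces it."""
    if format == "adjacency_csv":
        df = pd.DataFrame(net.weights, index=net.node_labels, columns=net.node_labels)
        df.to_csv(path, float_format="%.12g")
    elif format == "edgelist_tsv":
        with open(path, "w") as fh:
            iu, ju = np.nonzero(np.triu(net.weights, k=1))
            for i, j in zip(iu, ju):
                fh.write(
                    f"{net.node_labels[i]}\t{net.node_labels[j]}\t"
                    f"{net.weights[i, j]:.12g}\n"
                )
    else:
        raise FormatError(f"unknown format {format!r}")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
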