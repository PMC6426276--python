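"""routewalk: biased random-walk routing strategies for weighted networks.

A toolkit for the diffusion ↔ shortest-path communication spectrum: λ-biased
target-conditioned random walks, their transmission and informational costs,
strength-preserving null-model normalization, and privileged-node routing.
"""

from .graph_core import (
    DegenerateWeightRangeError,
    DisconnectedNetworkError,
    DistanceGraph,
    FormatError,
    InvalidOffsetError,
    NetworkError,
    WeightedNetwork,
    geodesic_distances,
    normalize_weights,
    read_network,
    weights_to_distances,
    write_network,
)
from .routing_model import (
    INF,
    AbsorbingChain,
    AbsorptionError,
    RoutingModelError,
    RoutingStrategy,
    build_strategy,
    fundamental_matrix,
    make_strategy,
    reference_strategy,
    shortest_path_limit_strategy,
    simulate_walk,
    simulate_walks,
    write_strategy,
)
from .cost_measures import (
    CostProfile,
    TradeoffSummary,
    cost_curves,
    default_lambda_grid,
    immediate_transmission_cost,
    nodal_averages,
    node_informational_cost,
    pairwise_informational_cost,
    pairwise_transmission_cost,
    profile_to_frame,
    summary_to_json,
    tradeoff_summary,
)
from .null_models import (
    AnnealConfig,
    NormalizedCosts,
    NullConfig,
    NullEnsemble,
    anneal_weights,
    build_ensemble,
    ensemble_costs,
    randomize_network,
    rewire_binary,
)
from .privileged_routing import (
    PrivilegedSet,
    StretchResult,
    hybrid_strategy,
    node_stretch,
    privileged_cost_curves,
    rank_nodes,
    select_privileged,
)
from .fixtures import SynthConfig, canonical_graph, synth_connectome

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def prepare(net: WeightedNetwork) -> DistanceGraph:
    """Convenience: distances + geodesics in one call."""
    return geodesic_distances(weights_to_distances(net))
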