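import numpy as np
import pytest

import routewalk as rw


@pytest.fixture(scope="session")
def path3():
    """3-node unit-distance path A—B—C (both weights e^-1)."""
    net = rw.canonical_graph("path_3_unit")
    return net, rw.prepare(net)


@pytest.fixture(scope="session")
def path4():
    """4-node unit-distance path."""
    net = rw.canonical_graph("path", 4)
    return net, rw.prepare(net)


@pytest.fixture(scope="session")
def toy():
    """Small heterogeneous 8-node graph."""
    net = rw.canonical_graph("toy_fig1")
    return net, rw.prepare(net)


@pytest.fixture(scope="session")
def synth_small():
    """32-node synthetic connectome for curve-shape checks."""
    cfg = rw.SynthConfig(n_nodes=32, n_modules=4, hub_count=3, seed=11)
    net = rw.synth_connectome(cfg)
    return net, rw.prepare(net)


@pytest.fixture(scope="session")
def synth_64():
    """Default-scale 64-node synthetic connectome."""
    net = rw.synth_connectome(rw.SynthConfig(seed=7))
    return net, rw.prepare(net)


def random_connected_net(n, density, rng):
    """Random connected network with weights in (0,1); retries until connected."""
    for _ in range(200):
        mat = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < density
        w = rng.uniform(0.05, 0.95, size=iu.size)
        mat[iu[mask], ju[mask]] = w[mask]
        mat[ju[mask], iu[mask]] = w[mask]
        try:
            return rw.WeightedNetwork.from_normalized(mat)
        except rw.NetworkError:
            continue
    raise RuntimeError("failed to sample a connected network")
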