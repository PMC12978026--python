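import numpy as np
import pytest

from neuroprune import (ClusterSpec, DatasetBundle, NetworkState, TrainConfig,
                        generate_dataset, init_network, prune_magnitude, train)
from neuroprune._streams import substream

TOY_LAYERS = (2, 16, 16, 8, 4)


@pytest.fixture(scope="session")
def toy_data() -> DatasetBundle:
    """Small canonical-geometry dataset: 2,000 train / 400 / 400 points."""
    return generate_dataset(ClusterSpec(), n_train=2_000, n_test_standard=400,
                            n_test_clean=400, seed=7)


@pytest.fixture(scope="session")
def toy_trained(toy_data) -> NetworkState:
    """A small dense network trained to (near-)perfect clean accuracy."""
    net = init_network(TOY_LAYERS, seed=7)
    train(net, toy_data, TrainConfig(epochs=8), substream(7, "train"))
    return net


@pytest.fixture(scope="session")
def toy_pruned(toy_trained) -> NetworkState:
    state, _ = prune_magnitude(toy_trained, 0.95)
    return state


def make_state(weights, biases=None, masks=None, activation="rectifier",
               dtype=np.float64) -> NetworkState:
    """Hand-built NetworkState from nested lists (float64 by default for oracles)."""
    ws = [np.asarray(w, dtype=dtype) for w in weights]
    bs = ([np.asarray(b, dtype=dtype) for b in biases] if biases is not None
          else [np.zeros(w.shape[0], dtype=dtype) for w in ws])
    ms = ([np.asarray(m, dtype=dtype) for m in masks] if masks is not None
          else [np.ones_like(w) for w in ws])
    return NetworkState(ws, bs, ms, activation=activation)
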