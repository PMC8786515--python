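import numpy as np
import pytest

from graphdbp import (
    ModelConfig,
    SimulationSpec,
    TrainConfig,
    init_params,
    simulate_dataset,
)
from graphdbp.features import default_property_table
from graphdbp.graph_build import AdjacencyMatrix, ProteinGraph


@pytest.fixture(scope="session")
def property_table():
    return default_property_table()


@pytest.fixture(scope="session")
def tiny_dataset():
    """Twelve small labeled graphs with a strong planted PPM signal."""
    spec = SimulationSpec(n_positive=6, n_negative=6, length_range=(15, 25), seed=7)
    graphs, manifest = simulate_dataset(spec)
    return graphs, manifest


@pytest.fixture(scope="session")
def default_model():
    config = ModelConfig()
    return config, init_params(config, seed=123)


@pytest.fixture
def fast_train_config():
    return TrainConfig(epochs=10, batch_size=8, seed=3, validation_fraction=0.2)


def random_graph(rng, n_nodes, n_features=54, edge_p=0.3, label=None, gid="g"):
    """Random binary symmetric graph with random node features (test helper)."""
    upper = rng.random((n_nodes, n_nodes)) < edge_p
    a = np.triu(upper, k=1)
    a = (a | a.T).astype(np.int8)
    feats = rng.standard_normal((n_nodes, n_features))
    return ProteinGraph(id=gid, features=feats, adjacency=AdjacencyMatrix(values=a),
                        label=label)
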