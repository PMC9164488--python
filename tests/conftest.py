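import numpy as np
import pytest

from spatialink import data_io, spatial_graph, vgae_core


@pytest.fixture(scope="session")
def small_tissue():
    """A modest synthetic tissue shared across unit tests."""
    ds, truth = data_io.simulate_tissue(
        n_cells=150, n_types=3, n_genes=30, n_informative=10, seed=7
    )
    return ds, truth


@pytest.fixture(scope="session")
def small_trained(small_tissue):
    """A quick trained model on the small tissue (z-scored features,
    early stopping) for reconstruction/sensitivity tests."""
    ds, _ = small_tissue
    graph = spatial_graph.build_adjacency(ds.coordinates)
    split = spatial_graph.split_edges(graph, seed=7)
    cfg = vgae_core.ModelConfig(
        epochs=150, seed=7, feature_scaling="log1p_zscore", early_stopping=True
    )
    result = vgae_core.train(ds, split, cfg)
    return ds, graph, split, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
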