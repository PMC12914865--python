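import numpy as np
import pytest

import copulagcn as cg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """Small well-separated simulated dataset shared across unit tests."""
    template = cg.make_template(n_genes=300, n_groups=3, marker_fraction=0.05,
                                marker_fold=8.0, library_size=600, seed=11)
    return cg.simulate_dataset(template, n_cells=90)


@pytest.fixture(scope="session")
def small_features(small_sim):
    return cg.build_features(small_sim.dataset, n_hvg=60)


@pytest.fixture(scope="session")
def small_graph(small_features):
    d = cg.pairwise_distances(small_features.values)
    return cg.knn_graph(d, k=5)
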