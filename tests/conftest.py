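import numpy as np
import pytest

from fcembed.connectivity import WeightedGraph
from fcembed.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-group cohort with a strong planted module."""
    cfg = CohortConfig(n_per_group=12, n_rois=16, n_timepoints=80,
                       effect_size=0.5, module_size=5, base_correlation=0.45,
                       labels=("HC", "AD"), seed=7)
    subjects, labels = generate_cohort(cfg)
    return cfg, subjects, labels


@pytest.fixture()
def triangle_graph():
    """Unit-weight triangle on nodes {0, 1, 2}."""
    w = np.ones((3, 3)) - np.eye(3)
    return WeightedGraph(w, ["a", "b", "c"], "absolute")


@pytest.fixture()
def path_graph_2():
    """Two-node path a-b."""
    w = np.array([[0.0, 1.0], [1.0, 0.0]])
    return WeightedGraph(w, ["a", "b"], "absolute")


def random_weighted_graph(rng, n_nodes, edge_prob=0.6):
    """Random connected-ish non-negative weighted graph."""
    w = rng.random((n_nodes, n_nodes)) * (rng.random((n_nodes, n_nodes)) < edge_prob)
    w = np.triu(w, 1)
    w = w + w.T
    # ensure no isolated nodes by chaining
    for i in range(n_nodes - 1):
        if w[i].sum() == 0 or w[i + 1].sum() == 0:
            w[i, i + 1] = w[i + 1, i] = rng.random() + 0.1
    return WeightedGraph(w, [f"n{i}" for i in range(n_nodes)], "absolute")
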