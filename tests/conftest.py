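import networkx as nx
import numpy as np
import pytest

from netalign.network_io import (AnchorSet, AnnotationTable, SpeciesNetwork,
                                 build_joint_graph)
from netalign.synthetic import SyntheticSpec, generate


def net_from_edges(edges, label="sp"):
    g = nx.Graph()
    g.add_edges_from(edges)
    return SpeciesNetwork(label, g)


@pytest.fixture
def triangle():
    return net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path4():
    return net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def toy_joint_graph():
    """6-node joint graph with both anchor types, for model-level tests."""
    g1 = net_from_edges([("a", "b"), ("b", "c")], "species1")
    g2 = net_from_edges([("u", "v"), ("v", "w"), ("u", "w")], "species2")
    anchors = [AnchorSet("ortholog", {("a", "u")}),
               AnchorSet("seqsim", {("b", "v"), ("c", "w")})]
    return build_joint_graph(g1, g2, anchors)


@pytest.fixture(scope="session")
def default_inst():
    from netalign.synthetic import default_instance

    return default_instance()


@pytest.fixture(scope="session")
def small_instance():
    """Fast synthetic instance (n=60) for training-loop tests."""
    return generate(SyntheticSpec(n_nodes=60, n_terms=12,
                                  term_module_size=(3, 8), seed=7))


def toy_features(jg, pos_dim=1, window_T=2):
    from netalign.features import distance_features, laplacian_positional
    from netalign.gnn_model import GraphFeatures

    return GraphFeatures(jg,
                         distance_features(jg.g1, window_T=window_T),
                         distance_features(jg.g2, window_T=window_T),
                         laplacian_positional(jg.g1, pos_dim),
                         laplacian_positional(jg.g2, pos_dim))
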