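import math

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from geneconnectome import GeneNetwork, InteractionRecord, build_network

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# Toy graph G1: confidence scores A-B 0.9, B-C 0.5, A-C 0.25, C-D 0.8,
# node E isolated.  Under reciprocal inversion the shortest route A->C is
# A->B->C (1/0.9 + 1/0.5 = 3.1111), beating the direct edge (1/0.25 = 4).
G1_SCORES = [("A", "B", 0.9), ("B", "C", 0.5), ("A", "C", 0.25), ("C", "D", 0.8)]

D_AB = 1 / 0.9
D_AC = 1 / 0.9 + 1 / 0.5
D_AD = D_AC + 1 / 0.8


@pytest.fixture
def g1_records() -> list[InteractionRecord]:
    return [InteractionRecord(a, b, s) for a, b, s in G1_SCORES]


@pytest.fixture
def g1_net(g1_records) -> GeneNetwork:
    return build_network(g1_records, include_nodes=["E"])


def net_from_distances(nodes, edges) -> GeneNetwork:
    """Build a GeneNetwork directly from a {(a, b): distance} dict."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (a, b), d in edges.items():
        g.add_edge(a, b, distance=d)
    return GeneNetwork(graph=g)


def approx_inf_aware(a: float, b: float, tol: float = 1e-9) -> bool:
    if math.isinf(a) or math.isinf(b):
        return a == b
    return abs(a - b) <= tol
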