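"""Build the weighted gene network from scored interactions.

Confidence scores in (0, 1] are inverted into *direct biological distances*:
a strong interaction is a short edge, a weak one a long edge.  Two inversion
functions are provided:

``reciprocal`` (default)
    d = 1 / s.  Penalizes weak interactions super-linearly and keeps
    distances unbounded, matching the long-tail behavior of connectomes.

``complement``
    d = 1 - s + eps with eps = 1e-6, so perfect-confidence edges keep a
    positive length.  Provided for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx

from .errors import DataError
from .netio import InteractionRecord

#: Offset keeping complement-mode distances strictly positive at s = 1.
COMPLEMENT_EPS = 1e-6

INVERSION_MODES = ("reciprocal", "complement")


def invert_score(score: float, inversion: str = "reciprocal") -> float:
    """Map a confidence score in (0, 1] to a positive direct distance."""
    if inversion == "reciprocal":
        return 1.0 / score
    if inversion == "complement":
        return 1.0 - score + COMPLEMENT_EPS
    raise DataError(f"unknown inversion mode {inversion!r}; expected one of {INVERSION_MODES}")


@dataclass
class GeneNetwork:
    """Undirected weighted gene graph; edge attribute ``distance`` > 0."""

    graph: nx.Graph
    inversion: str = "reciprocal"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.graph

    def nodes(self) -> Iterator[str]:
        return iter(self.graph.nodes)

    def distance(self, a: str, b: str) -> float:
        """Direct (single-edge) distance between two adjacent genes."""
        return self.graph.edges[a.upper(), b.upper()]["distance"]


def build_network(
    records: Sequence[InteractionRecord],
    inversion: str = "reciprocal",
    include_nodes: Sequence[str] = (),
) -> GeneNetwork:
    """Build the weighted network; one edge per unordered gene pair.

    The node set is all genes appearing in at least one edge, plus any
    ``include_nodes`` (genes known to the study but without interactions;
    they become isolated nodes with infinite distance to everything).
    Raises :class:`DataError` on an empty record list (the network must be
    non-empty) or an unknown inversion mode.  If duplicate pairs slip
    through, the maximum score (minimum distance) wins.
    """
    if not records:
        raise DataError("cannot build a network from an empty interaction list")
    g = nx.Graph()
    for node in include_nodes:
        g.add_node(node.upper())
    for rec in records:
        d = invert_score(rec.score, inversion)
        prev = g.edges.get((rec.gene_a, rec.gene_b))
        if prev is None or d < prev["distance"]:
            g.add_edge(rec.gene_a, rec.gene_b, distance=d, score=rec.score)
    return GeneNetwork(graph=g, inversion=inversion)


def network_summary(net: GeneNetwork) -> dict[str, int]:
    """Exact node, edge and connected-component counts."""
    return {
        "nodes": net.n_nodes,
        "edges": net.n_edges,
        "components": nx.number_connected_components(net.graph),
    }


def write_edgelist(net: GeneNetwork, path: str | Path) -> None:
    """Dump the network as an edge-list TSV (gene_a, gene_b, distance)."""
    edges = sorted((min(a, b), max(a, b), d["distance"]) for a, b, d in net.graph.edges(data=True))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\tdistance\n")
        for a, b, d in edges:
            fh.write(f"{a}\t{b}\t{d:.10g}\n")
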