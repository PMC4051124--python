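"""Brute-force shortest-path oracles, independent of the package's engine.

Two routes to the same truth: exhaustive simple-path enumeration (exact for
tiny graphs) and repeated edge relaxation until a fixed point (Bellman-Ford
style, valid for any graph with positive weights).  Both operate on a plain
edge-weight dict and never touch networkx.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

Edges = dict[tuple[str, str], float]  # unordered pair (a, b) with a < b -> distance


def neighbors(edges: Edges) -> dict[str, dict[str, float]]:
    adj: dict[str, dict[str, float]] = {}
    for (a, b), d in edges.items():
        adj.setdefault(a, {})[b] = d
        adj.setdefault(b, {})[a] = d
    return adj


def enumerate_distance(edges: Edges, source: str, target: str) -> float:
    """Minimal total weight over ALL simple paths source -> target."""
    if source == target:
        return 0.0
    adj = neighbors(edges)
    best = math.inf

    def walk(node: str, total: float, seen: frozenset[str]) -> None:
        nonlocal best
        if total >= best:
            return
        for nxt, d in adj.get(node, {}).items():
            if nxt == target:
                best = min(best, total + d)
            elif nxt not in seen:
                walk(nxt, total + d, seen | {nxt})

    walk(source, 0.0, frozenset({source}))
    return best


def relax_all_pairs(nodes: list[str], edges: Edges) -> dict[tuple[str, str], float]:
    """All-pairs distances by repeated relaxation until a fixed point."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), math.inf)
    np.fill_diagonal(dist, 0.0)
    for (a, b), d in edges.items():
        i, j = idx[a], idx[b]
        dist[i, j] = dist[j, i] = min(dist[i, j], d)
    changed = True
    while changed:
        changed = False
        for (a, b), d in edges.items():
            i, j = idx[a], idx[b]
            via_j = dist[j, :] + d
            better = via_j < dist[i, :]
            if better.any():
                dist[i, better] = via_j[better]
                dist[better, i] = via_j[better]
                changed = True
            via_i = dist[i, :] + d
            better = via_i < dist[j, :]
            if better.any():
                dist[j, better] = via_i[better]
                dist[better, j] = via_i[better]
                changed = True
    return {(a, b): dist[idx[a], idx[b]] for a in nodes for b in nodes}


def random_edges(rng: np.random.Generator, n: int, p: float) -> tuple[list[str], Edges]:
    """Random weighted graph: ER(n, p) with distances uniform in [0.5, 4)."""
    nodes = [f"N{i:02d}" for i in range(n)]
    edges: Edges = {}
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            edges[(nodes[i], nodes[j])] = float(rng.uniform(0.5, 4.0))
    return nodes, edges
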