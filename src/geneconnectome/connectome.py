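"""Gene-specific connectomes: shortest biological distances, routes, ranks.

The connectome of a core gene lists every other network gene ordered by
shortest-path biological distance, with ten annotation categories per
record: distance, rank, connectivity p-value, best reciprocal p-value
(BRP), distance/median ratio, distance/mean ratio, sphere (rank decile),
predicted route, degrees of separation, and full gene name.

Tie-breaking is deterministic: equal distances are ordered alphabetically
by target symbol, and unreachable targets (infinite distance) rank after
all reachable ones.  Ranks are ordinal 1..N after that ordering, so the
output is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .errors import UnknownGeneError
from .netio import AliasMap
from .network import GeneNetwork

#: Number of sphere bins (rank deciles).
N_SPHERES = 10


@dataclass(frozen=True)
class ConnectomeRecord:
    target: str
    distance: float
    rank: int
    p_value: float
    brp: float | None
    ratio_median: float | None
    ratio_mean: float | None
    sphere: int
    route: tuple[str, ...]
    degrees: int | None
    full_name: str = ""

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.distance)


@dataclass
class Connectome:
    """All non-core genes ranked by biological distance to ``core``."""

    core: str
    records: list[ConnectomeRecord]
    n_genes: int  # N = number of non-core genes in the network
    _by_target: dict[str, ConnectomeRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_target:
            self._by_target = {r.target: r for r in self.records}

    def record(self, target: str) -> ConnectomeRecord:
        t = target.upper()
        if t == self.core:
            return self.core_record()
        try:
            return self._by_target[t]
        except KeyError:
            raise UnknownGeneError(
                f"{target!r} is not in the connectome of {self.core}"
            ) from None

    def core_record(self) -> ConnectomeRecord:
        """The core gene queried against its own connectome: distance 0,
        rank 0, p-value at the 1/N floor."""
        p = 1.0 / self.n_genes
        return ConnectomeRecord(
            target=self.core,
            distance=0.0,
            rank=0,
            p_value=p,
            brp=p,
            ratio_median=0.0,
            ratio_mean=0.0,
            sphere=0,
            route=(self.core,),
            degrees=0,
            full_name="",
        )

    def __contains__(self, target: str) -> bool:
        t = target.upper()
        return t == self.core or t in self._by_target

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self):
        """Export as a DataFrame mirroring the connectome table columns."""
        import pandas as pd

        rows = []
        for r in self.records:
            rows.append(
                {
                    "target": r.target,
                    "distance": r.distance,
                    "rank": r.rank,
                    "p_value": r.p_value,
                    "brp": "NA" if r.brp is None else r.brp,
                    "ratio_median": "NA" if r.ratio_median is None else r.ratio_median,
                    "ratio_mean": "NA" if r.ratio_mean is None else r.ratio_mean,
                    "sphere": r.sphere,
                    "route": "->".join(r.route),
                    "degrees": "NA" if r.degrees is None else r.degrees,
                    "full_name": r.full_name,
                }
            )
        return pd.DataFrame(rows)


def shortest_paths(
    net: GeneNetwork, core: str
) -> tuple[dict[str, float], dict[str, list[str]]]:
    """Single-source shortest biological distances and minimizing routes.

    Returns ``(distances, routes)`` over every network node; nodes in other
    connected components get infinite distance and an empty route.
    """
    core = core.upper()
    if core not in net:
        raise UnknownGeneError(f"core gene {core!r} is not a network node")
    dist, paths = nx.single_source_dijkstra(net.graph, core, weight="distance")
    distances: dict[str, float] = {}
    routes: dict[str, list[str]] = {}
    for node in net.graph.nodes:
        if node in dist:
            distances[node] = dist[node]
            routes[node] = list(paths[node])
        else:
            distances[node] = math.inf
            routes[node] = []
    return distances, routes


def ranked_targets(net: GeneNetwork, source: str) -> list[tuple[str, float]]:
    """All non-source nodes ordered by (distance, symbol); unreachable last.

    This ordering defines ranks and therefore rank-percentile p-values.
    """
    distances, _ = shortest_paths(net, source)
    src = source.upper()
    items = [(t, d) for t, d in distances.items() if t != src]
    items.sort(key=lambda td: (td[1], td[0]))
    return items


def rank_of(net: GeneNetwork, source: str, target: str) -> int:
    """1-based rank of ``target`` in the connectome ordering of ``source``."""
    tgt = target.upper()
    for i, (t, _) in enumerate(ranked_targets(net, source), start=1):
        if t == tgt:
            return i
    raise UnknownGeneError(f"{target!r} is not a network node")


def build_connectome(
    net: GeneNetwork,
    core: str,
    alias_map: AliasMap | None = None,
    with_brp: bool = True,
) -> Connectome:
    """Assemble the full gene-specific connectome of ``core``.

    ``with_brp=True`` computes the best reciprocal p-value for every
    record, which costs one shortest-path run per *reachable* target;
    pass ``with_brp=False`` when building many connectomes at scale and
    only distance/p-value ranking is needed (BRP is then None/NA).
    """
    core = core.upper()
    distances, routes = shortest_paths(net, core)
    ordered = ranked_targets(net, core)
    n = len(ordered)
    finite = [d for _, d in ordered if math.isfinite(d)]
    med = _median(finite) if finite else math.nan
    mean = sum(finite) / len(finite) if finite else math.nan

    records: list[ConnectomeRecord] = []
    for rank, (target, d) in enumerate(ordered, start=1):
        reachable = math.isfinite(d)
        p = rank / n if reachable else 1.0
        if with_brp:
            if reachable:
                p_rev = _reverse_pvalue(net, target, core)
                brp: float | None = min(p, p_rev)
            else:
                brp = 1.0  # core is equally unreachable from the target
        else:
            brp = None
        route = tuple(routes[target]) if reachable else ()
        records.append(
            ConnectomeRecord(
                target=target,
                distance=d,
                rank=rank,
                p_value=p,
                brp=brp,
                ratio_median=(d / med) if reachable else None,
                ratio_mean=(d / mean) if reachable else None,
                sphere=math.ceil(N_SPHERES * rank / n),
                route=route,
                degrees=len(route) - 1 if reachable else None,
                full_name=alias_map.full_name(target) if alias_map else "",
            )
        )
    return Connectome(core=core, records=records, n_genes=n)


def route_between(net: GeneNetwork, a: str, b: str) -> list[str]:
    """One minimal-distance route from ``a`` to ``b``; empty if unreachable."""
    a, b = a.upper(), b.upper()
    if a not in net:
        raise UnknownGeneError(f"{a!r} is not a network node")
    if b not in net:
        raise UnknownGeneError(f"{b!r} is not a network node")
    if a == b:
        return [a]
    _, routes = shortest_paths(net, a)
    return routes[b]


def _reverse_pvalue(net: GeneNetwork, source: str, target: str) -> float:
    """Rank-percentile p-value of ``target`` within ``source``'s connectome."""
    ordered = ranked_targets(net, source)
    n = len(ordered)
    for i, (t, d) in enumerate(ordered, start=1):
        if t == target:
            return (i / n) if math.isfinite(d) else 1.0
    raise UnknownGeneError(f"{target!r} is not a network node")


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    m = len(s)
    mid = m // 2
    return s[mid] if m % 2 else 0.5 * (s[mid - 1] + s[mid])
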