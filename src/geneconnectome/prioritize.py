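"""Rank candidate gene lists against core genes.

Candidates — typically the genes surviving variant filtering of a
whole-exome experiment — are ranked against one or more core genes by
biological distance, connectivity p-value, or best reciprocal p-value,
either globally (each candidate reported once, with the core gene that
minimizes the metric) or separated by core gene.

Candidates that resolve to no network node are reported in the table's
``unresolved`` list with a logged warning, never silently dropped: real
WES lists routinely contain symbols absent from interaction databases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .connectome import Connectome, ConnectomeRecord, build_connectome, ranked_targets
from .errors import DataError
from .netio import AliasMap
from .network import GeneNetwork

logger = logging.getLogger(__name__)

METRICS = ("distance", "p_value", "brp")
MODES = ("global", "per_core")


@dataclass
class PrioritizationTable:
    """Ranked (candidate, core) rows plus the symbols that did not resolve."""

    rows: list[dict]
    metric: str
    mode: str
    unresolved: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        cols = [
            "candidate",
            "core",
            "distance",
            "rank_in_core_connectome",
            "p_value",
            "brp",
            "ratio_median",
            "ratio_mean",
            "sphere",
            "degrees",
            "route",
            "full_name",
        ]
        df = pd.DataFrame(self.rows, columns=cols)
        for col in ("brp", "ratio_median", "ratio_mean", "degrees"):
            # None becomes NaN during frame construction; both export as NA
            df[col] = df[col].astype(object).map(lambda v: "NA" if pd.isna(v) else v)
        return df

    def __len__(self) -> int:
        return len(self.rows)


def resolve_symbols(
    symbols: Sequence[str],
    alias_map: AliasMap | None,
    net: GeneNetwork,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Map input symbols to canonical network nodes.

    Resolution order per symbol (after upper-casing): exact network-node
    match, then alias-table match whose canonical symbol is a network node.
    Returns ``(resolved, unresolved)`` where resolved pairs are
    ``(input_symbol, canonical_node)``.
    """
    resolved: list[tuple[str, str]] = []
    unresolved: list[str] = []
    for raw in symbols:
        sym = raw.strip().upper()
        if not sym:
            continue
        if sym in net:
            resolved.append((sym, sym))
            continue
        if alias_map is not None:
            canonical = alias_map.resolve(sym)
            if canonical is not None and canonical in net:
                resolved.append((sym, canonical))
                continue
        unresolved.append(sym)
    return resolved, unresolved


def prioritize(
    net: GeneNetwork,
    candidates: Sequence[str],
    cores: Sequence[str],
    metric: str = "distance",
    mode: str = "global",
    alias_map: AliasMap | None = None,
    with_brp: bool = True,
) -> PrioritizationTable:
    """Rank ``candidates`` against ``cores``.

    ``mode="global"`` keeps, for each candidate, the row of the core gene
    minimizing the metric and sorts all rows by that metric ascending;
    ``mode="per_core"`` groups rows by core gene, each group sorted
    ascending.  Ties are broken alphabetically.  ``with_brp=False`` skips
    the BRP column (reported NA) unless the metric itself is ``brp``.
    """
    if metric not in METRICS:
        raise DataError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if mode not in MODES:
        raise DataError(f"unknown mode {mode!r}; expected one of {MODES}")
    if not candidates:
        raise DataError("candidate list is empty")
    if not cores:
        raise DataError("core gene list is empty")

    core_pairs, bad_cores = resolve_symbols(cores, alias_map, net)
    if not core_pairs:
        raise DataError(f"no core gene resolvable to a network node: {list(cores)}")
    if bad_cores:
        logger.warning("dropping unresolvable core gene(s): %s", ", ".join(bad_cores))
    # dedupe cores preserving first-seen order
    core_nodes = list(dict.fromkeys(c for _, c in core_pairs))

    cand_pairs, unresolved = resolve_symbols(candidates, alias_map, net)
    if unresolved:
        logger.warning("unresolved candidate symbol(s): %s", ", ".join(unresolved))
    cand_nodes = sorted(set(c for _, c in cand_pairs))

    need_brp = with_brp or metric == "brp"
    connectomes: dict[str, Connectome] = {
        core: build_connectome(net, core, alias_map, with_brp=False)
        for core in core_nodes
    }
    # One reverse shortest-path run per candidate covers all cores.
    reverse_p: dict[str, dict[str, float]] = {}
    if need_brp:
        for cand in cand_nodes:
            ordered = ranked_targets(net, cand)
            n = len(ordered)
            ranks = {
                t: (i / n if math.isfinite(d) else 1.0)
                for i, (t, d) in enumerate(ordered, start=1)
            }
            reverse_p[cand] = {core: ranks[core] for core in core_nodes if core != cand}

    rows: list[dict] = []
    for cand in cand_nodes:
        for core in core_nodes:
            rec = connectomes[core].record(cand)
            if not need_brp:
                brp = None
            elif cand == core:
                brp = rec.brp  # 1/N floor from the core self-record
            else:
                p_rev = reverse_p[cand][core]
                brp = rec.p_value if rec.p_value < p_rev else p_rev
            rows.append(_row(cand, core, rec, brp))

    key = {"distance": "distance", "p_value": "p_value", "brp": "brp"}[metric]

    def metric_value(row: dict) -> float:
        v = row[key]
        return math.inf if v is None else v

    if mode == "global":
        best: dict[str, dict] = {}
        for row in rows:
            cur = best.get(row["candidate"])
            if cur is None or (metric_value(row), row["core"]) < (metric_value(cur), cur["core"]):
                best[row["candidate"]] = row
        out = sorted(best.values(), key=lambda r: (metric_value(r), r["candidate"]))
    else:
        out = []
        for core in core_nodes:
            group = [r for r in rows if r["core"] == core]
            group.sort(key=lambda r: (metric_value(r), r["candidate"]))
            out.extend(group)
    return PrioritizationTable(rows=out, metric=metric, mode=mode, unresolved=unresolved)


def _row(candidate: str, core: str, rec: ConnectomeRecord, brp: float | None) -> dict:
    return {
        "candidate": candidate,
        "core": core,
        "distance": rec.distance,
        "rank_in_core_connectome": rec.rank,
        "p_value": rec.p_value,
        "brp": brp,
        "ratio_median": rec.ratio_median,
        "ratio_mean": rec.ratio_mean,
        "sphere": rec.sphere,
        "degrees": rec.degrees,
        "route": "->".join(rec.route),
        "full_name": rec.full_name,
    }
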