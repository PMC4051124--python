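"""Connectivity p-values, best reciprocal p-values, p-value combination.

The connectivity p-value of a target gene within a core gene's connectome
is its rank percentile, p = rank / N, where N is the number of non-core
genes in the network.  Under a null of drawing targets uniformly from the
connectome this p is exactly uniform on {1/N, 2/N, ..., 1}.  Unreachable
targets get p = 1.

The best reciprocal p-value (BRP) of a gene pair is the smaller of the
two directed rank-percentile p-values.  It is symmetric by construction
and compensates for hub (central) genes — whose connectomes rank almost
everything closely — and for isolated genes: a target deep in a hub's
connectome may still place the hub near the top of its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import chi2

from .connectome import Connectome, ranked_targets
from .errors import DataError, UnknownGeneError
from .network import GeneNetwork

COMBINE_METHODS = ("product", "fisher")


@dataclass(frozen=True)
class PValuePair:
    """Directed p-values of a gene pair and their minimum (the BRP)."""

    p_core_to_target: float
    p_target_to_core: float

    @property
    def brp(self) -> float:
        return min(self.p_core_to_target, self.p_target_to_core)


def connectivity_pvalue(connectome: Connectome, target: str) -> float:
    """Rank-percentile p-value of ``target`` in ``connectome``.

    The core gene itself gets the 1/N floor; unreachable targets get 1.
    """
    return connectome.record(target).p_value


def best_reciprocal_pvalue(net: GeneNetwork, a: str, b: str) -> PValuePair:
    """Both directed rank-percentile p-values for the pair and their minimum.

    Symmetric: ``best_reciprocal_pvalue(net, a, b).brp`` equals
    ``best_reciprocal_pvalue(net, b, a).brp``.
    """
    a, b = a.upper(), b.upper()
    for sym in (a, b):
        if sym not in net:
            raise UnknownGeneError(f"{sym!r} is not a network node")
    if a == b:
        p = 1.0 / (net.n_nodes - 1)
        return PValuePair(p, p)
    return PValuePair(
        p_core_to_target=_directed_pvalue(net, a, b),
        p_target_to_core=_directed_pvalue(net, b, a),
    )


def _directed_pvalue(net: GeneNetwork, source: str, target: str) -> float:
    ordered = ranked_targets(net, source)
    n = len(ordered)
    for rank, (t, d) in enumerate(ordered, start=1):
        if t == target:
            return (rank / n) if math.isfinite(d) else 1.0
    raise UnknownGeneError(f"{target!r} is not a network node")


def combine_pvalues(ps: Sequence[float], method: str = "product") -> float:
    """Combine per-patient p-values.

    ``product`` returns the plain product of the rank-percentile
    probabilities (the chance that independent uniform draws are each at
    least this extreme, taken jointly).  ``fisher`` returns the upper-tail
    probability of -2 * sum(ln p) under a chi-square law with 2k degrees
    of freedom.  Both are monotone in sum(ln p), so they order gene lists
    identically for equal-length inputs.
    """
    if len(ps) == 0:
        raise DataError("cannot combine an empty list of p-values")
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise DataError(f"p-value out of (0, 1]: {p!r}")
    if method == "product":
        out = 1.0
        for p in ps:
            out *= p
        return out
    if method == "fisher":
        stat = -2.0 * sum(math.log(p) for p in ps)
        return float(chi2.sf(stat, df=2 * len(ps)))
    raise DataError(f"unknown combination method {method!r}; expected one of {COMBINE_METHODS}")
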