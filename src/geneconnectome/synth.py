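"""Synthetic interaction networks and variant tables with planted structure.

The generator emulates the working hypothesis behind distance-based gene
prioritization: causal genes of a phenotype are functionally close to each
other.  A background Erdős–Rényi network with weak confidence scores
carries a planted, fully connected module of high-confidence edges; the
core gene and the causal candidate both sit inside the module, so the
causal gene is biologically close to the core while background candidates
are not.

The variant-table generator produces a whole-exome-like mixture of
synonymous, common, cohort-frequent, and rare nonsynonymous variants with
an exact (deterministic) composition, plus one guaranteed-surviving rare
nonsynonymous variant in the causal gene, so the filter's kept count is
analytically predictable.

All randomness flows through numpy Generators seeded from ``config.seed``;
identical configs yield identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError
from .netio import InteractionRecord, VariantRecord

#: Default composition of the synthetic variant table.
FRAC_SYNONYMOUS = 0.25
FRAC_COMMON = 0.25
FRAC_COHORT_FREQUENT = 0.10


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: a 500-gene Erdős–Rényi background at edge probability 0.02
    with confidence scores uniform in [0.15, 0.40), a fully connected
    10-gene planted module with scores uniform in [0.70, 0.95), and a
    200-gene candidate list.
    """

    n_genes: int = 500
    edge_prob: float = 0.02
    background_score_range: tuple[float, float] = (0.15, 0.40)
    module_size: int = 10
    module_score_range: tuple[float, float] = (0.70, 0.95)
    seed: int = 0
    n_candidates: int = 200
    hub: bool = False
    hub_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise DataError("n_genes must be >= 2")
        if not (0.0 < self.edge_prob < 1.0):
            raise DataError("edge_prob must be in (0, 1)")
        if self.module_size > self.n_genes:
            raise DataError(
                f"module_size {self.module_size} exceeds n_genes {self.n_genes}"
            )
        for name in ("background_score_range", "module_score_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi <= 1.0):
                raise DataError(f"{name} must satisfy 0 < low <= high <= 1")
        if self.module_size > 1 and self.module_score_range[0] <= self.background_score_range[1]:
            raise DataError(
                "module scores must lie strictly above the background score range"
            )


def gene_universe(config: SynthConfig) -> list[str]:
    """Deterministic gene symbols G0001..G<n> (width grows with n)."""
    width = max(4, len(str(config.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def generate_network(
    config: SynthConfig, planted: bool = True
) -> tuple[list[InteractionRecord], set[str]]:
    """Erdős–Rényi background plus (optionally) a planted high-score module.

    Returns the interaction records and the module gene set.  With
    ``planted=False`` the module genes are still drawn (so experiments can
    refer to the same core/causal genes) but no module edges or scores are
    added: the network is pure background and module membership has no
    effect — the chance-level control condition.
    """
    rng = np.random.default_rng([config.seed, 0])
    genes = gene_universe(config)
    module_idx = np.sort(rng.choice(config.n_genes, size=config.module_size, replace=False))
    module = {genes[i] for i in module_idx}
    in_module = np.zeros(config.n_genes, dtype=bool)
    in_module[module_idx] = True

    ii, jj = np.triu_indices(config.n_genes, k=1)
    present = rng.random(ii.size) < config.edge_prob
    if planted:
        present &= ~(in_module[ii] & in_module[jj])
    lo, hi = config.background_score_range
    scores = rng.uniform(lo, hi, size=int(present.sum()))

    records = [
        InteractionRecord(genes[a], genes[b], s)
        for a, b, s in zip(ii[present], jj[present], scores)
    ]

    if planted and config.module_size > 1:
        mlo, mhi = config.module_score_range
        midx = list(module_idx)
        n_mod_edges = config.module_size * (config.module_size - 1) // 2
        mod_scores = iter(rng.uniform(mlo, mhi, size=n_mod_edges))
        for k, a in enumerate(midx):
            for b in midx[k + 1 :]:
                records.append(InteractionRecord(genes[a], genes[b], next(mod_scores)))

    if config.hub:
        hub_idx = int(rng.integers(config.n_genes))
        n_spokes = max(1, int(round(config.hub_fraction * config.n_genes)))
        others = [i for i in range(config.n_genes) if i != hub_idx]
        spokes = rng.choice(len(others), size=min(n_spokes, len(others)), replace=False)
        mlo, mhi = config.module_score_range
        hub_scores = rng.uniform(mlo, mhi, size=spokes.size)
        existing = {r.pair for r in records}
        for s_idx, sc in zip(spokes, hub_scores):
            rec = InteractionRecord(genes[hub_idx], genes[others[s_idx]], sc)
            if rec.pair not in existing:
                records.append(rec)
                existing.add(rec.pair)

    # collapse any duplicate pairs keeping the max score, and fix the order
    best: dict[tuple[str, str], InteractionRecord] = {}
    for rec in records:
        prev = best.get(rec.pair)
        if prev is None or rec.score > prev.score:
            best[rec.pair] = rec
    return sorted(best.values()), module


def generate_variant_table(
    config: SynthConfig,
    causal_gene: str,
    n_variants: int,
    frac_synonymous: float = FRAC_SYNONYMOUS,
    frac_common: float = FRAC_COMMON,
    frac_cohort_frequent: float = FRAC_COHORT_FREQUENT,
    exclude: Sequence[str] = (),
) -> list[VariantRecord]:
    """A WES-like variant table with exact composition.

    Counts are deterministic: ``round(frac * n_variants)`` synonymous,
    common, and cohort-frequent variants; the remainder are rare
    nonsynonymous variants in *distinct* genes, the first of which is a
    guaranteed-surviving variant in ``causal_gene``.  Genes in ``exclude``
    never receive a rare variant (use it to keep planted-module genes out
    of the background candidate pool).  The kept set under default filter
    thresholds is exactly the rare variants.
    """
    causal_gene = causal_gene.upper()
    genes = gene_universe(config)
    if causal_gene not in genes:
        raise DataError(f"causal gene {causal_gene!r} is not in the gene universe")
    rng = np.random.default_rng([config.seed, 1])

    n_syn = round(frac_synonymous * n_variants)
    n_common = round(frac_common * n_variants)
    n_cohort = round(frac_cohort_frequent * n_variants)
    n_rare = n_variants - n_syn - n_common - n_cohort
    if n_rare < 1:
        raise DataError("composition leaves no room for the causal rare variant")

    excluded = {g.upper() for g in exclude} | {causal_gene}
    pool = [g for g in genes if g not in excluded]
    if n_rare - 1 > len(pool):
        raise DataError(
            f"need {n_rare - 1} distinct background genes but only {len(pool)} available"
        )
    rare_genes = [causal_gene] + [
        pool[i] for i in rng.choice(len(pool), size=n_rare - 1, replace=False)
    ]

    def rare_freqs() -> tuple[float, float, float]:
        return (
            float(rng.uniform(0.0, 0.009)),
            float(rng.uniform(0.0, 0.009)),
            float(rng.uniform(0.0, 0.006)),
        )

    records: list[VariantRecord] = []
    for g in rare_genes:
        f1, f2, fc = rare_freqs()
        records.append(VariantRecord(g, "missense", f1, f2, fc))
    for _ in range(n_syn):
        g = pool[int(rng.integers(len(pool)))]
        f1, f2, fc = rare_freqs()
        records.append(VariantRecord(g, "synonymous", f1, f2, fc))
    for _ in range(n_common):
        g = pool[int(rng.integers(len(pool)))]
        records.append(
            VariantRecord(
                g,
                "missense",
                float(rng.uniform(0.02, 0.20)),
                float(rng.uniform(0.02, 0.20)),
                float(rng.uniform(0.0, 0.006)),
            )
        )
    for _ in range(n_cohort):
        g = pool[int(rng.integers(len(pool)))]
        f1, f2, _ = rare_freqs()
        records.append(
            VariantRecord(g, "missense", f1, f2, float(rng.uniform(0.0065, 0.05)))
        )

    order = rng.permutation(len(records))
    return [records[i] for i in order]


def _solve_n_variants(n_rare_wanted: int, rare_frac: float) -> int:
    """Smallest variant count whose rounded composition leaves exactly
    ``n_rare_wanted`` rare variants (rounding can shift the split by one)."""
    start = max(n_rare_wanted, int(round(n_rare_wanted / rare_frac)) - 5)
    for n in range(start, start + 50):
        n_rare = (
            n
            - round(FRAC_SYNONYMOUS * n)
            - round(FRAC_COMMON * n)
            - round(FRAC_COHORT_FREQUENT * n)
        )
        if n_rare == n_rare_wanted:
            return n
    raise DataError(
        f"no variant count yields exactly {n_rare_wanted} rare variants"
    )


@dataclass(frozen=True)
class RecoveryCase:
    """One synthetic benchmark replicate ready for the full pipeline."""

    records: list[InteractionRecord]
    module: set[str]
    core: str
    causal: str
    variants: list[VariantRecord]


def generate_recovery_case(config: SynthConfig, planted: bool = True) -> RecoveryCase:
    """Network + variant table for one planted-pathway recovery replicate.

    The core gene and the causal candidate are both planted-module genes
    (distinct).  The variant count is chosen so that, after filtering, the
    candidate list holds exactly ``config.n_candidates`` genes: the causal
    gene plus ``n_candidates - 1`` background genes outside the module.
    """
    if config.module_size < 2:
        raise DataError("recovery case needs a module of at least 2 genes")
    records, module = generate_network(config, planted=planted)
    nodes = {g for r in records for g in r.pair}
    module_sorted = sorted(module)
    core = next((g for g in module_sorted if g in nodes), module_sorted[0])
    causal = next(g for g in module_sorted if g != core)

    rare_frac = 1.0 - FRAC_SYNONYMOUS - FRAC_COMMON - FRAC_COHORT_FREQUENT
    n_variants = _solve_n_variants(config.n_candidates, rare_frac)
    variants = generate_variant_table(
        config,
        causal,
        n_variants,
        exclude=sorted(module | {core}),
    )
    return RecoveryCase(
        records=records, module=module, core=core, causal=causal, variants=variants
    )
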