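"""Readers and writers for every file format the tool touches.

All tables are plain TSV, UTF-8, LF line endings.  Gene symbols are
case-normalized to upper case at read time, so the rest of the system only
ever sees canonical upper-case symbols.  Interaction confidence scores are
normalized into (0, 1] at read time by dividing by ``score_scale``
(default 1000, the STRING convention of integer scores in 1..1000).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import AmbiguousAliasError, DataError

logger = logging.getLogger(__name__)

#: Recognized variant effect classes.
EFFECT_CLASSES = frozenset(
    {"synonymous", "missense", "nonsense", "frameshift", "splice", "other"}
)


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One scored gene-gene direct interaction (a network edge source).

    The pair is unordered; the constructor canonicalizes so that
    ``gene_a < gene_b`` lexicographically, making records hashable and
    comparable regardless of input orientation.
    """

    gene_a: str
    gene_b: str
    score: float

    def __post_init__(self) -> None:
        a, b = self.gene_a.upper(), self.gene_b.upper()
        if a == b:
            raise DataError(f"self-interaction not allowed: {a}")
        if not (0.0 < self.score <= 1.0):
            raise DataError(f"score out of (0, 1]: {self.score!r} for pair {a}-{b}")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class AliasEntry:
    alias: str
    canonical: str
    full_name: str


@dataclass(frozen=True)
class VariantRecord:
    """One candidate variant with effect class and frequency annotations.

    ``freq_db1`` / ``freq_db2`` are population allele frequencies from two
    independent databases (e.g. 1000 Genomes and the NHLBI Exome Variant
    Server); ``cohort_freq`` is the fraction of patients in other-disease
    cohorts carrying the variant (a batch-effect proxy).  A frequency absent
    from the source table parses as 0, so a variant with no database record
    is retained by the frequency filters.
    """

    gene: str
    effect: str
    freq_db1: float = 0.0
    freq_db2: float = 0.0
    cohort_freq: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.upper())
        eff = self.effect.lower()
        if eff not in EFFECT_CLASSES:
            raise DataError(
                f"unknown effect class {self.effect!r}; "
                f"expected one of {sorted(EFFECT_CLASSES)}"
            )
        object.__setattr__(self, "effect", eff)
        for name in ("freq_db1", "freq_db2", "cohort_freq"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} out of [0, 1]: {v!r} for gene {self.gene}")


class AliasMap:
    """Lookup structure mapping aliases to canonical symbols and full names."""

    def __init__(self, entries: Iterable[AliasEntry] = ()) -> None:
        self._alias_to_canonical: dict[str, str] = {}
        self._full_names: dict[str, str] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: AliasEntry) -> None:
        alias = entry.alias.upper()
        canonical = entry.canonical.upper()
        prev = self._alias_to_canonical.get(alias)
        if prev is not None and prev != canonical:
            raise AmbiguousAliasError(
                f"alias {alias!r} maps to both {prev!r} and {canonical!r}"
            )
        self._alias_to_canonical[alias] = canonical
        if entry.full_name and (alias == canonical or canonical not in self._full_names):
            self._full_names[canonical] = entry.full_name

    def resolve(self, symbol: str) -> str | None:
        """Return the canonical symbol for ``symbol``, or None if unknown."""
        return self._alias_to_canonical.get(symbol.upper())

    def full_name(self, canonical: str) -> str:
        """Full gene name for a canonical symbol; empty string if absent."""
        return self._full_names.get(canonical.upper(), "")

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self._alias_to_canonical

    def __len__(self) -> int:
        return len(self._alias_to_canonical)


def _rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-blank, non-comment lines."""
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            yield lineno, [f.strip() for f in row]


def read_interactions(
    path: str | Path, score_scale: float = 1000.0
) -> list[InteractionRecord]:
    """Read a pairwise interaction table: gene_a, gene_b, score.

    Scores are divided by ``score_scale`` and must land in (0, 1].
    Duplicate unordered pairs are collapsed keeping the maximum score
    (the shortest resulting distance); self-loops are dropped with a
    logged count.  A header row is skipped if its score column does not
    parse as a number.
    """
    if score_scale <= 0:
        raise DataError(f"score_scale must be positive, got {score_scale}")
    best: dict[tuple[str, str], InteractionRecord] = {}
    n_self = 0
    first = True
    for lineno, row in _rows(path):
        if len(row) < 3:
            raise DataError(f"{path}: line {lineno}: expected >=3 columns, got {len(row)}")
        a, b, raw = row[0], row[1], row[2]
        try:
            score_raw = float(raw)
        except ValueError:
            if first:
                first = False
                continue  # header row
            raise DataError(f"{path}: line {lineno}: non-numeric score {raw!r}") from None
        first = False
        if not (0.0 < score_raw <= score_scale):
            raise DataError(
                f"{path}: line {lineno}: score {score_raw} outside (0, {score_scale}]"
            )
        if a.upper() == b.upper():
            n_self += 1
            continue
        rec = InteractionRecord(a, b, score_raw / score_scale)
        prev = best.get(rec.pair)
        if prev is None or rec.score > prev.score:
            best[rec.pair] = rec
    if n_self:
        logger.warning("%s: dropped %d self-loop row(s)", path, n_self)
    records = sorted(best.values())
    logger.info("%s: %d interaction record(s) read", path, len(records))
    return records


def write_interactions(
    records: Sequence[InteractionRecord],
    path: str | Path,
    score_scale: float = 1000.0,
) -> None:
    """Write interaction records on the raw score scale (round-trip safe)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for r in sorted(records):
            fh.write(f"{r.gene_a}\t{r.gene_b}\t{r.score * score_scale:.10g}\n")


def read_aliases(path: str | Path) -> AliasMap:
    """Read an alias table: alias, canonical, full_name."""
    amap = AliasMap()
    first = True
    for lineno, row in _rows(path):
        if len(row) < 2:
            raise DataError(f"{path}: line {lineno}: expected >=2 columns")
        if first and row[0].lower() == "alias" and row[1].lower() == "canonical":
            first = False
            continue
        first = False
        full = row[2] if len(row) > 2 else ""
        amap.add(AliasEntry(alias=row[0], canonical=row[1], full_name=full))
    return amap


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a variant table: gene, effect, freq_db1, freq_db2, cohort_freq.

    Missing or empty frequency fields parse as 0 (the variant is retained by
    the frequency filters; absence of a database record must not silently
    discard a rare variant).
    """
    records: list[VariantRecord] = []
    first = True
    for lineno, row in _rows(path):
        if len(row) < 2:
            raise DataError(f"{path}: line {lineno}: expected >=2 columns")
        if first and row[0].lower() == "gene" and row[1].lower() == "effect":
            first = False
            continue
        first = False
        freqs = []
        for i in range(2, 5):
            raw = row[i] if i < len(row) else ""
            if raw in ("", "NA", "na", "."):
                freqs.append(0.0)
            else:
                try:
                    freqs.append(float(raw))
                except ValueError:
                    raise DataError(
                        f"{path}: line {lineno}: non-numeric frequency {raw!r}"
                    ) from None
        try:
            records.append(
                VariantRecord(
                    gene=row[0],
                    effect=row[1],
                    freq_db1=freqs[0],
                    freq_db2=freqs[1],
                    cohort_freq=freqs[2],
                )
            )
        except DataError as exc:
            raise DataError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_variants(records: Sequence[VariantRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\teffect\tfreq_db1\tfreq_db2\tcohort_freq\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{r.effect}\t{r.freq_db1:.10g}\t{r.freq_db2:.10g}\t"
                f"{r.cohort_freq:.10g}\n"
            )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a candidate list: one symbol per line; blanks and '#' lines skipped."""
    symbols: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                symbols.append(s.upper())
    return symbols


def write_gene_list(symbols: Sequence[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in symbols:
            fh.write(f"{s.upper()}\n")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with header, UTF-8, LF line endings."""
    table.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")
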