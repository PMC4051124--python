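"""Whole-exome variant filtering applied before prioritization.

Three rules, applied in order:

(i)   effect filter — drop synonymous variants (configurable set);
(ii)  population-frequency filter — keep only variants rarer than
      ``popfreq_max`` (strictly ``<``, default 1%) in *both* population
      databases;
(iii) cohort filter — drop variants carried by more than ``cohort_max``
      (default 0.6%) of patients in other-disease cohorts, a batch-effect
      and hypermutable-gene guard.

The kept *set* is independent of rule order; only the per-rule drop
attribution (first failing rule wins) depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import DataError
from .netio import EFFECT_CLASSES, VariantRecord


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three-rule variant filter.

    ``popfreq_max`` is exclusive (a variant at exactly the threshold is
    dropped); ``cohort_max`` is inclusive (kept at exactly the threshold,
    dropped above it — the rule reads "more than").
    """

    popfreq_max: float = 0.01
    cohort_max: float = 0.006
    drop_effects: frozenset[str] = frozenset({"synonymous"})

    def __post_init__(self) -> None:
        for name in ("popfreq_max", "cohort_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} out of [0, 1]: {v!r}")
        bad = set(self.drop_effects) - EFFECT_CLASSES
        if bad:
            raise DataError(f"unknown effect class(es) in drop_effects: {sorted(bad)}")
        object.__setattr__(self, "drop_effects", frozenset(self.drop_effects))


RULE_NAMES = ("effect", "population_frequency", "cohort_frequency")


def filter_variants(
    records: Sequence[VariantRecord],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the three filtering rules; return kept records and drop counts.

    A variant is kept iff its effect is not in ``drop_effects`` AND both
    population frequencies are strictly below ``popfreq_max`` AND its
    cohort frequency does not exceed ``cohort_max``.  Drop counts are
    attributed to the first failing rule.
    """
    kept: list[VariantRecord] = []
    drops = {name: 0 for name in RULE_NAMES}
    for rec in records:
        if rec.effect in config.drop_effects:
            drops["effect"] += 1
        elif rec.freq_db1 >= config.popfreq_max or rec.freq_db2 >= config.popfreq_max:
            drops["population_frequency"] += 1
        elif rec.cohort_freq > config.cohort_max:
            drops["cohort_frequency"] += 1
        else:
            kept.append(rec)
    return kept, drops


def genes_of(records: Sequence[VariantRecord]) -> list[str]:
    """Unique gene symbols of the kept variants, sorted; feeds prioritize."""
    return sorted({r.gene for r in records})
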