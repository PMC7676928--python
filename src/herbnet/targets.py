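"""Target-set algebra: dedup, merge, intersect.

The therapeutic-target set of an herb against a disease is the
intersection of (a) the union of targets of its active compounds and
(b) the disease gene set merged across database sources.  Everything here
operates on normalized gene symbols (see :mod:`herbnet.symbols`); the
counts a study reports for "targets after removing duplicates" are exactly
the sizes of these sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError

logger = logging.getLogger("herbnet")

__all__ = ["TargetSet", "CompoundTargetMap",
           "union_targets", "merge_disease_sources", "intersect_targets"]


@dataclass(frozen=True)
class TargetSet:
    """A labelled set of normalized gene symbols."""

    label: str
    symbols: frozenset[str]

    def __init__(self, label: str, symbols: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "symbols", frozenset(symbols))

    def __len__(self):
        return len(self.symbols)

    def __contains__(self, symbol):
        return symbol in self.symbols

    def __iter__(self):
        return iter(sorted(self.symbols))


@dataclass(frozen=True)
class CompoundTargetMap:
    """The bipartite compound -> target relation as a deduplicated pair set."""

    pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __init__(self, pairs: Iterable[tuple[str, str]],
                 allowed_compounds: Iterable[str] | None = None):
        pairset = frozenset((c, t) for c, t in pairs)
        if allowed_compounds is not None:
            allowed = set(allowed_compounds)
            stray = {c for c, _ in pairset} - allowed
            if stray:
                raise ValidationError(
                    f"compound ids not in the active compound list: {sorted(stray)[:5]}")
        object.__setattr__(self, "pairs", pairset)

    @property
    def compounds(self) -> set[str]:
        return {c for c, _ in self.pairs}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.pairs}

    def targets_of(self, compound_id: str) -> set[str]:
        return {t for c, t in self.pairs if c == compound_id}

    def degree(self, compound_id: str) -> int:
        return sum(1 for c, _ in self.pairs if c == compound_id)

    def __len__(self):
        return len(self.pairs)


def union_targets(ctmap: CompoundTargetMap, label: str = "drug") -> TargetSet:
    """Distinct targets across all compounds (raw rows minus duplicates)."""
    return TargetSet(label, ctmap.targets)


def merge_disease_sources(sources: Sequence[TargetSet], label: str = "disease") -> TargetSet:
    """Union of disease gene lists from several database queries.

    Per-source sizes are logged so the raw-vs-deduplicated counts a report
    needs are visible.
    """
    if not sources:
        raise ValidationError("merge_disease_sources needs at least one source")
    merged: set[str] = set()
    for src in sources:
        logger.info("merge_disease_sources: %s contributes %d symbols", src.label, len(src))
        merged |= src.symbols
    logger.info("merge_disease_sources: %d distinct symbols after merge", len(merged))
    return TargetSet(label, merged)


def intersect_targets(drug: TargetSet, disease: TargetSet) -> TargetSet:
    """Therapeutic targets: symbols present in both the drug and disease sets."""
    return TargetSet(f"{drug.label}&{disease.label}", drug.symbols & disease.symbols)
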