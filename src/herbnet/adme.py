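"""ADME screening of herbal compounds.

Database exports of herbal ingredients carry two precomputed
pharmacokinetic scores: oral bioavailability (OB, percent) and
drug-likeness (DL, 0–1).  The conventional screen keeps compounds with
OB >= 30% and DL >= 0.18; survivors are called "active ingredients" and
drive the rest of the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .errors import ValidationError
from .io import CompoundRecord

logger = logging.getLogger("herbnet")

__all__ = ["AdmeCriteria", "filter_compounds"]


@dataclass(frozen=True)
class AdmeCriteria:
    """Thresholds for the OB/DL screen.

    ``inclusive=True`` means compounds sitting exactly on a threshold pass
    (the criteria are stated with ">="); set it to ``False`` for a strict
    sensitivity variant.
    """

    ob_min: float = 30.0   # percent
    dl_min: float = 0.18   # unitless
    inclusive: bool = True

    def __post_init__(self):
        if not (0.0 <= self.ob_min <= 100.0):
            raise ValidationError(f"ob_min must be in [0, 100], got {self.ob_min}")
        if not (0.0 <= self.dl_min <= 1.0):
            raise ValidationError(f"dl_min must be in [0, 1], got {self.dl_min}")

    def passes(self, record: CompoundRecord) -> bool:
        if record.ob is None or record.dl is None:
            return False
        if self.inclusive:
            return record.ob >= self.ob_min and record.dl >= self.dl_min
        return record.ob > self.ob_min and record.dl > self.dl_min


def filter_compounds(compounds: Iterable[CompoundRecord],
                     criteria: AdmeCriteria | None = None,
                     sort_active_by_ob: bool = False,
                     ) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Partition compounds into (active, rejected) by the OB/DL screen.

    The two parts are disjoint, cover the input, and preserve input order
    (unless ``sort_active_by_ob`` reorders the active part by descending
    OB).  Compounds with a missing OB or DL are rejected, never silently
    kept, and the count is logged.
    """
    criteria = criteria or AdmeCriteria()
    active: list[CompoundRecord] = []
    rejected: list[CompoundRecord] = []
    missing = 0
    for rec in compounds:
        if rec.ob is None or rec.dl is None:
            missing += 1
            rejected.append(rec)
        elif criteria.passes(rec):
            active.append(rec)
        else:
            rejected.append(rec)
    if missing:
        logger.info("filter_compounds: rejected %d compound(s) with missing OB/DL", missing)
    if sort_active_by_ob:
        active.sort(key=lambda r: (-r.ob, r.compound_id))
    return active, rejected
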