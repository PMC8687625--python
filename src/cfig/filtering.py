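"""ADME-based selection of potential active ingredients.

An ingredient passes the ADME screen when its Caco-2 permeability exceeds
``caco2_min`` (strict, default −0.4) and its drug-likeness is at least
``dl_min`` (inclusive, default 0.18). Ingredients detected in the preparation
by published chemical analyses carry a literature flag and are retained
regardless of ADME — the whitelist is a union with, not an override of, the
ADME rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import IngredientRecord

CACO2_MIN_DEFAULT = -0.4
DL_MIN_DEFAULT = 0.18


@dataclass(frozen=True)
class FilterDecision:
    ingredient_id: str
    passed_adme: bool
    whitelisted: bool
    reason: str

    @property
    def retained(self) -> bool:
        return self.passed_adme or self.whitelisted


def filter_ingredients(
    records: Sequence[IngredientRecord],
    caco2_min: float = CACO2_MIN_DEFAULT,
    dl_min: float = DL_MIN_DEFAULT,
) -> list[FilterDecision]:
    """One decision per record, input order preserved.

    Missing Caco-2 or drug-likeness fails the ADME screen (only the
    literature whitelist can then retain the record).
    """
    decisions = []
    for rec in records:
        passed = (
            rec.caco2 is not None
            and rec.dl is not None
            and rec.caco2 > caco2_min
            and rec.dl >= dl_min
        )
        if passed and rec.literature_flag:
            reason = "adme_and_literature"
        elif passed:
            reason = "adme"
        elif rec.literature_flag:
            reason = "literature_whitelist"
        elif rec.caco2 is None or rec.dl is None:
            reason = "missing_adme"
        else:
            reason = "failed_adme"
        decisions.append(
            FilterDecision(rec.ingredient_id, passed, rec.literature_flag, reason)
        )
    return decisions


def retained_ids(decisions: Iterable[FilterDecision]) -> list[str]:
    return [d.ingredient_id for d in decisions if d.retained]
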