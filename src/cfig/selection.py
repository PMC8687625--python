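"""Ingredients-contribution-proportion (ICP) selection of the critical
functional ingredients group (CFIG).

Ingredients are first sorted by raw target count in descending order, then
picked greedily: at each step the ingredient with the largest marginal gain in
coverage of the key response proteins is taken (ties broken by higher raw
target count, then lexicographic id). Selection stops once the cumulative
coverage reaches the coverage target or no ingredient adds new key proteins.
Only targets that are key response proteins count toward coverage; an
ingredient with many targets but no new key proteins is never picked, which
is why the selection order can differ sharply from the raw target-count
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ValidationError
from .networks import ItNetwork


@dataclass(frozen=True)
class Pick:
    ingredient_id: str
    marginal_gain: int
    cumulative_coverage: float


@dataclass
class CfigSelection:
    picks: list[Pick]
    coverage_target: float
    achieved_coverage: float
    unreachable: bool = False
    covered: set[str] = field(default_factory=set)

    @property
    def ingredient_ids(self) -> list[str]:
        return [p.ingredient_id for p in self.picks]


def _target_map(it_network: ItNetwork | Mapping[str, set[str]]) -> dict[str, set[str]]:
    if isinstance(it_network, ItNetwork):
        return {i: it_network.targets_of(i) for i in it_network.ingredients}
    return {i: set(t) for i, t in it_network.items()}


def icp_select(
    it_network: ItNetwork | Mapping[str, set[str]],
    key_proteins: set[str],
    coverage_target: float = 0.90,
) -> CfigSelection:
    """Greedy marginal-gain cover of the key response proteins.

    Accepts either an :class:`ItNetwork` or a plain ingredient → target-set
    mapping. Every pick has strictly positive marginal gain; the returned
    selection carries the full coverage trajectory.
    """
    if not (0 < coverage_target <= 1):
        raise ValidationError(f"coverage_target must be in (0, 1]: {coverage_target}")
    if not key_proteins:
        raise ValidationError("key protein set is empty")
    targets = _target_map(it_network)
    raw_counts = {i: len(t) for i, t in targets.items()}
    effective = {i: t & set(key_proteins) for i, t in targets.items()}

    n_key = len(key_proteins)
    covered: set[str] = set()
    picks: list[Pick] = []
    remaining = set(targets)
    while remaining:
        best, best_gain = None, 0
        for i in sorted(remaining, key=lambda i: (-raw_counts[i], i)):
            gain = len(effective[i] - covered)
            if gain > best_gain:
                best, best_gain = i, gain
        if best is None:
            break
        covered |= effective[best]
        picks.append(Pick(best, best_gain, len(covered) / n_key))
        remaining.discard(best)
        if len(covered) / n_key >= coverage_target:
            break
    achieved = len(covered) / n_key
    return CfigSelection(
        picks, coverage_target, achieved,
        unreachable=achieved < coverage_target, covered=covered,
    )


def coverage_curve(selection: CfigSelection) -> list[tuple[int, float]]:
    """(rank, cumulative coverage) pairs; monotone nondecreasing by construction."""
    if not selection.picks:
        raise ValidationError("empty selection has no coverage curve")
    return [(r, p.cumulative_coverage) for r, p in enumerate(selection.picks, start=1)]


def recovery_score(selection: CfigSelection, planted_critical_ids: set[str]) -> float:
    """Fraction of planted-critical ingredients among the first |planted| picks."""
    if not planted_critical_ids:
        raise ValidationError("planted set is empty; recovery undefined")
    prefix = set(selection.ingredient_ids[: len(planted_critical_ids)])
    return len(prefix & set(planted_critical_ids)) / len(planted_critical_ids)
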