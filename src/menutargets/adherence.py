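"""Boundary-inclusive target adherence, per item and aggregated.

An item meets a target when its compared value is **equal to or lower
than** the target value.  Compared values are taken on the basis each
programme prescribes: sugar per 100 g, calories per serving (with pizza
serving-count conventions), salt on the basis carried by the matched
target row.  Denominators are eligibility-based: an item missing the
required value for one programme leaves that programme's denominator only
(with an audit entry) and stays in every other.

Counts are carried as exact integers; proportions become rounded
percentages only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Literal, Optional

import pandas as pd

from .assignment import Assignment
from .model import Basis, GroupMap, MenuDataError, MenuItem, TargetSpec

PROGRAMME_AXES = ("sugar", "calorie", "salt")
Grouping = Literal["overall", "restaurant", "subcategory", "restaurant_type"]


@dataclass
class ProgrammeResult:
    """Outcome of one item against one programme."""

    eligible: bool
    met: Optional[bool] = None
    compared_value: Optional[float] = None
    target_value: Optional[float] = None
    basis_used: Optional[Basis] = None
    dropped_reason: Optional[str] = None  # why an assigned item left the denominator

    def __post_init__(self) -> None:
        assert (self.met is not None) == self.eligible


@dataclass
class AdherenceRecord:
    item: MenuItem
    assignment: Assignment
    results: dict[str, ProgrammeResult] = field(default_factory=dict)

    def result(self, programme: str) -> ProgrammeResult:
        return self.results[programme]


@dataclass
class AdherenceSummary:
    grouping: str
    label: str
    programme: str  # sugar | calorie | salt | all_applicable
    n_eligible: int
    n_met: int

    @property
    def proportion(self) -> Optional[Fraction]:
        if self.n_eligible == 0:
            return None
        return Fraction(self.n_met, self.n_eligible)

    def percent(self, ndigits: int = 0) -> Optional[float]:
        p = self.proportion
        return None if p is None else round(float(p) * 100.0, ndigits)


def _compared_value(
    item: MenuItem, assignment: Assignment, target: TargetSpec, programme: str
) -> Optional[float]:
    value = item.vector(target.basis).get(target.nutrient)
    if value is None:
        return None
    if programme == "calorie" and item.subcategory == "Pizzas":
        # Whole-pizza per-serving data is divided by the assumed serving
        # count; restaurant-declared per-person data is already per serving.
        if item.declared_servings is None and assignment.servings_for_calorie > 1:
            value = value / assignment.servings_for_calorie
    return value


def evaluate_item(item: MenuItem, assignment: Assignment) -> AdherenceRecord:
    """Evaluate one item against each of its matched targets."""
    record = AdherenceRecord(item=item, assignment=assignment)
    targets = {
        "sugar": assignment.sugar_target,
        "calorie": assignment.calorie_target,
        "salt": assignment.salt_target,
    }
    for programme, target in targets.items():
        if target is None:
            reason = (
                "pizza_servings_unknown"
                if programme == "calorie" and assignment.calorie_unassignable
                else None
            )
            record.results[programme] = ProgrammeResult(
                eligible=False, dropped_reason=reason
            )
            continue
        value = _compared_value(item, assignment, target, programme)
        if value is None:
            record.results[programme] = ProgrammeResult(
                eligible=False, dropped_reason=f"missing_{target.nutrient}_{target.basis.value}"
            )
            continue
        record.results[programme] = ProgrammeResult(
            eligible=True,
            met=value <= target.value,
            compared_value=value,
            target_value=target.value,
            basis_used=target.basis,
        )
    return record


def all_applicable(record: AdherenceRecord) -> Optional[bool]:
    """True iff the item met every programme it is eligible for; ``None``
    (excluded from the denominator) when eligible for none."""
    eligible = [r for r in record.results.values() if r.eligible]
    if not eligible:
        return None
    return all(r.met for r in eligible)


def _group_label(record: AdherenceRecord, grouping: Grouping, groups: GroupMap) -> str:
    item = record.item
    if grouping == "overall":
        return "All"
    if grouping == "restaurant":
        return item.restaurant
    if grouping == "subcategory":
        return item.subcategory
    if grouping == "restaurant_type":
        rtype = groups.restaurant_type.get(item.restaurant)
        if rtype is None:
            raise MenuDataError(f"restaurant {item.restaurant!r} missing from group map")
        return rtype.value
    raise MenuDataError(f"unknown grouping {grouping!r}")


def aggregate(
    records: Iterable[AdherenceRecord],
    grouping: Grouping,
    groups: Optional[GroupMap] = None,
) -> list[AdherenceSummary]:
    """Per-group eligible/met counts for each programme and all-applicable.

    Group denominators are conserved: summing ``n_eligible`` over a
    grouping's labels reproduces the overall denominator for every
    programme (asserted on every call).
    """
    records = list(records)
    groups = groups or GroupMap(restaurant_type={})
    counts: dict[tuple[str, str], list[int]] = {}
    totals: dict[str, list[int]] = {p: [0, 0] for p in (*PROGRAMME_AXES, "all_applicable")}
    for record in records:
        label = _group_label(record, grouping, groups)
        for programme in PROGRAMME_AXES:
            res = record.result(programme)
            if res.eligible:
                cell = counts.setdefault((label, programme), [0, 0])
                cell[0] += 1
                totals[programme][0] += 1
                if res.met:
                    cell[1] += 1
                    totals[programme][1] += 1
        aa = all_applicable(record)
        if aa is not None:
            cell = counts.setdefault((label, "all_applicable"), [0, 0])
            cell[0] += 1
            totals["all_applicable"][0] += 1
            if aa:
                cell[1] += 1
                totals["all_applicable"][1] += 1
    summaries = [
        AdherenceSummary(grouping, label, programme, n_eligible, n_met)
        for (label, programme), (n_eligible, n_met) in sorted(counts.items())
    ]
    for programme, (n_eligible, _) in totals.items():
        group_sum = sum(
            s.n_eligible for s in summaries if s.programme == programme
        )
        assert group_sum == n_eligible, (
            f"denominator not conserved for {programme}: {group_sum} != {n_eligible}"
        )
    return summaries


def summary_frame(summaries: Iterable[AdherenceSummary], ndigits: int = 0) -> pd.DataFrame:
    """Adherence summaries as a table: group, programme, counts, percent."""
    rows = [
        {
            "grouping": s.grouping,
            "label": s.label,
            "programme": s.programme,
            "n_eligible": s.n_eligible,
            "n_met": s.n_met,
            "percent_met": s.percent(ndigits),
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=["grouping", "label", "programme", "n_eligible", "n_met", "percent_met"],
    )
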