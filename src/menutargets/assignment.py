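"""Rule-driven assignment of menu items to reduction-target categories.

The hierarchy mirrors the programmes' technical guidance:

* sugar targets are matched first; only items without a sugar match are
  considered for a calorie target (an item never holds both);
* salt targets are matched against the out-of-home (OOH) sector table
  first, then the retailer/manufacturer (RM) table.

Category matching itself is mechanical: ordered rules match on the item's
subcategory and/or an explicit per-item target-category label (first match
wins).  The judgement of which real-world guidance category an item
belongs to is upstream of this package — it arrives as the label column
or as the rule file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .model import (
    EligibilityState,
    MenuDataError,
    MenuItem,
    PizzaStyle,
    Programme,
    TargetSpec,
)

logger = logging.getLogger(__name__)

#: Serving counts assumed for takeaway sharing pizzas sold whole, by size
#: label, when the restaurant declares no serving count of its own.
PIZZA_LABEL_SERVINGS = {"large": 3, "extra-large": 4, "extra large": 4, "xl": 4}

#: Size labels treated as single-person pizzas when nothing else is known.
SINGLE_SERVING_PIZZA_LABELS = {"small", "medium"}


@dataclass(frozen=True)
class CategoryRule:
    """One ordered matching rule: programme + category, with a predicate
    over subcategory and/or explicit per-item label."""

    programme: Programme
    category_name: str
    subcategories: Optional[frozenset[str]] = None
    labels: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.subcategories is None and self.labels is None:
            raise MenuDataError(
                f"rule for {self.category_name!r} has no predicate"
            )

    def matches(self, item: MenuItem) -> bool:
        if self.labels is not None:
            if item.target_category_label not in self.labels:
                return False
        if self.subcategories is not None:
            if item.subcategory not in self.subcategories:
                return False
        return True


@dataclass
class CategoryMap:
    """Ordered category rules plus a lookup of the actual TargetSpecs."""

    rules: list[CategoryRule]
    targets: dict[tuple[Programme, str], TargetSpec] = field(default_factory=dict)

    @classmethod
    def build(
        cls, rules: Iterable[CategoryRule], targets: Iterable[TargetSpec]
    ) -> "CategoryMap":
        lookup = {(t.programme, t.category_name): t for t in targets}
        cmap = cls(rules=list(rules), targets=lookup)
        cmap.validate()
        return cmap

    @classmethod
    def from_yaml(cls, path: str | Path, targets: Iterable[TargetSpec]) -> "CategoryMap":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        rules = []
        for rec in raw.get("rules", []):
            rules.append(
                CategoryRule(
                    programme=Programme(rec["programme"]),
                    category_name=str(rec["category"]),
                    subcategories=(
                        frozenset(rec["subcategories"]) if "subcategories" in rec else None
                    ),
                    labels=frozenset(rec["labels"]) if "labels" in rec else None,
                )
            )
        return cls.build(rules, targets)

    def to_yaml(self, path: str | Path) -> None:
        raw = {"rules": []}
        for r in self.rules:
            rec = {"programme": r.programme.value, "category": r.category_name}
            if r.subcategories is not None:
                rec["subcategories"] = sorted(r.subcategories)
            if r.labels is not None:
                rec["labels"] = sorted(r.labels)
            raw["rules"].append(rec)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    def validate(self) -> None:
        """Every rule must reference an existing target row."""
        for rule in self.rules:
            key = (rule.programme, rule.category_name)
            if key not in self.targets:
                raise MenuDataError(
                    f"rule references unknown target category "
                    f"({rule.programme.value}, {rule.category_name!r})"
                )

    def lint_overlaps(self) -> list[str]:
        """Warn on rule pairs within a programme that can both match the
        same subcategory (resolution is first-match-wins, but overlap is
        usually a config mistake)."""
        notes = []
        for i, a in enumerate(self.rules):
            for b in self.rules[i + 1 :]:
                if a.programme is not b.programme:
                    continue
                if a.subcategories and b.subcategories:
                    common = a.subcategories & b.subcategories
                    if common and a.labels is None and b.labels is None:
                        notes.append(
                            f"{a.programme.value}: rules {a.category_name!r} and "
                            f"{b.category_name!r} both match subcategories {sorted(common)}; "
                            "first match wins"
                        )
        return notes

    def first_match(
        self, item: MenuItem, programme: Programme
    ) -> Optional[TargetSpec]:
        for rule in self.rules:
            if rule.programme is programme and rule.matches(item):
                return self.targets[(programme, rule.category_name)]
        return None


@dataclass
class Assignment:
    """An item's matched targets under the hierarchy.

    ``servings_for_calorie`` is the serving count the calorie target is
    judged against for pizzas (1 for everything else).
    ``calorie_unassignable`` flags a takeaway pizza whose serving count
    could not be determined; such items leave the calorie denominator
    only, with an audit entry.
    """

    item: MenuItem
    sugar_target: Optional[TargetSpec] = None
    calorie_target: Optional[TargetSpec] = None
    salt_target: Optional[TargetSpec] = None
    salt_sector: Optional[str] = None  # "ooh" | "rm"
    servings_for_calorie: int = 1
    calorie_unassignable: bool = False

    def __post_init__(self) -> None:
        assert not (self.sugar_target and self.calorie_target)

    @property
    def eligibility_state(self) -> EligibilityState:
        has_salt = self.salt_target is not None
        has_sugar = self.sugar_target is not None
        has_cal = self.calorie_target is not None
        if has_salt and has_cal:
            return EligibilityState.SALT_AND_CALORIE
        if has_salt and has_sugar:
            return EligibilityState.SALT_AND_SUGAR
        if has_salt or has_sugar or has_cal:
            return EligibilityState.ONE_PROGRAMME
        return EligibilityState.NONE


def pizza_servings(item: MenuItem) -> Optional[int]:
    """Serving count for a pizza item.

    Restaurant-declared counts take precedence.  Italian-style pizzas are
    a single serving.  Whole takeaway pizzas fall back on size-label
    conventions: large -> 3 servings, extra-large -> 4; small and medium
    are single-person pizzas.  A diameter below the sharing threshold also
    implies a single serving.  Returns ``None`` when no rule applies — the
    item is then unassignable for the calorie target.
    """
    if item.subcategory != "Pizzas":
        raise MenuDataError(f"{item.item_id} is not a pizza")
    if item.declared_servings is not None:
        return item.declared_servings
    if item.pizza_style is PizzaStyle.ITALIAN:
        return 1
    label = (item.pizza_size_label or "").strip().lower()
    if label in PIZZA_LABEL_SERVINGS:
        return PIZZA_LABEL_SERVINGS[label]
    if label in SINGLE_SERVING_PIZZA_LABELS:
        return 1
    if item.pizza_diameter is not None and not item.is_sharing_pizza():
        return 1
    return None


def assign_sugar_then_calorie(
    item: MenuItem, cmap: CategoryMap, assignment: Assignment
) -> Assignment:
    """Sugar rules first; calorie rules only for items with no sugar match."""
    sugar = cmap.first_match(item, Programme.SUGAR)
    if sugar is not None:
        assignment.sugar_target = sugar
        return assignment
    calorie = cmap.first_match(item, Programme.CALORIE)
    if calorie is not None:
        if item.subcategory == "Pizzas":
            servings = pizza_servings(item)
            if servings is None:
                assignment.calorie_unassignable = True
                logger.warning(
                    "%s: takeaway pizza with unknown serving count; "
                    "unassignable for calorie target",
                    item.item_id,
                )
                return assignment
            assignment.servings_for_calorie = servings
        assignment.calorie_target = calorie
    return assignment


def assign_salt(item: MenuItem, cmap: CategoryMap, assignment: Assignment) -> Assignment:
    """OOH salt targets first; RM targets for anything left uncategorised."""
    ooh = cmap.first_match(item, Programme.SALT_OOH)
    if ooh is not None:
        assignment.salt_target = ooh
        assignment.salt_sector = "ooh"
        return assignment
    rm = cmap.first_match(item, Programme.SALT_RM)
    if rm is not None:
        assignment.salt_target = rm
        assignment.salt_sector = "rm"
    return assignment


def assign_all(items: Iterable[MenuItem], cmap: CategoryMap) -> list[Assignment]:
    """Compose the assignment steps for every item."""
    out = []
    for item in items:
        a = Assignment(item=item)
        assign_sugar_then_calorie(item, cmap, a)
        assign_salt(item, cmap, a)
        out.append(a)
    return out


def state_counts(assignments: Iterable[Assignment]) -> dict[EligibilityState, int]:
    counts = {state: 0 for state in EligibilityState}
    for a in assignments:
        counts[a.eligibility_state] += 1
    return counts
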