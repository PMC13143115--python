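"""Shared fixtures: hand-built menu items, a tiny target setup, and small
seeded synthetic corpora."""

from __future__ import annotations

import pytest

from menutargets import (
    Basis,
    CategoryMap,
    CategoryRule,
    GroupMap,
    MenuItem,
    NutrientVector,
    Programme,
    RestaurantType,
    TargetSpec,
    generate,
    small_config,
)
from menutargets.model import MealClass


def make_item(
    subcategory: str = "Burgers",
    restaurant: str = "Testaurant",
    name: str = "item",
    per100g: dict | None = None,
    per_serving: dict | None = None,
    serving_size: float | None = None,
    **kwargs,
) -> MenuItem:
    item = MenuItem(
        restaurant=restaurant,
        item_name=name,
        subcategory=subcategory,
        per100g=NutrientVector(**(per100g or {})),
        per_serving=NutrientVector(**(per_serving or {})),
        serving_size=serving_size,
        **kwargs,
    )
    from menutargets.model import Provenance

    for basis in (Basis.PER100G, Basis.PER_SERVING):
        for n in item.vector(basis).present():
            item.provenance[f"{basis.value}.{n}"] = Provenance.REPORTED
    if serving_size is not None:
        item.provenance["serving_size"] = Provenance.REPORTED
    return item


@pytest.fixture
def simple_targets() -> list[TargetSpec]:
    return [
        TargetSpec("SUG1", Programme.SUGAR, "Desserts (sugar)", "sugar", Basis.PER100G, 15.0),
        TargetSpec("CAL1", Programme.CALORIE, "Main meals", "kcal", Basis.PER_SERVING, 600.0),
        TargetSpec("CAL2", Programme.CALORIE, "Salads", "kcal", Basis.PER_SERVING, 450.0),
        TargetSpec("SALT1", Programme.SALT_OOH, "Main meals (salt)", "salt", Basis.PER_SERVING, 1.8),
        TargetSpec("SALT2", Programme.SALT_RM, "Table sauces", "salt", Basis.PER100G, 1.5),
    ]


@pytest.fixture
def simple_map(simple_targets) -> CategoryMap:
    rules = [
        CategoryRule(Programme.SUGAR, "Desserts (sugar)", subcategories=frozenset({"Desserts"})),
        CategoryRule(Programme.CALORIE, "Main meals",
                     subcategories=frozenset({"Other Mains", "Burgers", "Desserts"})),
        CategoryRule(Programme.CALORIE, "Salads", subcategories=frozenset({"Salads"})),
        CategoryRule(Programme.SALT_OOH, "Main meals (salt)",
                     subcategories=frozenset({"Other Mains", "Burgers"})),
        CategoryRule(Programme.SALT_RM, "Table sauces", subcategories=frozenset({"Sauces"})),
    ]
    return CategoryMap.build(rules, simple_targets)


@pytest.fixture
def simple_groups() -> GroupMap:
    return GroupMap(
        restaurant_type={"Testaurant": RestaurantType.OTHER_MAIN},
        meal_class={s: MealClass.MAINS for s in
                    ("Burgers", "Other Mains", "Salads")} |
                   {"Sauces": MealClass.SIDES_EXTRAS, "Desserts": MealClass.DESSERTS},
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A ~150-item seeded corpus with the default missingness pattern."""
    return generate(small_config(seed=11))


@pytest.fixture(scope="session")
def small_lossless_corpus():
    """Same scale, but every masking is losslessly restorable."""
    from menutargets import lossless_config
    from dataclasses import replace

    cfg = small_config(seed=12)
    cfg.missingness = replace(cfg.missingness, serving_size_absent=0.0)
    return generate(cfg)
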