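"""Seeded generator of synthetic menu corpora with known ground truth.

The generator emulates the statistical structure a multi-restaurant menu
audit has to cope with: 21 chains of five restaurant types with distinct
subcategory profiles, log-normal per-100 g nutrient densities by
subcategory (macronutrients kept energy-consistent), heterogeneous serving
sizes, pizza serving conventions (Italian vs takeaway styles, size labels,
declared serving counts), limited-time-offer flags, and the observed
missingness patterns — roughly half of items lacking a serving size and
reporting only one nutrient basis, plus occasional kJ-only energy and
sodium-only salt.

Target tables are *constructed from the generated corpus*: each target
category's value is placed at the order statistic of the eligible items'
compared values that realises the designed met fraction, and every item's
met flag is then recomputed exactly from the complete (unmasked) panel.
Downstream adherence is therefore a sharp ground truth, not a statistical
expectation.

No attempt is made to imitate real restaurants' actual nutrient values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .assignment import CategoryMap, CategoryRule
from .model import (
    Basis,
    GroupMap,
    KJ_PER_KCAL,
    MealClass,
    MenuDataError,
    MenuItem,
    NutrientVector,
    PizzaStyle,
    Programme,
    Provenance,
    RestaurantType,
    SODIUM_MG_PER_G_SALT,
    SUBCATEGORIES,
    TargetSpec,
)

# ---------------------------------------------------------------------------
# Default corpus shape
# ---------------------------------------------------------------------------

#: Restaurant counts per type (21 chains in total).
DEFAULT_TYPE_MIX: dict[RestaurantType, int] = {
    RestaurantType.BURGER: 4,
    RestaurantType.CHICKEN: 2,
    RestaurantType.PIZZA: 4,
    RestaurantType.SANDWICH: 5,
    RestaurantType.OTHER_MAIN: 6,
}

#: Subcategory weights by restaurant type (normalised at draw time).
DEFAULT_SUBCATEGORY_PROFILES: dict[RestaurantType, dict[str, float]] = {
    RestaurantType.BURGER: {
        "Burgers": 0.35, "Chicken": 0.08, "Potato Sides": 0.12, "Other Sides": 0.05,
        "Breakfast Items": 0.12, "Desserts": 0.12, "Sauces": 0.06,
        "Children's Meals": 0.06, "Salads": 0.02, "Sandwiches": 0.02,
    },
    RestaurantType.CHICKEN: {
        "Chicken": 0.30, "Burgers": 0.12, "Sandwiches": 0.10, "Potato Sides": 0.12,
        "Other Sides": 0.08, "Desserts": 0.08, "Sauces": 0.08,
        "Children's Meals": 0.06, "Salads": 0.03, "Other Mains": 0.03,
    },
    RestaurantType.PIZZA: {
        "Pizzas": 0.50, "Other Sides": 0.12, "Potato Sides": 0.06, "Chicken": 0.08,
        "Desserts": 0.10, "Sauces": 0.06, "Salads": 0.04, "Other Mains": 0.04,
    },
    RestaurantType.SANDWICH: {
        "Sandwiches": 0.35, "Breakfast Items": 0.15, "Salads": 0.08, "Desserts": 0.18,
        "Other Sides": 0.08, "Sauces": 0.02, "Other Mains": 0.08,
        "Potato Sides": 0.03, "Children's Meals": 0.03,
    },
    RestaurantType.OTHER_MAIN: {
        "Other Mains": 0.30, "Burgers": 0.08, "Chicken": 0.08, "Sandwiches": 0.06,
        "Salads": 0.06, "Potato Sides": 0.08, "Other Sides": 0.08, "Desserts": 0.14,
        "Breakfast Items": 0.06, "Sauces": 0.06,
    },
}

#: Per-100 g density medians and log-scale sigmas: (kcal, salt g, sugar g,
#: fat g), each as (median, sigma of log).
DEFAULT_DENSITY_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "Pizzas":           {"kcal": (250, 0.15), "salt": (1.30, 0.30), "sugar": (3.5, 0.40), "fat": (9.0, 0.30)},
    "Burgers":          {"kcal": (260, 0.15), "salt": (1.10, 0.30), "sugar": (4.0, 0.40), "fat": (12.0, 0.30)},
    "Chicken":          {"kcal": (240, 0.20), "salt": (1.00, 0.30), "sugar": (1.5, 0.50), "fat": (12.0, 0.30)},
    "Other Mains":      {"kcal": (180, 0.25), "salt": (0.90, 0.35), "sugar": (4.0, 0.50), "fat": (8.0, 0.35)},
    "Children's Meals": {"kcal": (200, 0.20), "salt": (0.80, 0.30), "sugar": (4.0, 0.50), "fat": (8.0, 0.30)},
    "Salads":           {"kcal": (120, 0.30), "salt": (0.60, 0.35), "sugar": (3.0, 0.50), "fat": (7.0, 0.40)},
    "Sandwiches":       {"kcal": (230, 0.20), "salt": (1.00, 0.30), "sugar": (4.0, 0.50), "fat": (9.0, 0.35)},
    "Potato Sides":     {"kcal": (220, 0.20), "salt": (0.90, 0.40), "sugar": (1.0, 0.50), "fat": (10.0, 0.30)},
    "Other Sides":      {"kcal": (250, 0.25), "salt": (1.00, 0.40), "sugar": (3.0, 0.60), "fat": (12.0, 0.35)},
    "Breakfast Items":  {"kcal": (260, 0.25), "salt": (1.00, 0.35), "sugar": (10.0, 0.70), "fat": (11.0, 0.35)},
    "Desserts":         {"kcal": (380, 0.20), "salt": (0.35, 0.40), "sugar": (32.0, 0.30), "fat": (16.0, 0.30)},
    "Sauces":           {"kcal": (150, 0.50), "salt": (2.00, 0.40), "sugar": (8.0, 0.80), "fat": (8.0, 0.60)},
}

#: Serving-size truncated-normal parameters (mean, sd, lo, hi) in grams.
#: Pizzas are handled by the size-label machinery instead.
DEFAULT_SERVING_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "Burgers": (250, 60, 120, 450),
    "Chicken": (220, 70, 80, 450),
    "Other Mains": (400, 100, 150, 750),
    "Children's Meals": (300, 80, 120, 550),
    "Salads": (250, 80, 80, 500),
    "Sandwiches": (230, 60, 100, 420),
    "Potato Sides": (150, 50, 60, 330),
    "Other Sides": (120, 50, 30, 300),
    "Breakfast Items": (250, 80, 80, 500),
    "Desserts": (120, 40, 40, 280),
    "Sauces": (40, 15, 10, 120),
}

#: Takeaway pizza whole weights (g) and diameters (inches) by size label.
PIZZA_SIZES = {
    "small": (350.0, 9.5, 1),
    "medium": (500.0, 11.5, 2),
    "large": (700.0, 13.5, 3),
    "extra-large": (900.0, 15.5, 4),
}
PIZZA_LABEL_WEIGHTS = {"small": 0.2, "medium": 0.3, "large": 0.3, "extra-large": 0.2}

MEAL_CLASS_MAP = {
    "Pizzas": MealClass.MAINS, "Burgers": MealClass.MAINS, "Chicken": MealClass.MAINS,
    "Other Mains": MealClass.MAINS, "Children's Meals": MealClass.MAINS,
    "Salads": MealClass.MAINS, "Sandwiches": MealClass.MAINS,
    "Breakfast Items": MealClass.MAINS,
    "Potato Sides": MealClass.SIDES_EXTRAS, "Other Sides": MealClass.SIDES_EXTRAS,
    "Sauces": MealClass.SIDES_EXTRAS,
    "Desserts": MealClass.DESSERTS,
}

# Straight-line category scheme used both to build the shipped CategoryMap
# and, independently, to compute ground-truth assignments.
SUGAR_SUBCATS = {"Desserts": "Desserts (sugar)"}
SUGAR_LABELS = {"Breakfast pastries": "Breakfast pastries",
                "Dessert sauces": "Dessert sauces"}
CALORIE_SUBCATS = {
    "Pizzas": "Pizzas", "Burgers": "Burgers", "Chicken": "Chicken",
    "Other Mains": "Main meals", "Children's Meals": "Children's meals",
    "Salads": "Salads", "Sandwiches": "Sandwiches",
    "Breakfast Items": "Breakfast mains", "Potato Sides": "Chips and fries",
}
SALT_OOH_SUBCATS = {
    "Pizzas": "Pizzas (salt)", "Burgers": "Burgers (salt)", "Chicken": "Chicken (salt)",
    "Sandwiches": "Sandwiches (salt)", "Children's Meals": "Children's meals (salt)",
    "Other Mains": "Main meals (salt)", "Potato Sides": "Seasoned fries",
    "Breakfast Items": "Breakfast (salt)",
}
SALT_RM_SUBCATS = {"Sauces": "Table sauces"}


@dataclass
class Missingness:
    """Masking rates applied when emitting the observable corpus.

    Defaults mirror the observed pattern of a real scraped corpus where
    1,630 of 3,099 items (52.6%) lacked a serving size and reported only
    one nutrient basis.
    """

    serving_size_absent: float = 1630 / 3099
    per100g_only_share: float = 0.5  # among serving-absent single-basis items
    single_basis_when_serving: float = 0.5  # losslessly restorable
    kj_only: float = 0.05
    sodium_only: float = 0.05
    unusable: float = 0.0

    def validate(self) -> None:
        for name, rate in self.__dict__.items():
            if not 0.0 <= rate <= 1.0:
                raise MenuDataError(f"missingness rate {name}={rate} outside [0, 1]")


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_restaurants: int = 21
    restaurant_type_mix: dict[RestaurantType, int] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX)
    )
    items_per_restaurant: tuple[float, float, float, float] = (148, 80, 40, 330)
    subcategory_profiles: dict[RestaurantType, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUBCATEGORY_PROFILES.items()}
    )
    density_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DENSITY_PARAMS.items()}
    )
    serving_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SERVING_PARAMS)
    )
    missingness: Missingness = field(default_factory=Missingness)
    #: Designed met fractions per programme axis.
    target_adherence_design: dict[str, float] = field(
        default_factory=lambda: {"sugar": 0.36, "calorie": 0.61, "salt": 0.58}
    )
    limited_time_rate: float = 37 / 3099
    pizza_fraction_italian: float = 0.15
    breakfast_pastry_fraction: float = 0.4
    dessert_sauce_fraction: float = 0.3

    def validate(self) -> None:
        self.missingness.validate()
        if sum(self.restaurant_type_mix.values()) != self.n_restaurants:
            raise MenuDataError("restaurant_type_mix must sum to n_restaurants")
        for programme, frac in self.target_adherence_design.items():
            if not 0.0 <= frac <= 1.0:
                raise MenuDataError(
                    f"designed met fraction for {programme} must be in [0, 1], got {frac}"
                )
        for rate in (self.limited_time_rate, self.pizza_fraction_italian,
                     self.breakfast_pastry_fraction, self.dessert_sauce_fraction):
            if not 0.0 <= rate <= 1.0:
                raise MenuDataError(f"rate {rate} outside [0, 1]")


@dataclass
class GroundTruth:
    """Complete panels and exact downstream answers for a generated corpus."""

    items: list[MenuItem]  # unmasked, fully completed panels
    records: pd.DataFrame  # one row per (item, programme): eligible/compared/target/met
    lossy_rows: frozenset[int]  # rows whose masking is not losslessly restorable

    def adherence_counts(self, programme: str) -> tuple[int, int]:
        """(n_met, n_eligible) per programme axis, or all-applicable."""
        if programme == "all_applicable":
            elig = self.records[self.records.eligible]
            per_item = elig.groupby("row")["met"].all()
            return int(per_item.sum()), int(len(per_item))
        sel = self.records[(self.records.programme == programme) & self.records.eligible]
        return int(sel.met.sum()), int(len(sel))


@dataclass
class SyntheticCorpus:
    items: list[MenuItem]  # masked, observable corpus
    targets: list[TargetSpec]
    category_map: CategoryMap
    group_map: GroupMap
    truth: GroundTruth
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# Drawing helpers
# ---------------------------------------------------------------------------


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(rng.normal(0.0, sigma)))


def _macro_panel(rng: np.random.Generator, kcal: float, salt: float,
                 sugar: float, fat: float) -> NutrientVector:
    """Build a per-100 g panel whose macronutrients imply the drawn kcal to
    within 5% (kcal = 4 protein + 9 fat + 3.75 carb, up to a small
    labelling-rounding factor u in [0.97, 1.03])."""
    fat = min(fat, 0.55 * kcal / 9.0)
    u = rng.uniform(0.97, 1.03)
    energy_left = kcal * u - 9.0 * fat  # energy for protein + carbohydrate
    sugar = min(sugar, 0.85 * energy_left / 3.75)
    carb_max = energy_left / 3.75
    beta = rng.uniform(0.3, 0.9)
    carb = sugar + beta * (carb_max - sugar)
    protein = (energy_left - 3.75 * carb) / 4.0
    vec = NutrientVector(
        kcal=kcal,
        kj=kcal * KJ_PER_KCAL,
        fat=fat,
        satfat=fat * rng.uniform(0.2, 0.6),
        carb=carb,
        sugar=sugar,
        protein=protein,
        fibre=rng.uniform(0.5, 4.0),
        salt=salt,
        sodium=salt * SODIUM_MG_PER_G_SALT,
    )
    implied = 4.0 * vec.protein + 9.0 * vec.fat + 3.75 * vec.carb
    assert abs(implied - kcal) <= 0.05 * kcal + 1e-9
    return vec


def _scale_vector(per100g: NutrientVector, serving_size: float) -> NutrientVector:
    scale = serving_size / 100.0
    out = NutrientVector()
    for n in per100g.present():
        out.set(n, per100g.get(n) * scale)
    return out


def _draw_pizza(rng: np.random.Generator, cfg: SyntheticConfig, declares: bool):
    """Returns (style, label, diameter, declared, whole_weight, serving_size)."""
    if rng.uniform() < cfg.pizza_fraction_italian:
        weight = _truncnorm(rng, 550, 60, 380, 750)
        diameter = _truncnorm(rng, 12.5, 0.8, 10.5, 14.5)
        return PizzaStyle.ITALIAN, None, diameter, None, weight, weight
    labels = list(PIZZA_LABEL_WEIGHTS)
    probs = np.array([PIZZA_LABEL_WEIGHTS[l] for l in labels])
    label = labels[rng.choice(len(labels), p=probs / probs.sum())]
    base_weight, base_diam, servings = PIZZA_SIZES[label]
    weight = base_weight * rng.uniform(0.9, 1.1)
    diameter = base_diam + rng.uniform(-0.2, 0.2)
    if declares:
        return PizzaStyle.TAKEAWAY, label, diameter, servings, weight, weight / servings
    return PizzaStyle.TAKEAWAY, label, diameter, None, weight, weight


def _truth_item(rng: np.random.Generator, cfg: SyntheticConfig, row: int,
                restaurant: str, subcategory: str, pizza_declares: bool) -> MenuItem:
    dens = cfg.density_params[subcategory]
    per100g = _macro_panel(
        rng,
        kcal=_lognormal(rng, *dens["kcal"]),
        salt=_lognormal(rng, *dens["salt"]),
        sugar=_lognormal(rng, *dens["sugar"]),
        fat=_lognormal(rng, *dens["fat"]),
    )
    style = label = diameter = declared = None
    if subcategory == "Pizzas":
        style, label, diameter, declared, _whole, serving = _draw_pizza(
            rng, cfg, pizza_declares
        )
    else:
        serving = _truncnorm(rng, *cfg.serving_params[subcategory])
    target_label = None
    if subcategory == "Breakfast Items" and rng.uniform() < cfg.breakfast_pastry_fraction:
        target_label = "Breakfast pastries"
    elif subcategory == "Sauces" and rng.uniform() < cfg.dessert_sauce_fraction:
        target_label = "Dessert sauces"
    item = MenuItem(
        restaurant=restaurant,
        item_name=f"Item {row:04d}",
        subcategory=subcategory,
        limited_time=bool(rng.uniform() < cfg.limited_time_rate),
        pizza_style=style,
        pizza_size_label=label,
        pizza_diameter=round(diameter, 1) if diameter is not None else None,
        declared_servings=declared,
        per100g=per100g,
        per_serving=_scale_vector(per100g, serving),
        serving_size=serving,
        target_category_label=target_label,
        row=row,
    )
    for basis in (Basis.PER100G, Basis.PER_SERVING):
        for n in item.vector(basis).present():
            item.provenance[f"{basis.value}.{n}"] = Provenance.REPORTED
    item.provenance["serving_size"] = Provenance.REPORTED
    return item


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------


def _blank(vec: NutrientVector) -> NutrientVector:
    return NutrientVector()


def mask(item: MenuItem, missingness: Missingness, rng: np.random.Generator
         ) -> tuple[MenuItem, bool]:
    """Mask a complete item to its observable form.

    Returns ``(masked item, lossy)`` where ``lossy`` is True iff the
    masking cannot be undone exactly by the completion formulas (the
    serving size was removed together with one nutrient basis, so
    downstream completion must fall back on subcategory imputation).
    """
    out = item.copy()
    out.provenance = {}
    lossy = False
    r = rng.uniform()
    if r < missingness.unusable:
        # strip every nutrient of interest and enough macros that kcal is
        # underivable: only fat, satfat and fibre survive
        for vec in (out.per100g, out.per_serving):
            for n in ("kcal", "kj", "salt", "sodium", "sugar", "carb", "protein"):
                vec.set(n, None)
        lossy = True
    else:
        if rng.uniform() < missingness.serving_size_absent:
            out.serving_size = None
            per100g_only = rng.uniform() < missingness.per100g_only_share
            if per100g_only:
                out.per_serving = _blank(out.per_serving)
            else:
                out.per100g = _blank(out.per100g)
            lossy = True
        elif rng.uniform() < missingness.single_basis_when_serving:
            if rng.uniform() < 0.5:
                out.per_serving = _blank(out.per_serving)
            else:
                out.per100g = _blank(out.per100g)
        if rng.uniform() < missingness.kj_only:
            for vec in (out.per100g, out.per_serving):
                if vec.kj is not None:
                    vec.kcal = None
        if rng.uniform() < missingness.sodium_only:
            for vec in (out.per100g, out.per_serving):
                if vec.sodium is not None:
                    vec.salt = None
    for basis in (Basis.PER100G, Basis.PER_SERVING):
        for n in out.vector(basis).present():
            out.provenance[f"{basis.value}.{n}"] = Provenance.REPORTED
    if out.serving_size is not None:
        out.provenance["serving_size"] = Provenance.REPORTED
    return out, lossy


# ---------------------------------------------------------------------------
# Ground-truth assignment and target placement (independent straight-line
# implementations of the hierarchy, used only to construct the truth)
# ---------------------------------------------------------------------------


def _truth_servings(item: MenuItem) -> Optional[int]:
    if item.declared_servings is not None:
        return item.declared_servings
    if item.pizza_style is PizzaStyle.ITALIAN:
        return 1
    label = (item.pizza_size_label or "").lower()
    if label in PIZZA_SIZES:
        return PIZZA_SIZES[label][2] if label in ("large", "extra-large") else 1
    return None


def _truth_assignment(item: MenuItem) -> dict[str, Optional[str]]:
    """(programme axis -> category name) under the hierarchy, or None."""
    out: dict[str, Optional[str]] = {"sugar": None, "calorie": None, "salt": None}
    if item.target_category_label in SUGAR_LABELS:
        out["sugar"] = SUGAR_LABELS[item.target_category_label]
    elif item.subcategory in SUGAR_SUBCATS:
        out["sugar"] = SUGAR_SUBCATS[item.subcategory]
    elif item.subcategory in CALORIE_SUBCATS:
        out["calorie"] = CALORIE_SUBCATS[item.subcategory]
    if item.subcategory in SALT_OOH_SUBCATS:
        out["salt"] = SALT_OOH_SUBCATS[item.subcategory]
    elif item.subcategory in SALT_RM_SUBCATS:
        out["salt"] = SALT_RM_SUBCATS[item.subcategory]
    return out


def _truth_compared(item: MenuItem, programme: str) -> Optional[float]:
    if programme == "sugar":
        return item.per100g.sugar
    if programme == "calorie":
        value = item.per_serving.kcal
        if item.subcategory == "Pizzas" and item.declared_servings is None:
            servings = _truth_servings(item)
            if servings is None:
                return None
            value = value / servings
        return value
    if programme == "salt":
        # OOH salt rows are per serving, RM rows (Table sauces) per 100 g
        if item.subcategory in SALT_RM_SUBCATS:
            return item.per100g.salt
        return item.per_serving.salt
    raise MenuDataError(programme)


def _place_targets(
    truth_items: list[MenuItem], design: dict[str, float]
) -> tuple[list[TargetSpec], pd.DataFrame]:
    """Place one target value per category at the order statistic realising
    the designed met fraction, then record exact per-item met flags."""
    compared: dict[tuple[str, str], list[tuple[int, float]]] = {}
    assignments = {}
    for item in truth_items:
        a = _truth_assignment(item)
        assignments[item.row] = a
        for programme, category in a.items():
            if category is None:
                continue
            value = _truth_compared(item, programme)
            if value is None:
                continue
            compared.setdefault((programme, category), []).append((item.row, value))

    programme_of_axis = {}
    specs: list[TargetSpec] = []
    values: dict[tuple[str, str], float] = {}
    tid = 0
    for (axis, category), pairs in sorted(compared.items()):
        frac = design[axis]
        vals = sorted(v for _, v in pairs)
        k = round(frac * len(vals))
        # Place the target between the k-th and (k+1)-th order statistics:
        # exactly k items meet it, and the margin to the boundary is large
        # relative to floating-point noise from unit round-trips.
        if k == 0:
            target_value = vals[0] * 0.5
        elif k == len(vals):
            target_value = vals[-1] * 1.01
        else:
            target_value = 0.5 * (vals[k - 1] + vals[k])
        if axis == "sugar":
            programme, nutrient, basis = Programme.SUGAR, "sugar", Basis.PER100G
        elif axis == "calorie":
            programme, nutrient, basis = Programme.CALORIE, "kcal", Basis.PER_SERVING
        elif category in SALT_RM_SUBCATS.values():
            programme, nutrient, basis = Programme.SALT_RM, "salt", Basis.PER100G
        else:
            programme, nutrient, basis = Programme.SALT_OOH, "salt", Basis.PER_SERVING
        tid += 1
        specs.append(
            TargetSpec(
                target_id=f"T{tid:02d}",
                programme=programme,
                category_name=category,
                nutrient=nutrient,
                basis=basis,
                value=target_value,
            )
        )
        values[(axis, category)] = target_value
        programme_of_axis[(axis, category)] = programme

    records = []
    for item in truth_items:
        for axis, category in assignments[item.row].items():
            target = values.get((axis, category)) if category else None
            value = _truth_compared(item, axis) if category else None
            eligible = target is not None and value is not None
            records.append(
                {
                    "row": item.row,
                    "restaurant": item.restaurant,
                    "subcategory": item.subcategory,
                    "programme": axis,
                    "category": category,
                    "eligible": eligible,
                    "compared": value if eligible else np.nan,
                    "target": target if eligible else np.nan,
                    "met": bool(value <= target) if eligible else False,
                }
            )
    return specs, pd.DataFrame(records)


def build_category_map(targets: list[TargetSpec]) -> CategoryMap:
    """The rule file matching the generator's category scheme."""
    available = {(t.programme, t.category_name) for t in targets}
    rules = []
    for label, category in SUGAR_LABELS.items():
        if (Programme.SUGAR, category) in available:
            rules.append(CategoryRule(Programme.SUGAR, category, labels=frozenset({label})))
    for subcat, category in SUGAR_SUBCATS.items():
        if (Programme.SUGAR, category) in available:
            rules.append(CategoryRule(Programme.SUGAR, category, subcategories=frozenset({subcat})))
    for mapping, programme in (
        (CALORIE_SUBCATS, Programme.CALORIE),
        (SALT_OOH_SUBCATS, Programme.SALT_OOH),
        (SALT_RM_SUBCATS, Programme.SALT_RM),
    ):
        for subcat, category in mapping.items():
            if (programme, category) in available:
                rules.append(CategoryRule(programme, category, subcategories=frozenset({subcat})))
    return CategoryMap.build(rules, targets)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def generate(config: Optional[SyntheticConfig] = None) -> SyntheticCorpus:
    """Generate a full synthetic corpus: masked items, targets placed to
    realise the designed adherence, matching category/group maps, and the
    exact ground truth."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    restaurants: list[tuple[str, RestaurantType]] = []
    for rtype, count in cfg.restaurant_type_mix.items():
        for i in range(count):
            restaurants.append((f"{rtype.value} Chain {i + 1}", rtype))

    truth_items: list[MenuItem] = []
    row = 0
    for name, rtype in restaurants:
        n_items = int(round(_truncnorm(rng, *cfg.items_per_restaurant)))
        profile = cfg.subcategory_profiles[rtype]
        subcats = list(profile)
        probs = np.array([profile[s] for s in subcats], dtype=float)
        probs /= probs.sum()
        pizza_declares = bool(rng.uniform() < 0.5)  # restaurant-level convention
        draws = rng.choice(len(subcats), size=n_items, p=probs)
        for d in draws:
            row += 1
            truth_items.append(
                _truth_item(rng, cfg, row, name, subcats[d], pizza_declares)
            )

    targets, records = _place_targets(truth_items, cfg.target_adherence_design)
    cmap = build_category_map(targets)
    group_map = GroupMap(
        restaurant_type={name: rtype for name, rtype in restaurants},
        meal_class=dict(MEAL_CLASS_MAP),
    )

    masked_items = []
    lossy = set()
    for item in truth_items:
        masked, is_lossy = mask(item, cfg.missingness, rng)
        masked_items.append(masked)
        if is_lossy:
            lossy.add(item.row)

    # Guarantee the subcategory-imputation precondition: every subcategory
    # keeps at least one known serving size (n_known >= 1).  If masking
    # removed them all, restore the first item's serving size; with one
    # basis plus a serving size, that item becomes losslessly restorable.
    with_serving = {m.subcategory for m in masked_items if m.serving_size is not None}
    for masked, item in zip(masked_items, truth_items):
        if masked.subcategory in with_serving:
            continue
        masked.serving_size = item.serving_size
        masked.provenance["serving_size"] = Provenance.REPORTED
        lossy.discard(item.row)
        with_serving.add(masked.subcategory)

    truth = GroundTruth(
        items=truth_items, records=records, lossy_rows=frozenset(lossy)
    )
    return SyntheticCorpus(
        items=masked_items,
        targets=targets,
        category_map=cmap,
        group_map=group_map,
        truth=truth,
        config=cfg,
    )


def study_scale_config(seed: int = 0) -> SyntheticConfig:
    """The default study-scale configuration: 21 restaurants, ~3,000 items,
    serving-size missingness ~= 0.53."""
    return SyntheticConfig(seed=seed)


def lossless_config(seed: int = 0) -> SyntheticConfig:
    """Same corpus shape but with every masking pattern losslessly
    restorable by the completion formulas (serving sizes always present)."""
    cfg = SyntheticConfig(seed=seed)
    cfg.missingness = replace(cfg.missingness, serving_size_absent=0.0)
    return cfg


def small_config(seed: int = 0, n_per_type: int = 1, items: int = 30) -> SyntheticConfig:
    """A scaled-down corpus (5 restaurants) for fast tests."""
    cfg = SyntheticConfig(seed=seed)
    cfg.n_restaurants = 5 * n_per_type
    cfg.restaurant_type_mix = {t: n_per_type for t in RestaurantType}
    cfg.items_per_restaurant = (items, items / 5, items / 2, items * 2)
    return cfg
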