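"""Core domain types for menu-nutrition analysis.

The unit conventions follow UK food labelling practice: energy in kcal and
kJ, macronutrients and salt in grams, sodium in milligrams.  A nutrient
value may legitimately be zero (e.g. 0 g sugar in black coffee), so
"missing" is encoded as ``None`` and is never conflated with zero anywhere
in the pipeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

#: kJ per kcal (thermochemical calorie convention used on UK labels).
KJ_PER_KCAL = 4.184

#: mg sodium per g salt: sodium (mg) = salt (g) * 1000 / 2.5.
SODIUM_MG_PER_G_SALT = 400.0

#: Atwater-style factors for the macronutrient energy fallback:
#: kcal = 4*protein + 9*fat + 3.75*carbohydrate.
MACRO_KCAL_FACTORS = {"protein": 4.0, "fat": 9.0, "carb": 3.75}

#: The 12 cross-restaurant food subcategories used for grouping and
#: serving-size imputation.
SUBCATEGORIES = (
    "Pizzas",
    "Burgers",
    "Chicken",
    "Other Mains",
    "Children's Meals",
    "Salads",
    "Sandwiches",
    "Potato Sides",
    "Other Sides",
    "Breakfast Items",
    "Desserts",
    "Sauces",
)

#: Names of the optional nutrient fields carried by :class:`NutrientVector`.
NUTRIENT_FIELDS = (
    "kcal",
    "kj",
    "fat",
    "satfat",
    "carb",
    "sugar",
    "protein",
    "fibre",
    "salt",
    "sodium",
)

#: Diameter (inches) at or above which a pizza counts as a sharing pizza.
SHARING_PIZZA_MIN_DIAMETER_IN = 11.5

#: Size labels that mark a pizza as a sharing pizza irrespective of diameter.
SHARING_PIZZA_LABELS = frozenset({"large", "extra-large", "extra large", "xl"})


class Provenance(str, enum.Enum):
    """How a field value came to be on a menu item."""

    REPORTED = "reported"
    DERIVED = "derived"
    SUBCATEGORY_IMPUTED = "subcategory_imputed"


class Programme(str, enum.Enum):
    """The reduction-target programmes.

    Salt has two sectors with separate target tables: out-of-home (OOH)
    and retailer/manufacturer (RM).  OOH salt targets are tried first.
    """

    SUGAR = "sugar"
    CALORIE = "calorie"
    SALT_OOH = "salt_ooh"
    SALT_RM = "salt_rm"


class Basis(str, enum.Enum):
    PER100G = "per100g"
    PER_SERVING = "per_serving"


class ValueKind(str, enum.Enum):
    AVERAGE = "average"
    MAXIMUM = "maximum"


class RestaurantType(str, enum.Enum):
    BURGER = "Burger"
    CHICKEN = "Chicken"
    PIZZA = "Pizza"
    SANDWICH = "Sandwich"
    OTHER_MAIN = "Other Main"


class MealClass(str, enum.Enum):
    MAINS = "Mains"
    SIDES_EXTRAS = "Sides/Extras"
    DESSERTS = "Desserts"


class PizzaStyle(str, enum.Enum):
    TAKEAWAY = "takeaway"
    ITALIAN = "italian"


class EligibilityState(str, enum.Enum):
    """The four ways an item can relate to the three target programmes."""

    NONE = "none"
    ONE_PROGRAMME = "one_programme"
    SALT_AND_CALORIE = "salt_and_calorie"
    SALT_AND_SUGAR = "salt_and_sugar"


class MenuDataError(ValueError):
    """Raised on invalid menu data, target tables or configuration."""


@dataclass
class NutrientVector:
    """Optional named nutrient quantities on a single basis.

    Every field is optional; ``None`` means "not reported", which is
    distinct from an explicit zero.  Masses are grams except ``sodium``
    (milligrams); energy is ``kcal`` / ``kj``.
    """

    kcal: Optional[float] = None
    kj: Optional[float] = None
    fat: Optional[float] = None
    satfat: Optional[float] = None
    carb: Optional[float] = None
    sugar: Optional[float] = None
    protein: Optional[float] = None
    fibre: Optional[float] = None
    salt: Optional[float] = None
    sodium: Optional[float] = None

    def get(self, nutrient: str) -> Optional[float]:
        return getattr(self, nutrient)

    def set(self, nutrient: str, value: float) -> None:
        setattr(self, nutrient, value)

    def present(self) -> Iterator[str]:
        for f in NUTRIENT_FIELDS:
            if getattr(self, f) is not None:
                yield f

    def is_empty(self) -> bool:
        return next(self.present(), None) is None

    def copy(self) -> "NutrientVector":
        return replace(self)

    def validate(self, where: str = "") -> None:
        """Check non-negativity and the unit-pair identities.

        The pair identities (kJ = 4.184 kcal, sodium = 400 * salt) are only
        enforced to a relative tolerance of 1e-6 and only when both members
        are present, i.e. after completion has run.
        """
        for f in NUTRIENT_FIELDS:
            v = getattr(self, f)
            if v is not None and v < 0:
                raise MenuDataError(f"negative {f} value {v!r} {where}".strip())
        if self.kcal is not None and self.kj is not None and self.kcal > 0:
            if abs(self.kj - self.kcal * KJ_PER_KCAL) > 1e-6 * self.kj:
                raise MenuDataError(
                    f"kJ/kcal pair inconsistent ({self.kj} vs {self.kcal}) {where}".strip()
                )
        if self.salt is not None and self.sodium is not None and self.salt > 0:
            if abs(self.sodium - self.salt * SODIUM_MG_PER_G_SALT) > 1e-6 * self.sodium:
                raise MenuDataError(
                    f"sodium/salt pair inconsistent ({self.sodium} vs {self.salt}) {where}".strip()
                )


@dataclass
class MenuItem:
    """One menu item row with nutrient panels on both bases.

    ``provenance`` maps a field key — ``"per100g.<nutrient>"``,
    ``"per_serving.<nutrient>"`` or ``"serving_size"`` — to how that value
    was obtained.  Values whose provenance is ``reported`` are never
    overwritten by the completion engine.

    Pizza conventions: ``per_serving`` holds nutrient content per reported
    serving under the restaurant's own convention.  When
    ``declared_servings`` is present the reported serving is a single
    person's share; otherwise it is the whole pizza and the calorie target
    is applied after dividing by the assumed serving count.
    """

    restaurant: str
    item_name: str
    subcategory: str
    limited_time: bool = False
    pizza_style: Optional[PizzaStyle] = None
    pizza_size_label: Optional[str] = None
    pizza_diameter: Optional[float] = None
    declared_servings: Optional[int] = None
    per100g: NutrientVector = field(default_factory=NutrientVector)
    per_serving: NutrientVector = field(default_factory=NutrientVector)
    serving_size: Optional[float] = None
    target_category_label: Optional[str] = None
    provenance: dict[str, Provenance] = field(default_factory=dict)
    row: Optional[int] = None

    def __post_init__(self) -> None:
        if self.subcategory not in SUBCATEGORIES:
            where = f"(row {self.row})" if self.row is not None else ""
            raise MenuDataError(
                f"unknown subcategory {self.subcategory!r} {where}".strip()
            )
        if self.serving_size is not None and self.serving_size <= 0:
            raise MenuDataError(
                f"serving_size must be positive, got {self.serving_size}"
            )

    @property
    def item_id(self) -> str:
        return f"{self.restaurant}::{self.item_name}"

    def vector(self, basis: Basis) -> NutrientVector:
        return self.per100g if basis is Basis.PER100G else self.per_serving

    def prov(self, key: str) -> Optional[Provenance]:
        return self.provenance.get(key)

    def set_value(
        self, basis: Basis, nutrient: str, value: float, provenance: Provenance
    ) -> None:
        self.vector(basis).set(nutrient, value)
        self.provenance[f"{basis.value}.{nutrient}"] = provenance

    def copy(self) -> "MenuItem":
        return replace(
            self,
            per100g=self.per100g.copy(),
            per_serving=self.per_serving.copy(),
            provenance=dict(self.provenance),
        )

    def is_sharing_pizza(self) -> bool:
        """Sharing pizza: size label large-or-above, or diameter >= 11.5 in."""
        if self.subcategory != "Pizzas":
            return False
        if self.pizza_size_label is not None:
            if self.pizza_size_label.strip().lower() in SHARING_PIZZA_LABELS:
                return True
        if self.pizza_diameter is not None:
            return self.pizza_diameter >= SHARING_PIZZA_MIN_DIAMETER_IN
        return False


@dataclass(frozen=True)
class TargetSpec:
    """One reduction-target row.

    The programme constrains nutrient and basis: sugar targets are sugar
    per 100 g, calorie targets kcal per serving; salt targets are salt on
    whichever basis the target table states (OOH rows are typically per
    serving, RM rows per 100 g).
    """

    target_id: str
    programme: Programme
    category_name: str
    nutrient: str
    basis: Basis
    value: float
    value_kind: ValueKind = ValueKind.AVERAGE

    def __post_init__(self) -> None:
        if self.value is None or self.value <= 0:
            raise MenuDataError(
                f"target {self.target_id!r}: value must be positive, got {self.value}"
            )
        if self.programme is Programme.SUGAR:
            if self.nutrient != "sugar" or self.basis is not Basis.PER100G:
                raise MenuDataError(
                    f"target {self.target_id!r}: sugar targets are sugar per 100 g"
                )
        elif self.programme is Programme.CALORIE:
            if self.nutrient != "kcal" or self.basis is not Basis.PER_SERVING:
                raise MenuDataError(
                    f"target {self.target_id!r}: calorie targets are kcal per serving"
                )
        elif self.nutrient != "salt":
            raise MenuDataError(
                f"target {self.target_id!r}: salt-programme targets must use salt"
            )


@dataclass
class GroupMap:
    """Restaurant -> restaurant type and subcategory -> meal class mappings."""

    restaurant_type: dict[str, RestaurantType]
    meal_class: dict[str, MealClass] = field(default_factory=dict)

    def validate_coverage(self, items: list["MenuItem"]) -> None:
        missing_r = sorted(
            {i.restaurant for i in items} - set(self.restaurant_type)
        )
        if missing_r:
            raise MenuDataError(f"restaurants missing from group map: {missing_r}")
        if self.meal_class:
            missing_s = sorted(
                {i.subcategory for i in items} - set(self.meal_class)
            )
            if missing_s:
                raise MenuDataError(
                    f"subcategories missing from meal-class map: {missing_s}"
                )
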