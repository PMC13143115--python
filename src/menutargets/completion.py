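"""Deterministic completion of missing nutrient fields and serving sizes.

The completion rules, in the order the pipeline applies them:

1. *Exclusion*: an item is unusable iff kcal, salt and sugar are all
   missing on both bases and none is derivable (kJ makes kcal derivable,
   sodium makes salt derivable, and a full macro panel makes kcal
   derivable via the Atwater-style factors).
2. *Unit conversions* on each basis: ``kcal = kJ / 4.184`` (and vice
   versa); ``sodium (mg) = salt (g) * 1000 / 2.5`` (and vice versa); the
   macronutrient fallback ``kcal = 4*protein + 9*fat + 3.75*carb`` applies
   only when the kJ conversion cannot.
3. *Basis scaling* with the serving size S (g):
   ``per100g = per_serving / (S/100)``, ``per_serving = (S/100) * per100g``,
   and ``S = 100 * per_serving / per100g`` when S itself is missing but
   some nutrient is reported on both bases.
4. *Subcategory fallback*: items still lacking a serving size get the
   subcategory mean (or, for sensitivity runs, lower/upper quartile) of
   serving sizes that were reported or derived — never of ones that were
   themselves imputed — after which basis scaling re-runs for those items.

Unit conversions run before basis scaling so that, e.g., a kJ-only item
can still seed serving-size derivation.  Reported values are never
overwritten; everything filled in is tagged ``derived`` or
``subcategory_imputed`` in the item's provenance map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np

from .model import (
    Basis,
    KJ_PER_KCAL,
    MACRO_KCAL_FACTORS,
    MenuDataError,
    MenuItem,
    NutrientVector,
    Provenance,
)

logger = logging.getLogger(__name__)

#: Priority order of nutrients used to derive a missing serving size from a
#: nutrient reported on both bases.  kcal first: it is the most
#: consistently reported field.
SERVING_DERIVATION_PRIORITY = ("kcal", "salt", "sugar", "carb", "fat", "protein")

#: Relative discrepancy between bases above which a warning is logged.
CROSS_BASIS_WARN_TOL = 0.05

Strategy = Literal["mean", "lq", "uq"]


@dataclass
class ServingStats:
    """Serving-size summary for one subcategory, over items whose serving
    size was reported or derived (never imputed)."""

    subcategory: str
    n_known: int
    mean: float
    median: float
    lq: float
    uq: float

    def by_strategy(self, strategy: Strategy) -> float:
        return {"mean": self.mean, "lq": self.lq, "uq": self.uq}[strategy]


@dataclass
class CompletionReport:
    """Audit trail of everything the completion engine did."""

    excluded: list[tuple[str, str]] = field(default_factory=list)
    filled: list[tuple[str, str, str]] = field(default_factory=list)  # (item, field, rule)
    warnings: list[str] = field(default_factory=list)
    serving_size_imputed: list[str] = field(default_factory=list)

    @property
    def n_excluded_all_missing(self) -> int:
        return sum(1 for _, reason in self.excluded if reason == "all_nutrients_missing")

    @property
    def n_serving_size_imputed(self) -> int:
        return len(self.serving_size_imputed)

    def record_fill(self, item: MenuItem, key: str, rule: str) -> None:
        self.filled.append((item.item_id, key, rule))


def _kcal_derivable(item: MenuItem) -> bool:
    for vec in (item.per100g, item.per_serving):
        if vec.kcal is not None or vec.kj is not None:
            return True
        if all(vec.get(m) is not None for m in MACRO_KCAL_FACTORS):
            return True
    return False


def _salt_derivable(item: MenuItem) -> bool:
    return any(
        vec.salt is not None or vec.sodium is not None
        for vec in (item.per100g, item.per_serving)
    )


def _sugar_present(item: MenuItem) -> bool:
    return any(vec.sugar is not None for vec in (item.per100g, item.per_serving))


def exclude_unusable(
    items: Iterable[MenuItem], report: Optional[CompletionReport] = None
) -> tuple[list[MenuItem], CompletionReport]:
    """Drop items for which kcal, salt and sugar are all missing and
    underivable by any completion formula."""
    report = report or CompletionReport()
    kept = []
    for item in items:
        if _kcal_derivable(item) or _salt_derivable(item) or _sugar_present(item):
            kept.append(item)
        else:
            report.excluded.append((item.item_id, "all_nutrients_missing"))
    return kept, report


def complete_energy(
    vector: NutrientVector,
    report: Optional[CompletionReport] = None,
    item: Optional[MenuItem] = None,
    basis: Optional[Basis] = None,
) -> NutrientVector:
    """Fill missing kcal/kJ by unit conversion, else kcal from macros.

    The macro rule is strictly a fallback: it applies only when both kcal
    and kJ are missing.  No reported value is ever overwritten.
    """

    def note(key: str, rule: str) -> None:
        if report is not None and item is not None and basis is not None:
            report.record_fill(item, f"{basis.value}.{key}", rule)
            item.provenance[f"{basis.value}.{key}"] = Provenance.DERIVED

    if vector.kcal is None and vector.kj is not None:
        vector.kcal = vector.kj / KJ_PER_KCAL
        note("kcal", "kcal=kJ/4.184")
    elif vector.kj is None and vector.kcal is not None:
        vector.kj = vector.kcal * KJ_PER_KCAL
        note("kj", "kJ=kcal*4.184")
    elif vector.kcal is None and vector.kj is None:
        if all(vector.get(m) is not None for m in MACRO_KCAL_FACTORS):
            vector.kcal = sum(
                factor * vector.get(m) for m, factor in MACRO_KCAL_FACTORS.items()
            )
            note("kcal", "kcal=4p+9f+3.75c")
            vector.kj = vector.kcal * KJ_PER_KCAL
            note("kj", "kJ=kcal*4.184")
    return vector


def complete_salt_sodium(
    vector: NutrientVector,
    report: Optional[CompletionReport] = None,
    item: Optional[MenuItem] = None,
    basis: Optional[Basis] = None,
) -> NutrientVector:
    """Fill the missing member of the salt/sodium pair from the other."""

    def note(key: str, rule: str) -> None:
        if report is not None and item is not None and basis is not None:
            report.record_fill(item, f"{basis.value}.{key}", rule)
            item.provenance[f"{basis.value}.{key}"] = Provenance.DERIVED

    if vector.sodium is None and vector.salt is not None:
        vector.sodium = vector.salt * 1000.0 / 2.5
        note("sodium", "sodium=salt*1000/2.5")
    elif vector.salt is None and vector.sodium is not None:
        vector.salt = vector.sodium * 2.5 / 1000.0
        note("salt", "salt=sodium*2.5/1000")
    return vector


def complete_units(item: MenuItem, report: Optional[CompletionReport] = None) -> MenuItem:
    """Apply energy and salt/sodium unit conversions on both bases."""
    for basis in (Basis.PER100G, Basis.PER_SERVING):
        complete_energy(item.vector(basis), report, item, basis)
        complete_salt_sodium(item.vector(basis), report, item, basis)
    return item


def _derive_serving_size(item: MenuItem, report: CompletionReport) -> None:
    for nutrient in SERVING_DERIVATION_PRIORITY:
        p100 = item.per100g.get(nutrient)
        pserv = item.per_serving.get(nutrient)
        if p100 is not None and pserv is not None and p100 > 0:
            size = (100.0 / p100) * pserv
            if size <= 0:
                item.provenance["invalid"] = Provenance.DERIVED
                report.excluded.append((item.item_id, "nonpositive_derived_serving_size"))
                return
            item.serving_size = size
            item.provenance["serving_size"] = Provenance.DERIVED
            report.record_fill(item, "serving_size", f"S=100*serv/100g[{nutrient}]")
            return


def _check_cross_basis(item: MenuItem, report: CompletionReport) -> None:
    if item.serving_size is None:
        return
    scale = item.serving_size / 100.0
    for nutrient in SERVING_DERIVATION_PRIORITY:
        p100 = item.per100g.get(nutrient)
        pserv = item.per_serving.get(nutrient)
        if p100 is not None and pserv is not None and p100 > 0:
            expected = p100 * scale
            if abs(pserv - expected) > CROSS_BASIS_WARN_TOL * max(expected, 1e-12):
                msg = (
                    f"{item.item_id}: {nutrient} disagrees across bases by >"
                    f"{CROSS_BASIS_WARN_TOL:.0%} (per-serving {pserv} vs "
                    f"{expected} implied); reported values kept"
                )
                report.warnings.append(msg)
                logger.warning(msg)


def complete_basis(item: MenuItem, report: Optional[CompletionReport] = None) -> MenuItem:
    """Derive a missing serving size, then scale nutrients across bases.

    Assumes :func:`complete_units` has already run on both bases.  Items
    whose derived serving size is non-positive are flagged ``invalid`` in
    provenance and reported for exclusion.
    """
    report = report if report is not None else CompletionReport()
    if item.serving_size is None:
        _derive_serving_size(item, report)
    _check_cross_basis(item, report)
    if item.serving_size is None or item.provenance.get("invalid"):
        return item
    scale = item.serving_size / 100.0
    for nutrient in item.per100g.__dataclass_fields__:
        p100 = item.per100g.get(nutrient)
        pserv = item.per_serving.get(nutrient)
        if p100 is not None and pserv is None:
            item.set_value(Basis.PER_SERVING, nutrient, p100 * scale, Provenance.DERIVED)
            report.record_fill(item, f"per_serving.{nutrient}", "serv=(S/100)*100g")
        elif pserv is not None and p100 is None:
            item.set_value(Basis.PER100G, nutrient, pserv / scale, Provenance.DERIVED)
            report.record_fill(item, f"per100g.{nutrient}", "100g=serv/(S/100)")
    return item


def serving_stats(
    items: Iterable[MenuItem], subcategory: Optional[str] = None
) -> dict[str, ServingStats]:
    """Serving-size mean/median/quartiles per subcategory.

    Only serving sizes whose provenance is ``reported`` or ``derived``
    contribute — imputed ones are excluded so imputation has no feedback
    loop.  Quartiles use linear interpolation between order statistics.
    """
    by_subcat: dict[str, list[float]] = {}
    for item in items:
        if item.serving_size is None:
            continue
        if item.prov("serving_size") is Provenance.SUBCATEGORY_IMPUTED:
            continue
        by_subcat.setdefault(item.subcategory, []).append(item.serving_size)
    out = {}
    for subcat, sizes in by_subcat.items():
        arr = np.asarray(sizes, dtype=float)
        out[subcat] = ServingStats(
            subcategory=subcat,
            n_known=len(sizes),
            mean=float(arr.mean()),
            median=float(np.median(arr)),
            lq=float(np.quantile(arr, 0.25, method="linear")),
            uq=float(np.quantile(arr, 0.75, method="linear")),
        )
    if subcategory is not None:
        if subcategory not in out:
            raise MenuDataError(
                f"no reported or derived serving sizes in subcategory {subcategory!r}"
            )
        return {subcategory: out[subcategory]}
    return out


def impute_serving_size(
    items: Iterable[MenuItem],
    stats: dict[str, ServingStats],
    strategy: Strategy = "mean",
    report: Optional[CompletionReport] = None,
) -> list[MenuItem]:
    """Give items still lacking a serving size their subcategory statistic,
    then re-run basis scaling for exactly those items."""
    report = report if report is not None else CompletionReport()
    out = []
    for item in items:
        if item.serving_size is None and not item.provenance.get("invalid"):
            st = stats.get(item.subcategory)
            if st is None:
                raise MenuDataError(
                    f"no serving stats for subcategory {item.subcategory!r} "
                    f"needed by {item.item_id}"
                )
            item.serving_size = st.by_strategy(strategy)
            item.provenance["serving_size"] = Provenance.SUBCATEGORY_IMPUTED
            report.serving_size_imputed.append(item.item_id)
            report.record_fill(item, "serving_size", f"subcategory_{strategy}")
            complete_basis(item, report)
        out.append(item)
    return out


def complete_corpus(
    items: Iterable[MenuItem],
    strategy: Strategy = "mean",
    precomputed_stats: Optional[dict[str, ServingStats]] = None,
) -> tuple[list[MenuItem], dict[str, ServingStats], CompletionReport]:
    """Run the full completion pipeline on copies of the input items.

    Returns the completed items (unusable and invalid ones dropped), the
    serving-size statistics actually used, and the audit report.  The
    pipeline is idempotent: re-running it on its own output is a no-op.
    """
    report = CompletionReport()
    items = [item.copy() for item in items]
    kept, report = exclude_unusable(items, report)
    for item in kept:
        complete_units(item, report)
        complete_basis(item, report)
    kept = [i for i in kept if not i.provenance.get("invalid")]
    stats = precomputed_stats if precomputed_stats is not None else serving_stats(kept)
    kept = impute_serving_size(kept, stats, strategy, report)
    return kept, stats, report


def report_frame(report: CompletionReport):
    """Completion audit as a table: item, field, rule applied."""
    import pandas as pd

    rows = [
        {"item_id": item_id, "field": fld, "rule": rule}
        for item_id, fld, rule in report.filled
    ] + [
        {"item_id": item_id, "field": "", "rule": f"excluded:{reason}"}
        for item_id, reason in report.excluded
    ]
    return pd.DataFrame(rows, columns=["item_id", "field", "rule"])
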