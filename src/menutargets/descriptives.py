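"""Grouped nutrient summaries on three serving bases.

Bases:

* ``per100g`` — nutrient content per 100 g;
* ``reported_serving`` — per the item's own serving (reported by the
  restaurant, or derived/imputed by the completion engine; for pizzas this
  is the restaurant's own serving convention);
* ``subcat_avg_serving`` — per the subcategory's average serving size,
  recomputed for *every* item as ``per100g * mean_serving / 100`` so the
  whole subcategory is standardised to one portion size.

The standard deviation is the sample SD (n-1 denominator), reported as 0
for single-item groups.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .completion import ServingStats
from .model import GroupMap, MenuDataError, MenuItem

logger = logging.getLogger(__name__)

SUMMARY_NUTRIENTS = ("kcal", "salt", "sugar", "fat")
SUMMARY_BASES = ("per100g", "reported_serving", "subcat_avg_serving")
Grouping = Literal["overall", "restaurant", "subcategory", "restaurant_type"]


def item_value(
    item: MenuItem,
    nutrient: str,
    basis: str,
    stats: Optional[dict[str, ServingStats]] = None,
) -> Optional[float]:
    """The item's value for one nutrient on one summary basis, or ``None``
    when it cannot be computed."""
    if basis == "per100g":
        return item.per100g.get(nutrient)
    if basis == "reported_serving":
        return item.per_serving.get(nutrient)
    if basis == "subcat_avg_serving":
        if stats is None or item.subcategory not in stats:
            return None
        p100 = item.per100g.get(nutrient)
        if p100 is None:
            return None
        return p100 * stats[item.subcategory].mean / 100.0
    raise MenuDataError(f"unknown basis {basis!r}")


def _label(item: MenuItem, grouping: Grouping, groups: GroupMap) -> str:
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


def _collect(
    items: Iterable[MenuItem],
    grouping: Grouping,
    nutrient: str,
    basis: str,
    groups: GroupMap,
    stats: Optional[dict[str, ServingStats]],
) -> dict[str, list[float]]:
    values: dict[str, list[float]] = {}
    n_skipped = 0
    for item in items:
        v = item_value(item, nutrient, basis, stats)
        if v is None:
            n_skipped += 1
            continue
        values.setdefault(_label(item, grouping, groups), []).append(v)
    if n_skipped:
        logger.info(
            "%d items missing %s on basis %s excluded from %s summary",
            n_skipped, nutrient, basis, grouping,
        )
    for vals in values.values():
        vals.sort()  # statistics become invariant to input row order
    return values


def summarize(
    items: Iterable[MenuItem],
    grouping: Grouping = "overall",
    nutrients: Iterable[str] = SUMMARY_NUTRIENTS,
    bases: Iterable[str] = SUMMARY_BASES,
    groups: Optional[GroupMap] = None,
    stats: Optional[dict[str, ServingStats]] = None,
) -> pd.DataFrame:
    """Mean/median/SD per (group, nutrient, basis).

    Items missing the nutrient on a basis are excluded from that row's n.
    """
    items = list(items)
    groups = groups or GroupMap(restaurant_type={})
    rows = []
    for nutrient in nutrients:
        for basis in bases:
            for label, vals in sorted(
                _collect(items, grouping, nutrient, basis, groups, stats).items()
            ):
                arr = np.asarray(vals, dtype=float)
                sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
                rows.append(
                    {
                        "grouping": grouping,
                        "label": label,
                        "nutrient": nutrient,
                        "basis": basis,
                        "n": len(arr),
                        "mean": float(arr.mean()),
                        "median": float(np.median(arr)),
                        "sd": sd,
                    }
                )
    return pd.DataFrame(
        rows, columns=["grouping", "label", "nutrient", "basis", "n", "mean", "median", "sd"]
    )


def distribution_export(
    items: Iterable[MenuItem],
    grouping: Grouping = "overall",
    nutrients: Iterable[str] = SUMMARY_NUTRIENTS,
    bases: Iterable[str] = ("per100g", "reported_serving"),
    groups: Optional[GroupMap] = None,
    stats: Optional[dict[str, ServingStats]] = None,
) -> pd.DataFrame:
    """Five-number summaries (min, LQ, median, UQ, max) per group —
    sufficient to draw box plots with whiskers at the range.

    Quartiles use the same linear-interpolation rule as serving-size
    statistics.
    """
    items = list(items)
    groups = groups or GroupMap(restaurant_type={})
    rows = []
    for nutrient in nutrients:
        for basis in bases:
            for label, vals in sorted(
                _collect(items, grouping, nutrient, basis, groups, stats).items()
            ):
                arr = np.asarray(vals, dtype=float)
                rows.append(
                    {
                        "grouping": grouping,
                        "label": label,
                        "nutrient": nutrient,
                        "basis": basis,
                        "n": len(arr),
                        "min": float(arr.min()),
                        "lq": float(np.quantile(arr, 0.25, method="linear")),
                        "median": float(np.median(arr)),
                        "uq": float(np.quantile(arr, 0.75, method="linear")),
                        "max": float(arr.max()),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["grouping", "label", "nutrient", "basis", "n", "min", "lq", "median", "uq", "max"],
    )


def pivot_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot a summary into group rows x (basis, statistic) columns, one
    table per nutrient stacked — the supplementary-table layout."""
    wide = summary.pivot_table(
        index=["nutrient", "grouping", "label"],
        columns="basis",
        values=["n", "mean", "median", "sd"],
        sort=False,
    )
    wide.columns = [f"{stat}_{basis}" for stat, basis in wide.columns]
    return wide.reset_index()


def _check_weighted_mean(summary_overall: pd.DataFrame, summary_group: pd.DataFrame) -> bool:
    """Overall mean equals the n-weighted mean of group means (used by the
    invariant test-suite; tolerance covers float accumulation only)."""
    for _, row in summary_overall.iterrows():
        grp = summary_group[
            (summary_group.nutrient == row.nutrient) & (summary_group.basis == row.basis)
        ]
        if grp.empty:
            continue
        weighted = (grp["mean"] * grp["n"]).sum() / grp["n"].sum()
        if not math.isclose(weighted, row["mean"], rel_tol=1e-9, abs_tol=1e-12):
            return False
    return True
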