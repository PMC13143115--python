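"""Sensitivity analyses: re-run the full pipeline under one perturbation
and diff the results against the primary run.

Two perturbation families are supported:

* ``exclude_lto`` — drop limited-time-offer items before analysis;
* ``serving_lq`` / ``serving_uq`` — impute missing serving sizes with the
  subcategory lower/upper quartile instead of the mean.  These runs reuse
  the primary run's serving-size statistics (computed from reported and
  derived sizes before any imputation), so the perturbation is confined to
  the imputation step itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .assignment import CategoryMap
from .model import GroupMap, MenuDataError, MenuItem
from .pipeline import PipelineResult, run_pipeline

SENSITIVITY_SPECS = {
    "exclude_lto": "limited-time offer items excluded before analysis",
    "serving_lq": "missing serving sizes imputed with subcategory lower quartile",
    "serving_uq": "missing serving sizes imputed with subcategory upper quartile",
}


@dataclass
class SensitivityResult:
    name: str
    primary: PipelineResult
    perturbed: PipelineResult
    nutrient_diff: pd.DataFrame
    adherence_diff: pd.DataFrame


def _nutrient_diff(primary: PipelineResult, perturbed: PipelineResult) -> pd.DataFrame:
    """Per (nutrient, basis): primary vs sensitivity overall mean and delta."""
    a = primary.summary_tables["overall"][["nutrient", "basis", "mean"]]
    b = perturbed.summary_tables["overall"][["nutrient", "basis", "mean"]]
    merged = a.merge(b, on=["nutrient", "basis"], suffixes=("_primary", "_sensitivity"))
    merged["delta"] = merged["mean_sensitivity"] - merged["mean_primary"]
    return merged


def _adherence_diff(primary: PipelineResult, perturbed: PipelineResult) -> pd.DataFrame:
    cols = ["programme", "n_eligible", "n_met", "percent_met"]
    a = primary.adherence_tables["overall"][cols]
    b = perturbed.adherence_tables["overall"][cols]
    merged = a.merge(b, on="programme", suffixes=("_primary", "_sensitivity"))
    merged["delta_percent"] = (
        merged["percent_met_sensitivity"] - merged["percent_met_primary"]
    )
    return merged


def run_sensitivity(
    items: Iterable[MenuItem],
    name: str,
    cmap: CategoryMap,
    groups: GroupMap,
    primary: PipelineResult,
) -> SensitivityResult:
    """Re-run the pipeline under one named perturbation and diff overall
    nutrient means and adherence against the primary run."""
    if name not in SENSITIVITY_SPECS:
        raise MenuDataError(
            f"unknown sensitivity spec {name!r}; choose from {sorted(SENSITIVITY_SPECS)}"
        )
    if name == "exclude_lto":
        perturbed = run_pipeline(items, cmap, groups, strategy="mean", exclude_lto=True)
    else:
        strategy = "lq" if name == "serving_lq" else "uq"
        perturbed = run_pipeline(
            items, cmap, groups, strategy=strategy, precomputed_stats=primary.stats
        )
    return SensitivityResult(
        name=name,
        primary=primary,
        perturbed=perturbed,
        nutrient_diff=_nutrient_diff(primary, perturbed),
        adherence_diff=_adherence_diff(primary, perturbed),
    )


def strategy_comparison(results: dict[str, "SensitivityResult"]) -> pd.DataFrame:
    """Three-strategy comparison table: one row per overall metric, one
    column per serving-size imputation strategy (mean / LQ / UQ)."""
    primary = next(iter(results.values())).primary
    frames = {"using_average": primary}
    if "serving_lq" in results:
        frames["using_lower_quartile"] = results["serving_lq"].perturbed
    if "serving_uq" in results:
        frames["using_upper_quartile"] = results["serving_uq"].perturbed
    rows = []
    for nutrient in ("kcal", "salt", "sugar"):
        for basis in ("per100g", "reported_serving"):
            row = {"metric": f"{nutrient} {basis}"}
            for col, res in frames.items():
                row[col] = res.overall_mean(nutrient, basis)
            rows.append(row)
    for programme in ("calorie", "salt", "sugar", "all_applicable"):
        row = {"metric": f"{programme} adherence %"}
        for col, res in frames.items():
            n_met, n_elig = res.overall_adherence()[programme]
            row[col] = round(100.0 * n_met / n_elig) if n_elig else None
        rows.append(row)
    return pd.DataFrame(rows)
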