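"""End-to-end orchestration: exclude -> complete -> assign -> adhere ->
summarise, with all result tables collected in one bundle."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from . import adherence, descriptives
from .assignment import Assignment, CategoryMap, assign_all, state_counts
from .completion import (
    CompletionReport,
    ServingStats,
    Strategy,
    complete_corpus,
    report_frame,
)
from .model import GroupMap, MenuItem

logger = logging.getLogger(__name__)

GROUPINGS = ("overall", "restaurant", "subcategory", "restaurant_type")


@dataclass
class PipelineResult:
    """Everything one analysis run produces."""

    items: list[MenuItem]
    stats: dict[str, ServingStats]
    report: CompletionReport
    assignments: list[Assignment]
    records: list[adherence.AdherenceRecord]
    adherence_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    distribution_tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        out: dict[str, pd.DataFrame] = {}
        out.update({f"adherence_{k}": v for k, v in self.adherence_tables.items()})
        out.update({f"nutrients_{k}": v for k, v in self.summary_tables.items()})
        out.update({f"distribution_{k}": v for k, v in self.distribution_tables.items()})
        out["completion_audit"] = report_frame(self.report)
        return out

    def overall_adherence(self) -> dict[str, tuple[int, int]]:
        """(n_met, n_eligible) per programme axis, overall."""
        df = self.adherence_tables["overall"]
        return {
            row.programme: (int(row.n_met), int(row.n_eligible))
            for row in df.itertuples()
        }

    def overall_mean(self, nutrient: str, basis: str) -> float:
        df = self.summary_tables["overall"]
        sel = df[(df.nutrient == nutrient) & (df.basis == basis)]
        return float(sel["mean"].iloc[0])


def run_pipeline(
    items: Iterable[MenuItem],
    cmap: CategoryMap,
    groups: GroupMap,
    strategy: Strategy = "mean",
    exclude_lto: bool = False,
    precomputed_stats: Optional[dict[str, ServingStats]] = None,
) -> PipelineResult:
    """Run the full analysis on (copies of) the input items."""
    items = list(items)
    if exclude_lto:
        n_before = len(items)
        items = [i for i in items if not i.limited_time]
        logger.info("excluded %d limited-time offer items", n_before - len(items))
    completed, stats, report = complete_corpus(
        items, strategy=strategy, precomputed_stats=precomputed_stats
    )
    logger.info(
        "completion: %d kept, %d excluded, %d serving sizes imputed",
        len(completed), len(report.excluded), report.n_serving_size_imputed,
    )
    assignments = assign_all(completed, cmap)
    logger.info("eligibility states: %s",
                {k.value: v for k, v in state_counts(assignments).items()})
    records = [adherence.evaluate_item(a.item, a) for a in assignments]

    result = PipelineResult(
        items=completed, stats=stats, report=report,
        assignments=assignments, records=records,
    )
    for grouping in GROUPINGS:
        summaries = adherence.aggregate(records, grouping, groups)
        result.adherence_tables[grouping] = adherence.summary_frame(summaries)
        result.summary_tables[grouping] = descriptives.summarize(
            completed, grouping, groups=groups, stats=stats
        )
        result.distribution_tables[grouping] = descriptives.distribution_export(
            completed, grouping, groups=groups, stats=stats
        )
    return result
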