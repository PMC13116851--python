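"""Sparsity sweep bookkeeping: FLOPs accounting, Pareto frontier, selection.

A sweep trains one gated model per sparsity weight lambda and records, for
each, the retained view set, its deterministic-mask Top-1 accuracy, and its
theoretical cost.  Cost is linear in the number of encoded views — dropped
views are never encoded — so a configuration's FLOPs is
``view_count x per-view cost``, with the per-view cost either measured from
the encoder or derived as ``baseline_flops / n_views``.

The *recommended* configuration minimises the view count subject to the
accuracy staying within a margin (1 percentage point by default) of the
all-view baseline; it always lies on the accuracy-vs-FLOPs Pareto frontier
of the qualifying records.  Table cells are rounded to 2 decimals half-up,
and derived columns (drop, saved %) are computed from the rounded cells so
the printed table is internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .training import round2

__all__ = [
    "SweepRecord",
    "ParetoTable",
    "TABLE_COLUMNS",
    "flops_total",
    "flops_saved_pct",
    "accuracy_drop",
    "pareto_frontier",
    "select_recommended",
    "label_configurations",
    "run_sweep",
    "table_to_dataframe",
    "table_from_dataframe",
]

TABLE_COLUMNS = ["λ", "Number of Parts", "Accuracy (%)", "Accuracy Drop (%)",
                 "FLOPs (G)", "FLOPs Saved (%)", "Configuration"]

LABELS = ("all-view", "reduced", "recommended", "aggressive", "single-view")


@dataclass
class SweepRecord:
    """One (lambda, retained views, accuracy, FLOPs) outcome of the sweep."""

    lambda_sparsity: float
    retained_views: tuple[str, ...]
    view_count: int
    accuracy: float          # Top-1 %, 2 decimals
    flops: float             # G, 2 decimals
    label: str = ""
    failed: bool = False

    def __post_init__(self):
        if self.view_count != len(self.retained_views) and self.retained_views:
            raise ValueError("view_count != |retained_views|")
        if not self.failed and not 0.0 <= self.accuracy <= 100.0:
            raise ValueError(f"accuracy {self.accuracy} outside [0, 100]")
        if self.flops < 0:
            raise ValueError("flops must be non-negative")


@dataclass
class ParetoTable:
    """The sweep collection plus its all-view baseline."""

    records: list[SweepRecord]
    baseline: SweepRecord
    per_view_flops: float
    n_views: int

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: r.lambda_sparsity)

    def ok_records(self) -> list[SweepRecord]:
        return [r for r in self.records if not r.failed]


def flops_total(view_count: int, per_view_flops: float) -> float:
    """Total cost in G for a configuration: linear in the retained views."""
    if view_count < 0:
        raise ValueError("view_count must be >= 0")
    return round2(view_count * per_view_flops)


def flops_saved_pct(baseline_flops: float, config_flops: float) -> float:
    """Percentage of the baseline cost saved (from the rounded cells)."""
    if not baseline_flops > 0:
        raise ValueError("baseline flops must be positive")
    return round2(100.0 * (baseline_flops - config_flops) / baseline_flops)


def accuracy_drop(baseline_acc: float, config_acc: float) -> float:
    """Accuracy drop in percentage points (negative if config beats baseline)."""
    for a in (baseline_acc, config_acc):
        if not 0.0 <= a <= 100.0:
            raise ValueError(f"accuracy {a} outside [0, 100]")
    return round2(baseline_acc - config_acc)


def pareto_frontier(records: list[SweepRecord]) -> list[SweepRecord]:
    """Non-dominated records (accuracy up, FLOPs down), by ascending FLOPs.

    A record is dominated if some other record has accuracy >= its accuracy
    and FLOPs <= its FLOPs with at least one inequality strict.
    """
    if not records:
        raise ValueError("need at least one record")
    kept = []
    for r in records:
        dominated = any(
            (o.accuracy >= r.accuracy and o.flops <= r.flops
             and (o.accuracy > r.accuracy or o.flops < r.flops))
            for o in records if o is not r)
        if not dominated:
            kept.append(r)
    return sorted(kept, key=lambda r: (r.flops, -r.accuracy))


def select_recommended(table: ParetoTable, margin_pp: float = 1.0) -> SweepRecord:
    """The qualifying record with the fewest views.

    Qualifying means accuracy within ``margin_pp`` percentage points of the
    all-view baseline.  Ties break by lower FLOPs, then lower lambda.  If no
    record qualifies the baseline itself is returned.
    """
    candidates = table.ok_records()
    if not candidates:
        raise ValueError("empty sweep table")
    qualifying = [r for r in candidates
                  if accuracy_drop(table.baseline.accuracy, r.accuracy)
                  <= margin_pp]
    if not qualifying:
        return table.baseline
    # higher accuracy breaks exact flops ties so the pick stays on the frontier
    return min(qualifying,
               key=lambda r: (r.view_count, r.flops, -r.accuracy,
                              r.lambda_sparsity))


def label_configurations(table: ParetoTable, margin_pp: float = 1.0) -> ParetoTable:
    """Assign the configuration labels; idempotent.

    all-view (all N views) and single-view (one view) by count; the selected
    record is recommended; other qualifying records are reduced; records
    beyond the margin with more than one view are aggressive.
    """
    recommended = select_recommended(table, margin_pp)
    for r in table.ok_records():
        drop = accuracy_drop(table.baseline.accuracy, r.accuracy)
        if r.view_count == table.n_views:
            r.label = "all-view"
        elif r.view_count == 1:
            r.label = "single-view"
        elif r is recommended:
            r.label = "recommended"
        elif drop <= margin_pp:
            r.label = "reduced"
        else:
            r.label = "aggressive"
    if table.baseline.view_count == table.n_views:
        table.baseline.label = "all-view"
    return table


def run_sweep(grid, trainer, view_names: list[str],
              per_view_flops: float, margin_pp: float = 1.0) -> ParetoTable:
    """Run one independent training per lambda and assemble the table.

    ``trainer`` is a callable ``trainer(lambda_sparsity) -> (accuracy_pct,
    retained_view_names)`` performing a fresh training run; the lambda = 0
    all-view baseline is always added.  A training failure marks its record
    failed but the table is still returned.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    n_views = len(view_names)
    records = []
    for lam in [0.0] + grid:
        try:
            acc, retained = trainer(lam)
            retained = tuple(retained)
            # stored unrounded; cells are rounded at report time
            rec = SweepRecord(lambda_sparsity=lam, retained_views=retained,
                              view_count=len(retained), accuracy=acc,
                              flops=len(retained) * per_view_flops)
        except Exception:  # noqa: BLE001 — a failed run must not kill the sweep
            rec = SweepRecord(lambda_sparsity=lam, retained_views=(),
                              view_count=0, accuracy=0.0, flops=0.0,
                              failed=True)
        records.append(rec)
    baseline = records[0]
    table = ParetoTable(records=records, baseline=baseline,
                        per_view_flops=per_view_flops, n_views=n_views)
    return label_configurations(table, margin_pp)


def table_to_dataframe(table: ParetoTable) -> pd.DataFrame:
    """Render the sweep with exactly the seven report column headers."""
    rows = []
    for r in table.ok_records():
        rows.append({
            TABLE_COLUMNS[0]: r.lambda_sparsity,
            TABLE_COLUMNS[1]: r.view_count,
            TABLE_COLUMNS[2]: r.accuracy,
            TABLE_COLUMNS[3]: accuracy_drop(table.baseline.accuracy, r.accuracy),
            TABLE_COLUMNS[4]: round2(r.flops),
            TABLE_COLUMNS[5]: flops_saved_pct(table.baseline.flops, r.flops),
            TABLE_COLUMNS[6]: r.label.capitalize() if r.label else "",
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def table_from_dataframe(df: pd.DataFrame, n_views: int | None = None,
                         per_view_flops: float | None = None) -> ParetoTable:
    """Rebuild a ParetoTable from a sweep CSV (report column headers).

    A lambda cell may list several comma-separated values that share one
    outcome row; each becomes its own record.  Retained view names are not
    recoverable from the report format and are left empty.
    """
    needed = set(TABLE_COLUMNS[:3]) | {TABLE_COLUMNS[4]}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"sweep table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        for lam in str(row[TABLE_COLUMNS[0]]).split(","):
            records.append(SweepRecord(
                lambda_sparsity=float(lam),
                retained_views=(),
                view_count=int(row[TABLE_COLUMNS[1]]),
                accuracy=float(row[TABLE_COLUMNS[2]]),
                flops=float(row[TABLE_COLUMNS[4]]),
                label=str(row.get(TABLE_COLUMNS[6], "")).lower()))
    if n_views is None:
        n_views = max(r.view_count for r in records)
    baseline = max(records, key=lambda r: (r.view_count, -r.lambda_sparsity))
    if per_view_flops is None:
        per_view_flops = baseline.flops / baseline.view_count
    return ParetoTable(records=records, baseline=baseline,
                       per_view_flops=per_view_flops, n_views=n_views)
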