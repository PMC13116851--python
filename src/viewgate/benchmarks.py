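"""Published benchmark sweep tables for the two reference surveys.

Two multi-view surveys of disease-vector specimens serve as the reference
workloads for the selection logic in this package: a 12-species fly
(Calyptratae) survey photographed in 8 anatomical views (512 specimens,
404/108 train/val split, 1.41 GFLOPs per encoded view) and a 5-species
mosquito (Culicidae) survey photographed in 11 views (363 specimens, 289/74
split).  The image data are not redistributable, but the published sweep
outcomes — accuracy and cost per sparsity weight — are, and they are exactly
the input format the selection rule consumes, so they double as golden
fixtures: running :func:`viewgate.pareto.select_recommended` on them must
return the published recommended configurations (5 parts at lambda 0.4 for
the flies; 2 parts at lambda 0.20 for the mosquitoes).

Rows whose printed lambda cell lists several values (e.g. "0.1, 0.2") are
kept as one row here and expanded by ``table_from_dataframe``.
"""

from __future__ import annotations

import pandas as pd

from .pareto import TABLE_COLUMNS, ParetoTable, table_from_dataframe

__all__ = [
    "fly_sweep_table",
    "mosquito_sweep_table",
    "FLY_BASELINE_FLOPS",
    "FLY_N_VIEWS",
    "MOSQUITO_BASELINE_FLOPS",
    "MOSQUITO_N_VIEWS",
    "FLY_BEST_SINGLE_VIEW_ACC",
    "MOSQUITO_BEST_SINGLE_VIEW_ACC",
]

FLY_N_VIEWS = 8
FLY_BASELINE_FLOPS = 11.31          # G, all 8 views
FLY_BEST_SINGLE_VIEW_ACC = 83.33    # mesonotum, the strongest single view

MOSQUITO_N_VIEWS = 11
MOSQUITO_BASELINE_FLOPS = 49.56     # G, all 11 views
MOSQUITO_BEST_SINGLE_VIEW_ACC = 97.18  # pre/post-spiracular setae view

_FLY_ROWS = [
    ("0.1, 0.2", 8, 87.04, 0.00, 11.31, 0.00, "All-view"),
    ("0.3",      7, 87.04, 0.00,  9.90, 12.47, "Reduced"),
    ("0.4",      5, 86.11, 0.93,  7.07, 37.49, "Recommended"),
    ("0.5",      3, 84.26, 2.78,  4.24, 62.51, "Aggressive"),
    ("0.6",      1, 83.33, 3.71,  1.41, 87.53, "Single-view"),
]

_MOSQUITO_ROWS = [
    ("0.00", 11, 100.00, 0.00, 49.56,  0.00, "All-view"),
    ("0.05",  9, 100.00, 0.00, 40.55, 18.20, "Reduced"),
    ("0.10",  8, 100.00, 0.00, 36.04, 27.28, "Reduced"),
    ("0.15",  3, 100.00, 0.00, 13.52, 72.72, "Reduced"),
    ("0.20",  2, 100.00, 0.00,  9.01, 81.82, "Recommended"),
    ("0.25",  1,  97.18, 2.82,  4.50, 87.53, "Single-view"),
]


def _frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def fly_sweep_table(as_table: bool = False) -> pd.DataFrame | ParetoTable:
    """The published 8-view fly sweep (DataFrame, or parsed ParetoTable)."""
    df = _frame(_FLY_ROWS)
    if as_table:
        return table_from_dataframe(df, n_views=FLY_N_VIEWS)
    return df


def mosquito_sweep_table(as_table: bool = False) -> pd.DataFrame | ParetoTable:
    """The published 11-view mosquito sweep."""
    df = _frame(_MOSQUITO_ROWS)
    if as_table:
        return table_from_dataframe(df, n_views=MOSQUITO_N_VIEWS)
    return df
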