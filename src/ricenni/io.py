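"""Readers and writers for the plot-table and report CSV dialects.

All files are UTF-8 CSV with '.' decimal separator.  The plot table is
the tidy one-row-per-plot-per-stage layout produced by the synthetic
generator (see that module for column semantics); readers validate the
schema and physical invariants row by row and report offending line
numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PLOT_TABLE_COLUMNS",
    "read_plot_table",
    "write_plot_table",
    "read_reflectance_table",
    "write_recommendations",
    "read_recommendations",
]

PLOT_TABLE_COLUMNS = (
    "plot_id",
    "cultivar",
    "stage",
    "n_rate",
    "leaf_dm",
    "stem_dm",
    "panicle_dm",
    "leaf_n",
    "stem_n",
    "panicle_n",
    "shoot_dm",
    "shoot_n",
    "yield_kg_ha",
)

_RECOMMENDATION_PREFIX = ("treatment", "basal")


class PlotTableError(ValueError):
    """Schema or invariant violation in a plot table, with line numbers."""


def read_plot_table(path) -> pd.DataFrame:
    """Read and validate a plot-level agronomic table.

    Checks: required columns present, organ dry weights >= 0, organ N
    concentrations in [0, 10] %, shoot_dm (t/ha) equal to the organ sum
    (kg/ha) within 1e-6, and shoot_n equal to the dry-weight-weighted
    mean organ concentration.  Violations raise :class:`PlotTableError`
    naming the first offending data lines (line 2 = first data row).
    """
    table = pd.read_csv(path)
    if table.empty:
        raise PlotTableError(f"{path}: empty plot table")
    missing = [c for c in PLOT_TABLE_COLUMNS if c not in table.columns and c != "yield_kg_ha"]
    if missing:
        raise PlotTableError(f"{path}: missing columns {missing}")
    errors = []

    def _flag(mask, message):
        if mask.any():
            lines = (np.flatnonzero(mask.to_numpy()) + 2)[:5].tolist()
            errors.append(f"{message} (lines {lines})")

    for organ in ("leaf", "stem", "panicle"):
        _flag(table[f"{organ}_dm"] < 0, f"negative {organ} dry weight")
        _flag((table[f"{organ}_n"] < 0) | (table[f"{organ}_n"] > 10), f"{organ} N% outside [0, 10]")
    organ_sum_t = (table["leaf_dm"] + table["stem_dm"] + table["panicle_dm"]) / 1000.0
    _flag((table["shoot_dm"] - organ_sum_t).abs() > 1e-6, "shoot_dm != organ sum")
    w = table[["leaf_dm", "stem_dm", "panicle_dm"]].to_numpy(dtype=float)
    n = table[["leaf_n", "stem_n", "panicle_n"]].to_numpy(dtype=float)
    weighted = (w * n).sum(axis=1) / np.where(w.sum(axis=1) > 0, w.sum(axis=1), 1.0)
    _flag(pd.Series((weighted - table["shoot_n"]).__abs__() > 1e-6), "shoot_n != weighted organ mean")
    if errors:
        raise PlotTableError(f"{path}: " + "; ".join(errors))
    return table


def write_plot_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in PLOT_TABLE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_reflectance_table(path) -> pd.DataFrame:
    from .indices import BAND_COLUMNS

    table = pd.read_csv(path)
    missing = [c for c in BAND_COLUMNS if c not in table.columns]
    if missing:
        raise PlotTableError(f"{path}: missing band columns {missing}")
    bad = pd.Series(False, index=table.index)
    for c in BAND_COLUMNS:
        bad |= (table[c] < 0) | (table[c] > 1)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2)[:5].tolist()
        raise PlotTableError(f"{path}: reflectance outside [0, 1] (lines {lines})")
    return table


def write_recommendations(plans, path, round_to: int = 2) -> None:
    """Write per-treatment topdressing plans as a fixed-order CSV.

    ``plans`` maps treatment label -> :class:`~ricenni.nbalance.TopdressingPlan`
    (or is an iterable of (label, plan) pairs).  Plans are checked for
    conservation before writing; rounding happens only here.
    """
    items = plans.items() if hasattr(plans, "items") else list(plans)
    rows = []
    stages = None
    for label, plan in items:
        if abs(plan.basal + sum(plan.topdressings) - plan.total) > 1e-9:
            raise ValueError(f"plan {label!r} violates conservation")
        if stages is None:
            stages = plan.stages
        elif plan.stages != stages:
            raise ValueError("all plans must share the same topdressing stages")
        rows.append({"treatment": label, **plan.as_row(round_to=round_to)})
    if stages is None:
        stages = ()
    columns = ["treatment", "basal", *[f"topdress_{s}" for s in stages], "total"]
    frame = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    frame.to_csv(path, index=False)


def read_recommendations(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for c in _RECOMMENDATION_PREFIX:
        if c not in table.columns:
            raise PlotTableError(f"{path}: missing column {c!r}")
    return table
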