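"""Per-cell and per-lineage expression summaries.

Supports coloring (mean expression per cell over its lifetime) and
cross-embryo comparison (mean expression over a user-selected set of
lineages at each aligned timepoint).  Summaries use the arithmetic mean; no
interpolation is performed across missing timepoints, so trajectory tables
can have gaps.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import EmbryoTable
from .lineage import select_cells

TRAJECTORY_COLUMNS = ("embryo_id", "condition", "time", "mean_expression", "n_cells")


def cell_mean_expression(table: EmbryoTable, expr_column: str = "blot") -> Dict[str, float]:
    """Mean expression of each cell over all timepoints at which a value
    exists; cells with no values are omitted."""
    if expr_column not in table.data.columns:
        raise ValueError(f"expression column {expr_column!r} absent from "
                         f"embryo {table.embryo_id!r}")
    grouped = table.data.groupby(table.data["cell"].astype(str))[expr_column].mean()
    return {cell: float(v) for cell, v in grouped.items() if np.isfinite(v)}


def lineage_trajectory(
    tables: Sequence[EmbryoTable],
    patterns: Sequence[str],
    include_descendants: bool = True,
    expr_column: str = "blot",
    conditions: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-embryo expression trajectory over a lineage selection.

    For each embryo and timepoint, the mean of ``expr_column`` over the
    selected cells present at that timepoint (timepoints with no selected
    cell carrying a value are omitted).  Tables are expected to be
    time-aligned already; a warning is emitted when the time axes look
    unaligned.  ``conditions`` optionally maps embryo_id to a condition
    label (defaults to the embryo_id itself) so replicate groups can be
    aggregated downstream.
    """
    if not tables:
        raise ValueError("no embryos supplied")
    starts = [float(t.data["time"].min()) for t in tables if len(t.data)]
    if (
        len(tables) > 1
        and starts
        and all(s > 0 for s in starts)
        and max(starts) != min(starts)
    ):
        warnings.warn(
            "time axes look unaligned (all-positive times with mismatched "
            "starts); did you run align_times?",
            stacklevel=2,
        )
    frames: List[pd.DataFrame] = []
    for tbl in tables:
        if expr_column not in tbl.data.columns:
            raise ValueError(f"expression column {expr_column!r} absent from "
                             f"embryo {tbl.embryo_id!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected = select_cells(tbl, patterns, include_descendants)
        sub = tbl.data[
            tbl.data["cell"].astype(str).isin(selected)
            & tbl.data[expr_column].notna()
        ]
        if len(sub) == 0:
            raise ValueError(
                f"selection {list(patterns)} yields no expressing cell at any "
                f"time in embryo {tbl.embryo_id!r}"
            )
        grouped = sub.groupby("time")[expr_column].agg(["mean", "count"])
        cond = (conditions or {}).get(tbl.embryo_id, tbl.embryo_id)
        frames.append(pd.DataFrame({
            "embryo_id": tbl.embryo_id,
            "condition": cond,
            "time": grouped.index.to_numpy(dtype=float),
            "mean_expression": grouped["mean"].to_numpy(dtype=float),
            "n_cells": grouped["count"].to_numpy(dtype=int),
        }))
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["embryo_id", "time"], kind="mergesort").reset_index(drop=True)
    return out[list(TRAJECTORY_COLUMNS)]


def subset_embryos(
    tables: Sequence[EmbryoTable],
    patterns: Optional[Sequence[str]] = None,
    time_window: Optional[Tuple[float, float]] = None,
    include_descendants: bool = True,
) -> List[EmbryoTable]:
    """Restrict each table to the selected cells and/or time window
    (inclusive).  Empty results are allowed, with a warning."""
    out: List[EmbryoTable] = []
    for tbl in tables:
        df = tbl.data
        mask = np.ones(len(df), dtype=bool)
        if patterns is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                selected = select_cells(tbl, patterns, include_descendants)
            mask &= df["cell"].astype(str).isin(selected).to_numpy()
        if time_window is not None:
            t0, t1 = time_window
            t = df["time"].to_numpy(dtype=float)
            mask &= (t >= t0) & (t <= t1)
        sub = df[mask].reset_index(drop=True)
        if len(sub) == 0:
            warnings.warn(f"subset of embryo {tbl.embryo_id!r} is empty", stacklevel=2)
        out.append(tbl.with_data(sub))
    return out
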