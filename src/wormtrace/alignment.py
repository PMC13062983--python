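"""Event-based time alignment across embryos.

Recordings start at arbitrary developmental stages, so comparing expression
across embryos requires a shared time origin.  Alignment shifts each
embryo's time axis so that a chosen developmental event — the birth (first
appearance) or last observation of a named blastomere — occurs at time 0.
Times before the event become negative; within-embryo time differences are
preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .io_formats import EmbryoTable

EVENT_KINDS = ("birth", "last-seen")


@dataclass(frozen=True)
class TimeAlignment:
    """Record of an alignment: the event and the per-embryo offset that was
    added to each time axis (offset = -event time)."""

    cell: str
    kind: str
    offsets: Dict[str, float]


def event_time(table: EmbryoTable, cell, kind: str = "birth"):
    """Time of a developmental event for ``cell`` in the table's current
    time units: ``birth`` = first appearance of the exact name, ``last-seen``
    = last appearance."""
    kind = kind.replace("_", "-")
    if kind == "death":
        kind = "last-seen"
    if kind not in EVENT_KINDS:
        raise ValueError(f"unknown event kind {kind!r}; use one of {EVENT_KINDS}")
    times = table.data.loc[table.data["cell"].astype(str) == str(cell), "time"]
    if len(times) == 0:
        raise ValueError(
            f"cell {cell!r} never observed in embryo {table.embryo_id!r}"
        )
    return times.min() if kind == "birth" else times.max()


def align_times(
    tables: Sequence[EmbryoTable],
    cell,
    kind: str = "birth",
) -> Tuple[List[EmbryoTable], TimeAlignment]:
    """Shift every table's time axis so the event occurs at time 0.

    All tables must share a time flag; embryos missing the event are listed
    in the error.  Idempotent: aligning already-aligned tables yields zero
    offsets.  If times were ordinal they are preserved in an ``ordinal``
    auxiliary column and the axis becomes a signed numeric one.
    """
    if not tables:
        raise ValueError("no embryos supplied")
    flags = {t.time_units for t in tables}
    if len(flags) > 1:
        raise ValueError(f"mixed time flags across embryos: {sorted(flags)}")
    missing = []
    events = []
    for tbl in tables:
        try:
            events.append(event_time(tbl, cell, kind))
        except ValueError:
            missing.append(tbl.embryo_id)
    if missing:
        raise ValueError(
            f"event cell {cell!r} not observed in embryo(s): {', '.join(missing)}"
        )
    aligned = []
    offsets: Dict[str, float] = {}
    for tbl, t_event in zip(tables, events):
        df = tbl.data.copy()
        if tbl.time_units == "ordinal" and "ordinal" not in df.columns:
            df["ordinal"] = df["time"].astype(int)
        df["time"] = df["time"].astype(float) - float(t_event)
        offsets[tbl.embryo_id] = -float(t_event)
        aligned.append(tbl.with_data(df, time_units="aligned"))
    return aligned, TimeAlignment(cell=str(cell), kind=kind.replace("_", "-"), offsets=offsets)
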