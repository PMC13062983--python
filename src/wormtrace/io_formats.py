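"""Readers and writers for embryo cell-tracking tables.

Three dialects are supported:

* **CD files** — comma-separated text with a header line; required columns
  ``cell, time, x, y, z`` (case-insensitive), plus any number of quantitative
  expression columns (``blot`` by convention) and an optional ``diameter``.
  One row per (cell, timepoint).  Positions are pixel/plane coordinates until
  :func:`apply_metadata` converts them to microns.
* **StarryNite zip archives** — one nuclei text file per timepoint.  The
  supported record layout is comma-separated: nucleus index, valid flag,
  predecessor index, two successor indices, x, y, z, diameter, identity name,
  and a trailing expression value.  The ordinal timepoint is the last run of
  digits in the member file name (``t042-nuclei`` -> 42).  Other layouts are
  rejected loudly.
* **TIME files** — two columns mapping ordinal timepoint to elapsed minutes;
  a single header line is auto-detected.

All writers emit UNIX line endings.
"""

from __future__ import annotations

import math
import re
import zipfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError

REQUIRED_COLUMNS = ("cell", "time", "x", "y", "z")
#: Columns that are never treated as expression channels.
_AUX_COLUMNS = ("diameter", "ordinal")

_FLOAT_FORMAT = "%.10g"


@dataclass
class EmbryoTable:
    """Long-format record set for one embryo: one row per (cell, time).

    ``data`` holds columns ``cell, time, x, y, z``, the expression columns in
    ``expr_columns`` order, and optionally ``diameter`` and ``ordinal``.
    ``units`` is ``"pixel"`` (x/y in pixels, z in image planes) or
    ``"micron"``; ``time_units`` is ``"ordinal"`` (integer timepoint index,
    >= 1), ``"minutes"`` (elapsed time) or ``"aligned"`` (signed axis after
    event alignment).
    """

    data: pd.DataFrame
    embryo_id: str = "embryo"
    units: str = "pixel"
    time_units: str = "ordinal"
    expr_columns: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        if self.expr_columns is None:
            self.expr_columns = tuple(
                c for c in self.data.columns
                if c not in REQUIRED_COLUMNS and c not in _AUX_COLUMNS
            )
        else:
            self.expr_columns = tuple(self.expr_columns)
        self.validate()

    def validate(self) -> None:
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
        for col in self.expr_columns:
            if col not in df.columns:
                raise FormatError(f"expression column {col!r} not in table")
        if self.units not in ("pixel", "micron"):
            raise ValueError(f"unknown units flag {self.units!r}")
        if self.time_units not in ("ordinal", "minutes", "aligned"):
            raise ValueError(f"unknown time flag {self.time_units!r}")
        if len(df) == 0:
            return
        dup = df.duplicated(subset=["cell", "time"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise FormatError(
                f"duplicate (cell, time) pair ({first['cell']!r}, {first['time']!r}) "
                f"in embryo {self.embryo_id!r}"
            )
        pos = df[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(pos).all():
            raise FormatError(f"non-finite position in embryo {self.embryo_id!r}")
        t = df["time"].to_numpy(dtype=float)
        if not np.isfinite(t).all():
            raise FormatError("non-finite time value")
        if self.time_units == "ordinal" and (t <= 0).any():
            raise FormatError("ordinal timepoints must be >= 1")

    # -- convenience -------------------------------------------------------

    def copy(self) -> "EmbryoTable":
        return replace(self, data=self.data.copy())

    def with_data(self, data: pd.DataFrame, **kwargs) -> "EmbryoTable":
        return replace(self, data=data, **kwargs)

    def times(self) -> np.ndarray:
        return np.sort(self.data["time"].unique())

    def cells(self) -> Tuple[str, ...]:
        return tuple(sorted(set(self.data["cell"].astype(str))))

    def at_time(self, time) -> pd.DataFrame:
        return self.data[self.data["time"] == time]


def tables_allclose(a: EmbryoTable, b: EmbryoTable, tol: float = 1e-6) -> bool:
    """Field-for-field equality of two tables within a numeric tolerance.

    Rows are matched on (cell, time ordinal rank); NaN (missing expression)
    equals NaN.
    """
    if a.embryo_id != b.embryo_id or a.units != b.units or a.time_units != b.time_units:
        return False
    if set(a.data.columns) != set(b.data.columns) or a.expr_columns != b.expr_columns:
        return False
    if len(a.data) != len(b.data):
        return False
    if len(a.data) == 0:
        return True
    da = a.data.sort_values(["cell", "time"]).reset_index(drop=True)
    db = b.data.sort_values(["cell", "time"]).reset_index(drop=True)
    if not (da["cell"].astype(str) == db["cell"].astype(str)).all():
        return False
    for col in da.columns:
        if col == "cell":
            continue
        va = da[col].to_numpy(dtype=float)
        vb = db[col].to_numpy(dtype=float)
        if not np.allclose(va, vb, rtol=tol, atol=tol, equal_nan=True):
            return False
    return True


# ---------------------------------------------------------------------------
# CD files
# ---------------------------------------------------------------------------

def read_cd(
    path,
    expr_columns: Optional[Sequence[str]] = None,
    embryo_id: Optional[str] = None,
    units: str = "pixel",
    time_units: str = "auto",
) -> EmbryoTable:
    """Read a CD-format table.

    Header matching for the required columns is case-insensitive with
    surrounding whitespace stripped.  All non-required columns are retained as
    expression channels (minus ``diameter``/``ordinal``) unless
    ``expr_columns`` restricts them.  Rows whose numeric fields do not parse
    are rejected with row-number diagnostics; blank expression fields are
    stored as missing, not zero.

    The CD format itself carries no time flag, so ``time_units="auto"``
    infers one: positive integer times with no ``ordinal`` column are
    ordinal timepoints (the plain StarryNite/AceTree export); otherwise the
    axis is a converted one — ``aligned`` when any time is <= 0, ``minutes``
    when all are positive (files written back by the unit-conversion and
    alignment steps carry the original index in an ``ordinal`` column).
    Pass ``time_units`` explicitly to override.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [str(c).strip() for c in raw.columns]

    lower_map = {}
    for col in raw.columns:
        lower_map.setdefault(col.lower(), col)
    rename = {}
    for req in REQUIRED_COLUMNS + _AUX_COLUMNS:
        if req in lower_map and lower_map[req] != req:
            rename[lower_map[req]] = req
    if rename:
        raw = raw.rename(columns=rename)
    for req in REQUIRED_COLUMNS:
        if req not in raw.columns:
            raise FormatError(f"{path.name}: missing required column {req!r}")

    other = [c for c in raw.columns if c not in REQUIRED_COLUMNS and c not in _AUX_COLUMNS]
    if expr_columns is not None:
        missing = [c for c in expr_columns if c not in raw.columns]
        if missing:
            raise FormatError(f"{path.name}: expression column(s) {missing} not found")
        other = list(expr_columns)

    df = pd.DataFrame()
    df["cell"] = raw["cell"].astype(str).str.strip()
    bad_rows: list = []

    def _numeric(col: str, required: bool) -> pd.Series:
        src = raw[col].astype(str).str.strip()
        present = src.notna() & (src != "") & (src.str.lower() != "nan")
        vals = pd.to_numeric(src.where(present), errors="coerce")
        bad = present & vals.isna()
        if required:
            bad = bad | ~present
        if bad.any():
            # +2: header is line 1, data starts at line 2
            bad_rows.extend((col, int(i) + 2) for i in np.flatnonzero(bad.to_numpy()))
        return vals

    df["time"] = _numeric("time", required=True)
    for col in ("x", "y", "z"):
        df[col] = _numeric(col, required=True)
    for col in other:
        df[col] = _numeric(col, required=False)
    if "diameter" in raw.columns:
        df["diameter"] = _numeric("diameter", required=False)
    if "ordinal" in raw.columns:
        df["ordinal"] = _numeric("ordinal", required=False)

    if bad_rows:
        detail = ", ".join(f"{col}@line{ln}" for col, ln in bad_rows[:10])
        raise FormatError(
            f"{path.name}: {len(bad_rows)} unparseable numeric field(s): {detail}"
        )
    if time_units == "auto":
        t = df["time"].to_numpy(dtype=float)
        if len(df) == 0:
            time_units = "ordinal"
        elif "ordinal" in df.columns or not np.allclose(t, np.round(t)) \
                or (t < 1).any():
            time_units = "aligned" if (t <= 0).any() else "minutes"
        else:
            time_units = "ordinal"
    if time_units == "ordinal" and len(df):
        t = df["time"].to_numpy(dtype=float)
        if not np.allclose(t, np.round(t)):
            raise FormatError(f"{path.name}: ordinal time values must be integers")
        df["time"] = np.round(t).astype(int)

    return EmbryoTable(
        data=df.reset_index(drop=True),
        embryo_id=embryo_id if embryo_id is not None else path.stem,
        units=units,
        time_units=time_units,
        expr_columns=tuple(other),
    )


def write_cd(table: EmbryoTable, path) -> None:
    """Write a CD file readable by :func:`read_cd`.

    Column order is ``cell,time,x,y,z``, then the expression columns in
    stored order, then ``diameter``/``ordinal`` when present.  Floats keep at
    least 10 significant digits; missing values are written blank.
    """
    path = Path(path)
    cols = list(REQUIRED_COLUMNS) + list(table.expr_columns)
    for aux in _AUX_COLUMNS:
        if aux in table.data.columns:
            cols.append(aux)
    df = table.data[cols].copy()
    if table.time_units == "ordinal" and len(df):
        df["time"] = df["time"].astype(int)
    if "ordinal" in df.columns and len(df) and df["ordinal"].notna().all():
        df["ordinal"] = df["ordinal"].astype(int)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


# ---------------------------------------------------------------------------
# TIME files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeMap:
    """Mapping from ordinal timepoint to elapsed minutes; strictly increasing
    in both coordinates."""

    entries: Tuple[Tuple[int, float], ...]

    def __post_init__(self):
        ordinals = [o for o, _ in self.entries]
        elapsed = [e for _, e in self.entries]
        if len(set(ordinals)) != len(ordinals):
            raise FormatError("duplicate ordinal in time map")
        if sorted(ordinals) != list(ordinals):
            raise FormatError("ordinals not sorted in time map")
        if any(b <= a for a, b in zip(elapsed, elapsed[1:])):
            raise FormatError("elapsed times not strictly increasing in time map")

    def as_dict(self) -> Dict[int, float]:
        return dict(self.entries)

    def elapsed(self, ordinal: int) -> float:
        for o, e in self.entries:
            if o == int(ordinal):
                return e
        raise KeyError(f"ordinal timepoint {ordinal} not in time map")

    def ordinal(self, elapsed: float) -> int:
        for o, e in self.entries:
            if math.isclose(e, elapsed, rel_tol=0.0, abs_tol=1e-9):
                return o
        raise KeyError(f"elapsed time {elapsed} not in time map")


def read_time_file(path) -> TimeMap:
    """Read a TIME file (two columns: ordinal timepoint, elapsed minutes).

    Fields are comma- or whitespace-separated; a single leading header line
    is detected by its first field failing to parse as a number.
    """
    path = Path(path)
    entries = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path.name}: empty TIME file")
    start = 0
    first = re.split(r"[,\s]+", lines[0])
    try:
        float(first[0])
    except ValueError:
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = [f for f in re.split(r"[,\s]+", line) if f]
        if len(fields) < 2:
            raise FormatError(f"{path.name}: line {lineno}: need two columns")
        try:
            ordinal = int(float(fields[0]))
            elapsed = float(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path.name}: line {lineno}: {exc}") from exc
        entries.append((ordinal, elapsed))
    entries.sort(key=lambda oe: oe[0])
    return TimeMap(tuple(entries))


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbryoMetadata:
    """Voxel dimensions and optional timestamp map for unit conversion."""

    xy_res: float  # microns per pixel
    z_res: float   # microns per image plane
    time_map: Optional[TimeMap] = None

    def __post_init__(self):
        if not (self.xy_res > 0 and self.z_res > 0):
            raise ValueError("voxel resolutions must be strictly positive")


def apply_metadata(table: EmbryoTable, meta: EmbryoMetadata) -> EmbryoTable:
    """Convert a pixel/ordinal table to microns (and elapsed minutes if a
    time map is supplied).

    Not idempotent by design: applying to an already-micron table raises
    rather than silently re-scaling.  The ordinal timepoint is retained as an
    auxiliary ``ordinal`` column when times are converted.
    """
    if table.units != "pixel":
        raise ValueError(
            f"embryo {table.embryo_id!r} is already in micron units; "
            "refusing to re-scale"
        )
    df = table.data.copy()
    df["x"] = df["x"].astype(float) * meta.xy_res
    df["y"] = df["y"].astype(float) * meta.xy_res
    df["z"] = df["z"].astype(float) * meta.z_res
    time_units = table.time_units
    if meta.time_map is not None and table.time_units == "ordinal":
        lookup = meta.time_map.as_dict()
        ordinals = df["time"].astype(int)
        missing = sorted(set(ordinals) - set(lookup))
        if missing:
            raise KeyError(
                f"ordinal timepoint(s) {missing[:5]} absent from time map"
            )
        df["ordinal"] = ordinals
        df["time"] = ordinals.map(lookup).astype(float)
        time_units = "minutes"
    return table.with_data(df, units="micron", time_units=time_units)


# ---------------------------------------------------------------------------
# StarryNite zip archives
# ---------------------------------------------------------------------------

def _member_time(member: str) -> Optional[int]:
    base = Path(member).name
    if "nuclei" not in base.lower():
        return None
    runs = re.findall(r"\d+", base.split("nuclei")[0])
    if not runs:
        runs = re.findall(r"\d+", base)
    return int(runs[-1]) if runs else None


def read_starrynite_zip(path, embryo_id: Optional[str] = None) -> EmbryoTable:
    """Parse a raw StarryNite ``.zip`` archive of per-timepoint nuclei files.

    Only nuclei with a nonzero valid flag produce rows; x/y are pixels, z is
    in image planes, and the trailing expression field maps to column
    ``blot`` (blank = missing).
    """
    path = Path(path)
    rows = []
    with zipfile.ZipFile(path) as zf:
        members = [
            (t, m) for m in zf.namelist()
            if not m.endswith("/") and (t := _member_time(m)) is not None
        ]
        if not members:
            raise FormatError(f"{path.name}: no nuclei files found in archive")
        for tp, member in sorted(members):
            text = zf.read(member).decode("utf-8", errors="replace")
            for lineno, line in enumerate(text.splitlines(), start=1):
                line = line.strip()
                if not line:
                    continue
                fields = [f.strip() for f in line.split(",")]
                if len(fields) < 10:
                    raise FormatError(
                        f"{path.name}:{member}: line {lineno}: expected >= 10 "
                        f"comma-separated fields, got {len(fields)}"
                    )
                try:
                    valid = int(float(fields[1]))
                    x, y, z = (float(fields[i]) for i in (5, 6, 7))
                    diameter = float(fields[8]) if fields[8] else np.nan
                except ValueError as exc:
                    raise FormatError(
                        f"{path.name}:{member}: line {lineno}: {exc}"
                    ) from exc
                if valid == 0:
                    continue
                identity = fields[9]
                blot = np.nan
                if len(fields) >= 11 and fields[-1]:
                    try:
                        blot = float(fields[-1])
                    except ValueError as exc:
                        raise FormatError(
                            f"{path.name}:{member}: line {lineno}: bad "
                            f"expression value {fields[-1]!r}"
                        ) from exc
                rows.append((identity, tp, x, y, z, blot, diameter))
    df = pd.DataFrame(
        rows, columns=["cell", "time", "x", "y", "z", "blot", "diameter"]
    )
    return EmbryoTable(
        data=df,
        embryo_id=embryo_id if embryo_id is not None else path.stem,
        units="pixel",
        time_units="ordinal",
        expr_columns=("blot",),
    )


def write_starrynite_zip(table: EmbryoTable, path, expr_column: str = "blot") -> None:
    """Write a table as a StarryNite-dialect zip (one nuclei file per
    timepoint); the counterpart of :func:`read_starrynite_zip`."""
    path = Path(path)
    if table.time_units != "ordinal":
        raise ValueError("StarryNite archives require ordinal timepoints")
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for tp in table.times():
            sub = table.at_time(tp)
            lines = []
            for idx, (_, row) in enumerate(sub.iterrows(), start=1):
                diameter = row.get("diameter", np.nan)
                expr = row.get(expr_column, np.nan) if expr_column in sub.columns else np.nan
                fields = [
                    str(idx), "1", "-1", "-1", "-1",
                    _FLOAT_FORMAT % row["x"],
                    _FLOAT_FORMAT % row["y"],
                    _FLOAT_FORMAT % row["z"],
                    (_FLOAT_FORMAT % diameter) if np.isfinite(diameter) else "",
                    str(row["cell"]),
                    (_FLOAT_FORMAT % expr) if np.isfinite(expr) else "",
                ]
                lines.append(",".join(fields))
            zf.writestr(f"t{int(tp):03d}-nuclei", "\n".join(lines) + "\n")
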