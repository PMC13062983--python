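"""Exponential depth correction of reporter expression.

Fluorescence signal attenuates with imaging depth (z) in a confocal stack.
Following the standard practice for lineage-resolved reporter quantification,
the loss is modeled as exponential:

    E_ij = exp(a_i) * exp(-k * z_ij) * noise

for cell-timepoint j of embryo i, i.e. on the log scale a per-embryo
intercept ``a_i`` (absorbing brightness differences between replicates) and a
single shared decay rate ``k`` (per micron).  The model is fitted by ordinary
least squares on log expression over all rows with positive expression,
pooling replicate embryos *before* any rotation to a common axis (depth must
still mean optical depth).  Correction rescales expression to a common
reference depth:

    E_corr = E * exp(k * (z - z_ref))

Only ``k`` and ``z_ref`` are used at apply time, so a model learned on one
cohort transfers to embryos imaged under equivalent conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np

from .errors import FormatError
from .io_formats import EmbryoTable

_MIN_POINTS = 10
_MAGIC = "wormtrace-depth-model v1"


@dataclass(frozen=True)
class DepthModel:
    """Fitted depth-attenuation model.

    ``decay_rate`` is k in 1/micron (positive = signal falls with depth);
    ``per_embryo_scale`` maps embryo id to its log-scale intercept a_i;
    ``z_ref`` is the reference depth in microns that corrected values are
    reported at.
    """

    decay_rate: float
    per_embryo_scale: Dict[str, float]
    z_ref: float
    expr_column: str
    n_points_fit: int

    def correction_factor(self, z) -> np.ndarray:
        return np.exp(self.decay_rate * (np.asarray(z, dtype=float) - self.z_ref))

    def save(self, path) -> None:
        lines = [
            _MAGIC,
            "decay_rate: %.17g" % self.decay_rate,
            "z_ref: %.17g" % self.z_ref,
            "expr_column: %s" % self.expr_column,
            "n_points_fit: %d" % self.n_points_fit,
        ]
        for eid in sorted(self.per_embryo_scale):
            lines.append("scale %s: %.17g" % (eid, self.per_embryo_scale[eid]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "DepthModel":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0].strip() != _MAGIC:
            raise FormatError(f"{path}: not a wormtrace depth-model file "
                              f"(or version mismatch)")
        kv: Dict[str, str] = {}
        scales: Dict[str, float] = {}
        for line in lines[1:]:
            if ":" not in line:
                continue
            key, val = line.split(":", 1)
            key = key.strip()
            if key.startswith("scale "):
                scales[key[len("scale "):]] = float(val)
            else:
                kv[key] = val.strip()
        try:
            return cls(
                decay_rate=float(kv["decay_rate"]),
                z_ref=float(kv["z_ref"]),
                expr_column=kv["expr_column"],
                n_points_fit=int(kv["n_points_fit"]),
                per_embryo_scale=scales,
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: truncated or malformed depth-model file") from exc


def fit_depth_model(
    tables: Sequence[EmbryoTable],
    expr_column: str = "blot",
    z_ref: float = 0.0,
) -> DepthModel:
    """Fit the shared-slope / per-embryo-intercept decay model.

    Rows with expression <= 0 or missing are excluded (log undefined).
    Requires micron coordinates and at least 10 usable points with a nonzero
    depth range.  Tables should not yet be rotated to the canonical frame
    (z must remain optical depth).
    """
    if not tables:
        raise ValueError("no embryos supplied")
    if len(tables) < 2:
        warnings.warn("fitting a depth model on a single embryo; replicates "
                      "are recommended", stacklevel=2)
    ids: List[str] = []
    zs: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    for tbl in tables:
        if tbl.units != "micron":
            raise ValueError(f"embryo {tbl.embryo_id!r} is not in micron units")
        if expr_column not in tbl.data.columns:
            raise ValueError(f"expression column {expr_column!r} absent from "
                             f"embryo {tbl.embryo_id!r}")
        e = tbl.data[expr_column].to_numpy(dtype=float)
        z = tbl.data["z"].to_numpy(dtype=float)
        mask = np.isfinite(e) & (e > 0)
        if mask.any():
            ids.append(tbl.embryo_id)
            zs.append(z[mask])
            ys.append(np.log(e[mask]))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate embryo ids among replicates")
    n = int(sum(len(z) for z in zs))
    if n < _MIN_POINTS:
        raise ValueError(f"only {n} usable positive-expression points; "
                         f"need >= {_MIN_POINTS}")
    z_all = np.concatenate(zs)
    if np.ptp(z_all) <= 0:
        raise ValueError("no depth range: all z values identical")

    # Design: one intercept column per embryo + depth column; slope on z = -k.
    y = np.concatenate(ys)
    X = np.zeros((n, len(ids) + 1))
    start = 0
    for i, z in enumerate(zs):
        X[start:start + len(z), i] = 1.0
        start += len(z)
    X[:, -1] = z_all
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    k = -float(coef[-1])
    scales = {eid: float(coef[i]) for i, eid in enumerate(ids)}
    return DepthModel(
        decay_rate=k,
        per_embryo_scale=scales,
        z_ref=float(z_ref),
        expr_column=expr_column,
        n_points_fit=n,
    )


def apply_depth_model(table: EmbryoTable, model: DepthModel) -> EmbryoTable:
    """Correct expression to the model's reference depth.

    The corrected values replace ``model.expr_column``; the raw values are
    preserved under a ``_raw`` suffix.  The multiplicative factor is defined
    for any expression value, so zero/negative rows are corrected too.
    Positions are unchanged.
    """
    col = model.expr_column
    if col not in table.data.columns:
        raise ValueError(f"expression column {col!r} absent from embryo "
                         f"{table.embryo_id!r}")
    if table.units != "micron":
        raise ValueError("apply_depth_model requires micron coordinates")
    df = table.data.copy()
    raw_col = col + "_raw"
    df[raw_col] = df[col]
    factor = model.correction_factor(df["z"].to_numpy(dtype=float))
    df[col] = df[col].to_numpy(dtype=float) * factor
    expr_cols = tuple(table.expr_columns)
    if raw_col not in expr_cols:
        expr_cols = expr_cols + (raw_col,)
    return table.with_data(df, expr_columns=expr_cols)


def save_depth_model(model: DepthModel, path) -> None:
    model.save(path)


def load_depth_model(path) -> DepthModel:
    return DepthModel.load(path)
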