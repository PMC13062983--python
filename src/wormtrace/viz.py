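"""Plotting: 3D nuclear positions, expression-colored lineage trees, and
trajectory curves, with static export to PNG/SVG/PDF.

Conventions: lineage trees run with time increasing downward and leaves at
uniform x spacing in canonical sibling order (a left of p, etc.); expression
colors use a perceptually uniform sequential colormap with explicit min/max
clamping, and missing values render grey.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import LineCollection
from matplotlib.colors import Normalize

from .io_formats import EmbryoTable
from .lineage import is_descendant, parse_name, select_cells, sort_key

EXPORT_FORMATS = ("png", "svg", "pdf")
_MISSING_COLOR = "0.6"


@dataclass
class StyleSpec:
    """Styling for 3D plots and trees.

    ``color_column`` names the expression channel (or None for a constant
    color); values outside [color_min, color_max] are clamped, not
    overflowed.  ``highlight`` entries are (pattern, marker, color) triples
    drawn on top of the base markers.
    """

    color_column: Optional[str] = "blot"
    color_min: Optional[float] = None
    color_max: Optional[float] = None
    highlight: Tuple[Tuple[str, str, str], ...] = ()
    marker_size_mode: str = "constant"     # or "diameter"
    marker_size: float = 40.0
    colormap: str = "viridis"
    constant_color: str = "tab:blue"

    def __post_init__(self):
        if (
            self.color_min is not None
            and self.color_max is not None
            and not self.color_min < self.color_max
        ):
            raise ValueError("color_min must be < color_max")
        if self.marker_size_mode not in ("constant", "diameter"):
            raise ValueError(f"unknown marker_size_mode {self.marker_size_mode!r}")


def _color_limits(values: np.ndarray, style: StyleSpec) -> Tuple[float, float]:
    finite = values[np.isfinite(values)]
    lo = style.color_min if style.color_min is not None else (
        float(finite.min()) if finite.size else 0.0)
    hi = style.color_max if style.color_max is not None else (
        float(finite.max()) if finite.size else 1.0)
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def plot3d(table: EmbryoTable, time, style: Optional[StyleSpec] = None):
    """3D scatter of nuclei at one timepoint, one marker per cell.

    Colors map ``style.color_column`` with clamping; highlighted pattern
    selections are drawn on top with their own markers.  Axes are in the
    table's units with equal aspect ratio.
    """
    style = style or StyleSpec()
    sub = table.at_time(time)
    if len(sub) == 0:
        raise ValueError(f"time {time} absent from embryo {table.embryo_id!r}")
    xs, ys, zs = (sub[c].to_numpy(dtype=float) for c in ("x", "y", "z"))

    if style.marker_size_mode == "diameter" and "diameter" in sub.columns:
        d = sub["diameter"].to_numpy(dtype=float)
        d = np.where(np.isfinite(d), d, np.nanmean(d) if np.isfinite(d).any() else 8.0)
        sizes = (d / max(d.max(), 1e-9)) ** 2 * style.marker_size * 4
    else:
        sizes = np.full(len(sub), style.marker_size)

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    if style.color_column is not None and style.color_column in sub.columns:
        vals = sub[style.color_column].to_numpy(dtype=float)
        lo, hi = _color_limits(vals, style)
        have = np.isfinite(vals)
        clipped = np.clip(vals[have], lo, hi)
        ax.scatter(xs[have], ys[have], zs[have], c=clipped, s=sizes[have],
                   cmap=style.colormap, vmin=lo, vmax=hi, depthshade=False)
        if (~have).any():
            ax.scatter(xs[~have], ys[~have], zs[~have], c=_MISSING_COLOR,
                       s=sizes[~have], depthshade=False)
    else:
        ax.scatter(xs, ys, zs, c=style.constant_color, s=sizes, depthshade=False)

    for pattern, marker, color in style.highlight:
        names = select_cells(table, [pattern], include_descendants=False)
        mask = sub["cell"].astype(str).isin(names).to_numpy()
        if mask.any():
            ax.scatter(xs[mask], ys[mask], zs[mask], marker=marker, c=color,
                       s=sizes[mask] * 1.8, depthshade=False)

    unit = "μm" if table.units == "micron" else "px"
    ax.set_xlabel(f"x ({unit})")
    ax.set_ylabel(f"y ({unit})")
    ax.set_zlabel(f"z ({unit if table.units == 'micron' else 'planes'})")
    ax.set_title(f"{table.embryo_id} @ t={time}")
    spans = [max(float(np.ptp(v)), 1e-9) for v in (xs, ys, zs)]
    ax.set_box_aspect(spans)
    return fig


# ---------------------------------------------------------------------------
# Lineage trees
# ---------------------------------------------------------------------------

@dataclass
class TreeLayout:
    """Geometric layout of a lineage tree: leaf-order x positions, vertical
    lifetime spans, and parent->children links over observed cells."""

    root: str
    x: Dict[str, float]
    span: Dict[str, Tuple[float, float]]     # (birth, last-seen) in window
    children: Dict[str, List[str]]
    window: Tuple[float, float]

    @property
    def leaves(self) -> List[str]:
        return sorted((c for c in self.x if not self.children.get(c)),
                      key=lambda c: self.x[c])


def build_tree_layout(table: EmbryoTable, root, t_start=None, t_end=None) -> TreeLayout:
    """Lay out the lineage tree rooted at ``root`` restricted to
    [t_start, t_end].

    Each observed descendant attaches to its nearest observed ancestor (so
    tracking gaps do not break the tree); leaves get uniform x positions in
    canonical sibling order and each parent sits at the midpoint of its
    daughters' x range.
    """
    root = str(root)
    df = table.data
    t = df["time"].to_numpy(dtype=float)
    t0 = float(t.min()) if t_start is None else float(t_start)
    t1 = float(t.max()) if t_end is None else float(t_end)
    windowed = df[(t >= t0) & (t <= t1)]

    root_name = parse_name(root)
    members: List[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cell in sorted(set(windowed["cell"].astype(str))):
            if cell == root or (
                not parse_name(cell).is_literal
                and not root_name.is_literal
                and is_descendant(cell, root)
            ):
                members.append(cell)
    if not members:
        raise ValueError(
            f"root {root!r} (and descendants) never observed in window "
            f"[{t0}, {t1}] of embryo {table.embryo_id!r}"
        )

    member_set = set(members)
    children: Dict[str, List[str]] = {m: [] for m in members}
    tree_root = root if root in member_set else None
    orphans: List[str] = []
    for cell in members:
        if cell == root:
            continue
        # climb to the nearest observed ancestor
        parent = None
        current = parse_name(cell)
        from .lineage import LineageName, parent_of
        anc = parent_of(current)
        while isinstance(anc, LineageName):
            if anc.text in member_set:
                parent = anc.text
                break
            if anc.text == root:
                break
            anc = parent_of(anc)
        if parent is not None:
            children[parent].append(cell)
        else:
            orphans.append(cell)
    if tree_root is None:
        # root itself unobserved: hang orphans under a virtual root
        tree_root = root
        children[root] = orphans
    else:
        children[root] = children.get(root, []) + orphans

    for kids in children.values():
        kids.sort(key=sort_key)

    span: Dict[str, Tuple[float, float]] = {}
    grouped = windowed.groupby(windowed["cell"].astype(str))["time"]
    mins, maxs = grouped.min(), grouped.max()
    for m in members:
        span[m] = (float(mins[m]), float(maxs[m]))

    x: Dict[str, float] = {}
    counter = [0.0]

    def assign(cell: str) -> float:
        kids = children.get(cell, [])
        if not kids:
            x[cell] = counter[0]
            counter[0] += 1.0
        else:
            xs = [assign(k) for k in kids]
            x[cell] = (min(xs) + max(xs)) / 2.0
        return x[cell]

    assign(tree_root)
    if tree_root not in member_set:
        x.pop(tree_root, None)
    return TreeLayout(root=root, x=x, span=span, children=children, window=(t0, t1))


def tree_segments(
    layout: TreeLayout,
    table: EmbryoTable,
    expr_column: Optional[str] = "blot",
) -> List[Tuple[str, float, float, float]]:
    """One colored sub-segment per observed (cell, time) row in the window:
    (cell, t_from, t_to, value).  The value is the expression at t_from
    (NaN when missing or no column)."""
    df = table.data
    t = df["time"].to_numpy(dtype=float)
    t0, t1 = layout.window
    windowed = df[(t >= t0) & (t <= t1)]
    has_expr = expr_column is not None and expr_column in df.columns
    out: List[Tuple[str, float, float, float]] = []
    for cell in layout.x:
        sub = windowed[windowed["cell"].astype(str) == cell].sort_values("time")
        times = sub["time"].to_numpy(dtype=float)
        if times.size == 0:
            continue
        vals = (sub[expr_column].to_numpy(dtype=float) if has_expr
                else np.full(times.size, np.nan))
        kids = layout.children.get(cell, [])
        if kids:
            t_last = min(layout.span[k][0] for k in kids if k in layout.span)
        else:
            t_last = times[-1]
        for i, ti in enumerate(times):
            tj = times[i + 1] if i + 1 < times.size else max(t_last, ti)
            out.append((cell, float(ti), float(tj), float(vals[i])))
    return out


def render_tree(
    layout: TreeLayout,
    table: EmbryoTable,
    expr_column: Optional[str] = "blot",
    style: Optional[StyleSpec] = None,
):
    """Render a lineage tree colored per timepoint by expression.

    Vertical segments span each cell's observed lifetime (time increases
    downward); horizontal connectors join parents to daughters at division.
    Save through :func:`export_figure` with an ``.svg`` path for vector
    output.  A missing expression column produces a monochrome tree with a
    warning.
    """
    style = style or StyleSpec(color_column=expr_column)
    have_expr = expr_column is not None and expr_column in table.data.columns
    if not have_expr and expr_column is not None:
        warnings.warn(
            f"expression column {expr_column!r} absent; rendering a "
            "monochrome tree", stacklevel=2)
    segs = tree_segments(layout, table, expr_column if have_expr else None)

    fig, ax = plt.subplots(figsize=(max(4.0, 0.35 * max(len(layout.x), 1)), 5))
    lines = [((layout.x[c], a), (layout.x[c], b)) for c, a, b, _ in segs]
    values = np.array([v for _, _, _, v in segs])

    if have_expr and np.isfinite(values).any():
        lo, hi = _color_limits(values, style)
        cmap = matplotlib.colormaps[style.colormap]
        norm = Normalize(vmin=lo, vmax=hi)
        colors = [
            cmap(norm(np.clip(v, lo, hi))) if np.isfinite(v)
            else matplotlib.colors.to_rgba(_MISSING_COLOR)
            for v in values
        ]
        lc = LineCollection(lines, colors=colors, linewidths=3)
        fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax,
                     label=expr_column)
    else:
        lc = LineCollection(lines, colors="black", linewidths=3)
    ax.add_collection(lc)

    connectors = []
    for parent, kids in layout.children.items():
        if not kids or parent not in layout.x:
            continue
        t_div = min(layout.span[k][0] for k in kids if k in layout.span)
        xs = [layout.x[k] for k in kids] + [layout.x[parent]]
        connectors.append(((min(xs), t_div), (max(xs), t_div)))
        for k in kids:
            connectors.append(((layout.x[k], t_div), (layout.x[k], layout.span[k][0])))
    if connectors:
        ax.add_collection(LineCollection(connectors, colors="black", linewidths=1))

    for leaf in layout.leaves:
        ax.annotate(leaf, (layout.x[leaf], layout.window[1]),
                    rotation=90, ha="center", va="top", fontsize=7,
                    annotation_clip=False)
    ax.set_xlim(-1, max(layout.x.values(), default=0) + 1)
    ax.set_ylim(layout.window[0] - 1, layout.window[1] + 1)
    ax.invert_yaxis()
    ax.set_ylabel(f"time ({table.time_units})")
    ax.set_xticks([])
    ax.set_title(f"{table.embryo_id}: {layout.root} lineage")
    return fig


def plot_trajectories(trajectory: pd.DataFrame, by: str = "embryo_id"):
    """Expression-versus-time curves from a trajectory table (one line per
    embryo or per condition; gaps where timepoints are missing)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in trajectory.groupby(by):
        grp = grp.sort_values("time")
        ax.plot(grp["time"], grp["mean_expression"], marker="o", ms=3, label=str(label))
    ax.set_xlabel("aligned time")
    ax.set_ylabel("mean expression")
    ax.legend(fontsize=8)
    return fig


def export_figure(fig, path, format: Optional[str] = None,
                  width: Optional[float] = None, height: Optional[float] = None,
                  dpi: int = 100) -> Path:
    """Export a figure to PNG, SVG or PDF.  ``width``/``height`` are pixels
    at ``dpi``; the file format defaults to the path suffix."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; use one of {EXPORT_FORMATS}")
    if width is not None and height is not None:
        fig.set_size_inches(width / dpi, height / dpi)
    fig.savefig(path, format=fmt, dpi=dpi)
    return path
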