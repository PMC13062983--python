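"""Synthetic tracked embryos with known ground truth.

Generates embryo tables that exercise the whole pipeline without external
data: a stereotyped division schedule over Sulston names, deterministic
cell placement inside an ellipsoid in a canonical frame (anterior +x, left
+y, dorsal +z), an arbitrary acquisition pose (proper rotation +
translation), and a reporter-expression program with exponential depth
attenuation and multiplicative lognormal noise.

Placement follows the name algebra: a daughter is displaced from its mother
along the axis implied by its division letter (a/p -> x, l/r -> y,
d/v -> z) with a step that shrinks each generation, so the default landmark
groups (posterior Cxp, dorsal Cxaa, right MSap, left MSpp) are geometrically
meaningful.  The division times and anchor positions are fixture constants
chosen to give a plausibly proportioned ~40-cell embryo, not biological
claims.

The stored ground-truth ``canonical`` table is the output of one
orientation fit+apply on the noise-placed embryo, so it is an exact fixed
point of :func:`wormtrace.geometry.fit_orientation` and the acquired table
maps onto it exactly through the ground-truth transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import lineage
from .geometry import DEFAULT_LANDMARKS, LandmarkGroups, RigidTransform, apply_transform, fit_orientation
from .io_formats import EmbryoTable
from .lineage import (FOUNDER_DAUGHTERS, match_pattern, parent_of,
                      parse_name, sort_key)

# Division time of each founder in the early chain (daughters appear at +1).
_CHAIN_DIVISIONS = {"P0": 2, "P1": 4, "EMS": 6, "P2": 6, "P3": 8, "P4": 10}

# First letter-division time and per-generation period for each letter founder.
_FIRST_DIVISION = {"AB": 8, "MS": 12, "E": 14, "C": 13, "D": 21}
_PERIOD = {"AB": 6, "MS": 6, "E": 8, "C": 6, "D": 8}

# Division-letter pair used at each generation (cycled when deeper).
_LETTERS_BY_GEN = {
    "AB": ("ap", "lr", "ap", "dv"),
    "MS": ("ap", "ap", "lr"),
    "E": ("ap", "lr"),
    "C": ("ap", "ap", "ap"),
    "D": ("ap",),
}

DEFAULT_FOUNDER_DEPTHS: Dict[str, int] = {"AB": 4, "MS": 3, "E": 2, "C": 3, "D": 1}

# Canonical-frame anchor positions (microns) for the early chain.
_ANCHORS = {
    "P0": (0.0, 0.0, 0.0),
    "AB": (11.0, 0.0, 0.0), "P1": (-8.0, 0.0, 0.0),
    "EMS": (-5.0, 0.0, -3.0), "P2": (-13.0, 0.0, 1.0),
    "MS": (-3.0, 0.0, -3.0), "E": (-8.0, 0.0, -5.0),
    "C": (-12.0, 0.0, 4.0), "P3": (-15.0, 0.0, 0.0),
    "D": (-14.0, 0.0, 2.0), "P4": (-16.0, 0.0, -1.0),
    "Z2": (-16.5, 1.0, -1.0), "Z3": (-16.5, -1.0, -1.0),
}

# Displacement overrides applied at birth (lifts MSa/MSp onto the left/right
# flanks at z ~ 0 so MSap / MSpp mark the LR axis cleanly).
_PLACEMENT_OVERRIDES = {"MSa": (0.0, -4.0, 3.0), "MSp": (0.0, 4.0, 3.0)}

_LETTER_DIRECTION = {
    "a": (1.0, 0.0, 0.0), "p": (-1.0, 0.0, 0.0),
    "l": (0.0, 1.0, 0.0), "r": (0.0, -1.0, 0.0),
    "d": (0.0, 0.0, 1.0), "v": (0.0, 0.0, -1.0),
}

_STEP0 = 5.0
_STEP_SHRINK = 0.6


def default_schedule(
    founder_depths: Optional[Mapping[str, int]] = None,
    t_end: int = 34,
    first_division: Optional[Mapping[str, int]] = None,
    periods: Optional[Mapping[str, int]] = None,
) -> Dict[str, int]:
    """Build the stereotyped division schedule: cell name -> division time.

    Cells absent from the schedule persist until ``t_end``.  A division at
    time t produces daughters at t+1; divisions that would bear daughters
    after ``t_end`` are dropped (the mother becomes a leaf).
    """
    depths = dict(DEFAULT_FOUNDER_DEPTHS if founder_depths is None else founder_depths)
    first = {**_FIRST_DIVISION, **(first_division or {})}
    period = {**_PERIOD, **(periods or {})}
    schedule: Dict[str, int] = {}
    for name, t_div in _CHAIN_DIVISIONS.items():
        if t_div + 1 <= t_end:
            schedule[name] = t_div

    def expand(name: str, founder: str, gen: int) -> None:
        depth = depths.get(founder, 0)
        if gen >= depth:
            return
        t_div = first[founder] + period[founder] * gen
        if t_div + 1 > t_end:
            return
        schedule[name] = t_div
        pair = _LETTERS_BY_GEN.get(founder, ("ap",))
        for letter in pair[gen % len(pair)]:
            expand(name + letter, founder, gen + 1)

    for founder in depths:
        if founder in _FIRST_DIVISION or founder in first:
            expand(founder, founder, 0)
    return schedule


def _lineage_depth(name: str) -> int:
    depth = 0
    current = parse_name(name)
    while True:
        parent = parent_of(current)
        if not isinstance(parent, lineage.LineageName):
            return depth
        depth += 1
        current = parent


def _expand_tree(schedule: Mapping[str, int], t_end: int):
    """Births/deaths implied by a schedule, from P0 at t=1."""
    births: Dict[str, int] = {}
    deaths: Dict[str, int] = {}
    stack = [("P0", 1)]
    while stack:
        name, born = stack.pop()
        if born > t_end:
            continue
        t_div = schedule.get(name)
        if t_div is not None and t_div + 1 <= born:
            raise ValueError(
                f"schedule violates parent-before-daughter at {name!r}: "
                f"born {born}, divides {t_div}"
            )
        births[name] = born
        if t_div is None or t_div >= t_end:
            deaths[name] = t_end
            continue
        deaths[name] = t_div
        n = parse_name(name)
        if not n.suffix and n.founder in FOUNDER_DAUGHTERS:
            daughters = FOUNDER_DAUGHTERS[n.founder]
        else:
            # Division letters: scheduled daughters win (explicit user
            # schedules), else the founder's per-generation letter cycle.
            candidates = [name + ch for ch in lineage.DIVISION_LETTERS]
            scheduled = [c for c in candidates if c in schedule]
            if scheduled:
                pair = {"a": "ap", "p": "ap", "l": "lr", "r": "lr", "d": "dv", "v": "dv"}
                daughters = tuple(name + ch for ch in pair[scheduled[0][-1]])
            else:
                cycle = _LETTERS_BY_GEN.get(n.founder, ("ap",))
                letters = cycle[len(n.suffix) % len(cycle)]
                daughters = tuple(name + ch for ch in letters)
        for d in daughters:
            stack.append((d, t_div + 1))
    return births, deaths


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic embryo (see module docstring for
    what the defaults emulate)."""

    founder_depths: Optional[Mapping[str, int]] = None
    t_end: int = 34
    schedule: Optional[Mapping[str, int]] = None
    half_axes: Tuple[float, float, float] = (25.0, 15.0, 15.0)
    #: acquisition pose as (rotation matrix, translation); None = random draw
    orientation: Optional[Tuple[np.ndarray, np.ndarray]] = None
    #: (pattern, onset time, level): cells in the pattern's lineage express
    #: `level` from `onset` onward; others stay at `baseline_level`
    expression_program: Tuple[Tuple[str, float, float], ...] = (("MS", 13.0, 300.0),)
    baseline_level: float = 20.0
    decay_rate: float = 0.04          # 1/micron
    noise_sigma: float = 0.1          # lognormal sigma on the log scale
    position_jitter_sigma: float = 0.3  # microns, per cell at birth
    min_depth: float = 2.0            # shallowest nucleus depth, acquired frame
    t_ref: Optional[int] = None       # orientation reference time; None = t_end
    landmarks: Optional[LandmarkGroups] = DEFAULT_LANDMARKS
    canonicalize: bool = True


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    canonical: EmbryoTable
    transform: RigidTransform      # maps acquired coordinates -> canonical
    decay_rate: float
    schedule: Dict[str, int]
    births: Dict[str, int]
    deaths: Dict[str, int]
    seed: int
    params: SimulationParams

    def cells_alive(self, t: int) -> Set[str]:
        return {c for c, b in self.births.items() if b <= t <= self.deaths[c]}


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, sign-fixed)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _base_positions(births: Mapping[str, int], rng, jitter: float) -> Dict[str, np.ndarray]:
    positions: Dict[str, np.ndarray] = {}
    for name in sorted(births, key=sort_key):
        n = parse_name(name)
        if not n.suffix:
            pos = np.array(_ANCHORS.get(name, (0.0, 0.0, 0.0)))
        else:
            mother = name[:-1]
            step = _STEP0 * _STEP_SHRINK ** (len(n.suffix) - 1)
            pos = positions[mother] + step * np.array(_LETTER_DIRECTION[name[-1]])
        pos = pos + np.array(_PLACEMENT_OVERRIDES.get(name, (0.0, 0.0, 0.0)))
        if jitter > 0:
            pos = pos + rng.normal(0.0, jitter, size=3)
        positions[name] = pos
    return positions


def _expression_level(name: str, t: float, params: SimulationParams) -> float:
    level = params.baseline_level
    n = parse_name(name)
    for pattern, onset, lvl in params.expression_program:
        if t < onset:
            continue
        current = n
        hit = False
        while isinstance(current, lineage.LineageName):
            if match_pattern(current, pattern):
                hit = True
                break
            current = parent_of(current)
        if hit:
            level = max(level, lvl)
    return level


def simulate_embryo(
    params: SimulationParams,
    seed: int,
    embryo_id: Optional[str] = None,
) -> Tuple[EmbryoTable, GroundTruth]:
    """Simulate one tracked embryo.

    Returns the table in the acquired frame (micron units, ordinal time)
    plus the :class:`GroundTruth` carrying the canonical-frame table, the
    acquisition transform, the true decay rate and the division schedule.
    Fixed ``seed`` gives byte-identical output.
    """
    rng = np.random.default_rng(seed)
    schedule = dict(params.schedule) if params.schedule is not None else default_schedule(
        params.founder_depths, params.t_end
    )
    births, deaths = _expand_tree(schedule, params.t_end)
    positions = _base_positions(births, rng, params.position_jitter_sigma)

    hx, hy, hz = params.half_axes
    for name, p in positions.items():
        if (p[0] / hx) ** 2 + (p[1] / hy) ** 2 + (p[2] / hz) ** 2 > 1.0:
            raise ValueError(f"cell {name!r} placed outside the embryo ellipsoid")

    names = sorted(births, key=sort_key)
    rows = []
    for t in range(1, params.t_end + 1):
        for name in names:
            if births[name] <= t <= deaths[name]:
                x, y, z = positions[name]
                diameter = 8.0 * 0.85 ** _lineage_depth(name)
                rows.append((name, t, x, y, z, diameter))
    base = pd.DataFrame(rows, columns=["cell", "time", "x", "y", "z", "diameter"])
    t_ref = params.t_ref if params.t_ref is not None else params.t_end
    eid = embryo_id if embryo_id is not None else f"sim{seed}"
    table = EmbryoTable(
        data=base, embryo_id=eid, units="micron", time_units="ordinal",
        expr_columns=(),
    )

    if params.canonicalize:
        if params.landmarks is None:
            raise ValueError("canonicalize=True requires landmark groups")
        tf0 = fit_orientation(table, t_ref, params.landmarks)
        canonical = apply_transform(table, tf0, scope="all")
    else:
        canonical = table

    if params.orientation is not None:
        Q = np.asarray(params.orientation[0], dtype=float)
        t_vec = np.asarray(params.orientation[1], dtype=float).copy()
    else:
        Q = random_rotation(rng)
        t_vec = rng.uniform(-15.0, 15.0, size=3)
    pts = canonical.data[["x", "y", "z"]].to_numpy(dtype=float)
    acq = pts @ Q.T + t_vec
    # lift the stack so the shallowest nucleus sits at min_depth
    shift = params.min_depth - acq[:, 2].min()
    t_vec[2] += shift
    acq[:, 2] += shift

    acq_df = canonical.data.copy()
    acq_df[["x", "y", "z"]] = acq

    # expression: programmed level, attenuated by acquired depth, noised
    levels = np.array([
        _expression_level(c, t, params)
        for c, t in zip(acq_df["cell"], acq_df["time"])
    ])
    noise = (
        rng.lognormal(mean=0.0, sigma=params.noise_sigma, size=len(acq_df))
        if params.noise_sigma > 0 else np.ones(len(acq_df))
    )
    blot = levels * np.exp(-params.decay_rate * acq[:, 2]) * noise
    acq_df["blot"] = blot
    can_df = canonical.data.copy()
    can_df["blot"] = blot

    order = ["cell", "time", "x", "y", "z", "blot", "diameter"]
    acquired_table = EmbryoTable(
        data=acq_df[order].reset_index(drop=True), embryo_id=eid,
        units="micron", time_units="ordinal", expr_columns=("blot",),
    )
    canonical_table = EmbryoTable(
        data=can_df[order].reset_index(drop=True), embryo_id=eid,
        units="micron", time_units="ordinal", expr_columns=("blot",),
    )
    truth = GroundTruth(
        canonical=canonical_table,
        transform=RigidTransform(center=t_vec, rotation=Q.T, reference_time=t_ref),
        decay_rate=params.decay_rate,
        schedule=schedule,
        births=births,
        deaths=deaths,
        seed=seed,
        params=params,
    )
    return acquired_table, truth


def simulate_replicates(
    params: SimulationParams,
    n: int,
    seeds: Optional[Sequence[int]] = None,
    id_prefix: str = "rep",
) -> List[Tuple[EmbryoTable, GroundTruth]]:
    """Independent replicate embryos sharing the schedule and decay rate but
    drawing their own acquisition pose, jitter and noise."""
    if n < 1:
        raise ValueError("need n >= 1 replicates")
    if seeds is None:
        seeds = list(range(n))
    if len(seeds) != n:
        raise ValueError("len(seeds) must equal n")
    return [
        simulate_embryo(params, seed, embryo_id=f"{id_prefix}{i:02d}")
        for i, seed in enumerate(seeds)
    ]


def random_table(
    rng: np.random.Generator,
    n_cells: int = 12,
    n_times: int = 5,
    expr_columns: Tuple[str, ...] = ("blot",),
    literal_frac: float = 0.2,
    missing_frac: float = 0.1,
    embryo_id: str = "random",
) -> EmbryoTable:
    """A random but valid pixel/ordinal table (random Sulston names plus some
    literal labels, sparse observation, occasional missing expression) for
    round-trip and invariance tests."""
    founders = ("AB", "MS", "E", "C", "D")
    cells: List[str] = []
    while len(cells) < n_cells:
        if rng.random() < literal_frac:
            name = f"Nuc{rng.integers(1, 999)}"
        else:
            founder = founders[rng.integers(len(founders))]
            depth = int(rng.integers(0, 6))
            name = founder + "".join(
                lineage.DIVISION_LETTERS[rng.integers(6)] for _ in range(depth)
            )
        if name not in cells:
            cells.append(name)
    rows = []
    for cell in cells:
        t0 = int(rng.integers(1, n_times + 1))
        t1 = int(rng.integers(t0, n_times + 1))
        for t in range(t0, t1 + 1):
            vals = {
                col: (np.nan if rng.random() < missing_frac
                      else float(rng.uniform(0.0, 5000.0)))
                for col in expr_columns
            }
            rows.append({
                "cell": cell, "time": t,
                "x": float(rng.uniform(0, 512)),
                "y": float(rng.uniform(0, 512)),
                "z": float(rng.uniform(0, 30)),
                **vals,
            })
    df = pd.DataFrame(rows, columns=["cell", "time", "x", "y", "z", *expr_columns])
    return EmbryoTable(
        data=df, embryo_id=embryo_id, units="pixel", time_units="ordinal",
        expr_columns=expr_columns,
    )
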