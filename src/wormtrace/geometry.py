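"""Rigid-body orientation of embryos into a canonical anatomical frame.

Confocal stacks are acquired with the embryo in an arbitrary pose.  At a
chosen reference timepoint the long (anterior-posterior) axis is found by
PCA over all nuclear positions; user-specified landmark cell groups then fix
the sign of that axis and the roll about it.  Axis convention (stated here
because every downstream figure depends on it):

    anterior -> +x,  left -> +y,  dorsal -> +z   (right-handed frame)

Roll: each provided dorsal/ventral/left/right group yields one candidate
roll angle that would put its centroid on its target half-axis; the final
roll is the circular mean of the candidates, which minimizes the summed
squared angular deviation for small spreads.  Ventral and right groups enter
as dorsal/left candidates rotated by pi.

The resulting transform maps raw micron coordinates ``p`` to canonical ones
via ``R @ (p - center)`` and can be applied to the reference timepoint only
or to every timepoint (full-embryo rotation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import FormatError
from .io_formats import EmbryoTable
from .lineage import select_cells

_ORTHO_TOL = 1e-9


def wrap_angle(a):
    """Wrap angle(s) to [-pi, pi)."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


def circular_mean(angles: Sequence[float]) -> float:
    """Circular mean of angles in radians, in [-pi, pi)."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular_mean of empty sequence")
    return float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))))


def _rot_x(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector ``a`` onto unit vector ``b``."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-15:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees: rotate about any axis perpendicular to a
        helper = np.array([0.0, 0.0, 1.0])
        if abs(a[2]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(a, helper)
        n /= np.linalg.norm(n)
        return 2.0 * np.outer(n, n) - np.eye(3)
    n = np.cross(a, b)
    s = np.linalg.norm(n)
    n = n / s
    theta = np.arctan2(s, c)
    K = np.array([[0, -n[2], n[1]], [n[2], 0, -n[0]], [-n[1], n[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


@dataclass(frozen=True, eq=False)
class RigidTransform:
    """Centering translation + proper rotation fitted at ``reference_time``.

    Maps raw coordinates p to canonical ones: ``rotation @ (p - center)``.
    """

    center: np.ndarray
    rotation: np.ndarray
    reference_time: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float).reshape(3, 3))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation matrix is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation matrix is not proper (det != +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (self.rotation @ (points - self.center).T).T

    def inverse(self) -> "RigidTransform":
        """Transform undoing this one.

        The forward map is p -> R (p - c); its inverse R^T p + c equals
        R^T (p - (-R c)) in the same (center, rotation) parameterization.
        """
        return RigidTransform(
            center=-(self.rotation @ self.center),
            rotation=self.rotation.T,
            reference_time=self.reference_time,
        )

    def is_identity(self, tol: float = 1e-6) -> bool:
        return (
            np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.center, 0.0, atol=tol)
        )

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        lines = ["wormtrace-rigid-transform v1",
                 "reference_time: %.17g" % self.reference_time,
                 "center: " + " ".join("%.17g" % v for v in self.center)]
        for i in range(3):
            lines.append("rotation_row%d: " % i + " ".join("%.17g" % v for v in self.rotation[i]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0].strip() != "wormtrace-rigid-transform v1":
            raise FormatError(f"{path}: not a wormtrace rigid-transform file")
        kv = {}
        for line in lines[1:]:
            if ":" in line:
                key, val = line.split(":", 1)
                kv[key.strip()] = val.strip()
        try:
            t_ref = float(kv["reference_time"])
            center = np.array([float(v) for v in kv["center"].split()])
            rotation = np.array(
                [[float(v) for v in kv["rotation_row%d" % i].split()] for i in range(3)]
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: truncated or malformed transform file") from exc
        return cls(center=center, rotation=rotation, reference_time=t_ref)


@dataclass(frozen=True)
class LandmarkGroups:
    """Lineage-pattern groups marking anatomical directions at the reference
    time.  At least one of anterior/posterior fixes the AP sign; at least one
    of dorsal/ventral/left/right fixes the roll."""

    anterior: Tuple[str, ...] = ()
    posterior: Tuple[str, ...] = ()
    dorsal: Tuple[str, ...] = ()
    ventral: Tuple[str, ...] = ()
    left: Tuple[str, ...] = ()
    right: Tuple[str, ...] = ()

    def __post_init__(self):
        for name in ("anterior", "posterior", "dorsal", "ventral", "left", "right"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if not (self.anterior or self.posterior):
            raise ValueError("need an anterior or posterior landmark group (AP sign)")
        if not (self.dorsal or self.ventral or self.left or self.right):
            raise ValueError("need a dorsal/ventral/left/right landmark group (roll)")


#: The default landmark groups: posterior C granddaughters, dorsal Cxaa cells,
#: and the left/right MS granddaughter pair.
DEFAULT_LANDMARKS = LandmarkGroups(
    posterior=("Cxp",), dorsal=("Cxaa",), right=("MSap",), left=("MSpp",)
)

# Target direction angle in the y-z plane (phi = atan2(z, y)) for each roll
# group: left -> +y, dorsal -> +z, right -> -y, ventral -> -z.
_ROLL_TARGETS = {
    "left": 0.0,
    "dorsal": np.pi / 2,
    "right": np.pi,
    "ventral": -np.pi / 2,
}


def _group_centroid(table: EmbryoTable, t_ref, patterns, label: str) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        members = select_cells(table, patterns, include_descendants=True)
    at_t = table.at_time(t_ref)
    present = at_t[at_t["cell"].astype(str).isin(members)]
    if len(present) == 0:
        raise ValueError(
            f"landmark group {label!r} ({', '.join(patterns)}) resolves to no "
            f"observed cell at time {t_ref}"
        )
    return present[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0)


def fit_orientation(
    table: EmbryoTable,
    t_ref=None,
    groups: Optional[LandmarkGroups] = None,
) -> RigidTransform:
    """Fit the canonical-orientation transform at ``t_ref``.

    PCA over all nuclear positions at ``t_ref`` gives the AP axis; the
    anterior/posterior group fixes its sign (anterior = +x); provided roll
    groups are combined by circular mean as described in the module
    docstring.  ``t_ref`` defaults to the last timepoint.
    """
    if table.units != "micron":
        raise ValueError("fit_orientation requires micron coordinates "
                         "(run apply_metadata first)")
    if groups is None:
        groups = DEFAULT_LANDMARKS
    if t_ref is None:
        t_ref = table.times()[-1]
    at_t = table.at_time(t_ref)
    if len(at_t) == 0:
        raise ValueError(f"no cells at reference time {t_ref}")
    P = at_t[["x", "y", "z"]].to_numpy(dtype=float)
    if len(P) < 4:
        raise ValueError(f"need >= 4 cells at time {t_ref}, found {len(P)}")
    center = P.mean(axis=0)
    X = P - center
    cov = X.T @ X
    eigvals, eigvecs = np.linalg.eigh(cov)
    lam = eigvals[::-1]          # descending
    if lam[0] <= 0 or (lam[0] - lam[1]) <= 1e-6 * lam[0]:
        raise ValueError("ambiguous long axis: two leading principal "
                         "components have (nearly) equal variance")
    u = eigvecs[:, -1]

    # AP sign from anterior/posterior landmark centroids
    ant = _group_centroid(table, t_ref, groups.anterior, "anterior") if groups.anterior else None
    post = _group_centroid(table, t_ref, groups.posterior, "posterior") if groups.posterior else None
    if ant is not None and post is not None:
        ref = float(np.dot(ant - post, u))
    elif ant is not None:
        ref = float(np.dot(ant - center, u))
    else:
        ref = -float(np.dot(post - center, u))
    if ref == 0.0:
        raise ValueError("anterior/posterior landmarks project to zero on the "
                         "long axis; AP sign is ambiguous")
    if ref < 0:
        u = -u

    R1 = _rotation_between(u, np.array([1.0, 0.0, 0.0]))

    # Roll candidates from each provided group
    candidates = []
    for label in ("dorsal", "ventral", "left", "right"):
        patterns = getattr(groups, label)
        if not patterns:
            continue
        gc = _group_centroid(table, t_ref, patterns, label)
        q = R1 @ (gc - center)
        if np.hypot(q[1], q[2]) < 1e-12:
            raise ValueError(f"landmark group {label!r} lies on the AP axis; "
                             "roll is undefined")
        phi = np.arctan2(q[2], q[1])
        candidates.append(float(wrap_angle(_ROLL_TARGETS[label] - phi)))
    theta = circular_mean(candidates)
    R = _rot_x(theta) @ R1
    return RigidTransform(center=center, rotation=R, reference_time=t_ref)


def apply_transform(table: EmbryoTable, tf: RigidTransform, scope: str = "all") -> EmbryoTable:
    """Apply a rigid transform to a table.

    ``scope="all"`` rotates every timepoint (full-embryo rotation);
    ``scope="reference"`` rotates only rows at ``tf.reference_time``.  All
    non-position fields are unchanged; pairwise distances are preserved.
    """
    if table.units != "micron":
        raise ValueError("apply_transform requires micron coordinates")
    if scope not in ("all", "reference"):
        raise ValueError(f"unknown scope {scope!r} (use 'all' or 'reference')")
    df = table.data.copy()
    if scope == "reference":
        mask = (df["time"] == tf.reference_time).to_numpy()
        if not mask.any():
            raise ValueError(
                f"reference time {tf.reference_time} absent from embryo "
                f"{table.embryo_id!r}"
            )
    else:
        mask = np.ones(len(df), dtype=bool)
    pts = df.loc[mask, ["x", "y", "z"]].to_numpy(dtype=float)
    new = tf.apply(pts)
    df.loc[mask, "x"] = new[:, 0]
    df.loc[mask, "y"] = new[:, 1]
    df.loc[mask, "z"] = new[:, 2]
    return table.with_data(df)
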