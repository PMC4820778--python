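"""Per-branch geometry and per-specimen aggregation.

Each branch of a traced villous tree yields:

* ``length`` — polyline length of the centerline (micrometers);
* ``tortuosity`` — centerline length divided by the straight-line distance
  between the branch's own endpoints (>= 1, exactly 1 for a straight branch);
* ``planar_angle`` — change of direction relative to the parent branch, in
  degrees in [0, 180]; the direction of a branch is the chord from its
  proximal to its distal endpoint (a local-tangent variant is available for
  sensitivity analysis); absent for the root branch, which has no previous
  branch;
* ``surface_area`` / ``volume`` — from the frustum model: each segment
  between consecutive center points is a truncated cone with end radii
  d/2; lateral surfaces only (end caps are internal cross-sections of a
  continuous villus).

Aggregation produces one value per specimen and terminal-distance order
(bT0-bT2): the unweighted arithmetic mean over all qualifying branches of
all that specimen's trees, absent when no branch qualifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ManifestError
from .tree_model import Branch, TreeRecord, VillousTree, terminal_distance_order

__all__ = [
    "BranchMetrics",
    "SpecimenAggregate",
    "branch_length",
    "chord_vector",
    "tangent_vector",
    "planar_branching_angle",
    "tortuosity",
    "frustum_surface_area",
    "frustum_volume",
    "mean_diameter",
    "measure_tree",
    "metrics_table",
    "aggregate_specimen",
    "aggregate_table",
]

METRIC_COLUMNS = {
    "mpa": "planar_angle_deg",
    "mt": "tortuosity",
    "ml": "length_um",
    "msa": "surface_um2",
    "mv": "volume_um3",
}


@dataclass(frozen=True)
class BranchMetrics:
    """Measurements of one branch; ``planar_angle`` is None for the root."""

    branch_id: str
    order: int
    planar_angle: float | None
    tortuosity: float
    length: float
    surface_area: float
    volume: float
    mean_diameter: float


@dataclass
class SpecimenAggregate:
    """Per-specimen means by terminal distance order.

    Each of ``mpa`` (angle), ``mt`` (tortuosity), ``ml`` (length), ``msa``
    (surface area) and ``mv`` (volume) maps order -> mean or None when no
    branch of that order contributed a defined value.
    """

    specimen_id: str
    group_label: str
    mpa: dict[int, float | None]
    mt: dict[int, float | None]
    ml: dict[int, float | None]
    msa: dict[int, float | None]
    mv: dict[int, float | None]
    branch_counts: dict[int, int]


def branch_length(branch: Branch) -> float:
    """Polyline length: sum of Euclidean distances between consecutive points."""
    return float(np.linalg.norm(np.diff(branch.xyz, axis=0), axis=1).sum())


def chord_vector(branch: Branch) -> np.ndarray:
    """Vector from the branch's proximal endpoint to its distal endpoint."""
    v = branch.xyz[-1] - branch.xyz[0]
    if np.linalg.norm(v) == 0.0:
        raise DegenerateGeometryError(
            f"branch {branch.branch_id}: coincident endpoints, chord undefined"
        )
    return v


def tangent_vector(branch: Branch, at_end: bool) -> np.ndarray:
    """Local direction at the distal (at_end=True) or proximal end."""
    v = branch.xyz[-1] - branch.xyz[-2] if at_end else branch.xyz[1] - branch.xyz[0]
    if np.linalg.norm(v) == 0.0:
        raise DegenerateGeometryError(
            f"branch {branch.branch_id}: zero-length end segment"
        )
    return v


def planar_branching_angle(
    branch: Branch, parent: Branch, convention: str = "chord"
) -> float:
    """Angle (degrees, [0, 180]) between a branch's direction and its parent's.

    0 means pure continuation with no change of direction.  With the default
    ``chord`` convention directions are endpoint-to-endpoint chords; with
    ``tangent`` they are the local segments meeting at the shared node.
    """
    if convention == "chord":
        u, v = chord_vector(parent), chord_vector(branch)
    elif convention == "tangent":
        u, v = tangent_vector(parent, at_end=True), tangent_vector(branch, at_end=False)
    else:
        raise ValueError(f"unknown angle convention {convention!r}")
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def tortuosity(branch: Branch) -> float:
    """Centerline length over the straight endpoint-to-endpoint distance (>= 1)."""
    chord = float(np.linalg.norm(branch.xyz[-1] - branch.xyz[0]))
    if chord == 0.0:
        raise DegenerateGeometryError(
            f"branch {branch.branch_id}: coincident endpoints, tortuosity undefined"
        )
    return branch_length(branch) / chord


def _segment_radii_heights(branch: Branch) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r = branch.diameters / 2.0
    h = np.linalg.norm(np.diff(branch.xyz, axis=0), axis=1)
    return r[:-1], r[1:], h


def frustum_surface_area(branch: Branch) -> float:
    """Lateral surface of the chain of conical frusta (square micrometers).

    Per segment: pi (r1 + r2) s with slant s = sqrt(h^2 + (r1 - r2)^2).
    End caps are excluded, which makes the measure invariant under
    subdividing a straight, linearly tapering branch.
    """
    r1, r2, h = _segment_radii_heights(branch)
    slant = np.sqrt(h**2 + (r1 - r2) ** 2)
    return float(np.sum(np.pi * (r1 + r2) * slant))


def frustum_volume(branch: Branch) -> float:
    """Volume of the chain of conical frusta: sum of pi h/3 (r1^2 + r1 r2 + r2^2)."""
    r1, r2, h = _segment_radii_heights(branch)
    return float(np.sum(np.pi * h / 3.0 * (r1**2 + r1 * r2 + r2**2)))


def mean_diameter(branch: Branch) -> float:
    """Length-weighted mean diameter along the centerline.

    Each segment contributes its mean end diameter weighted by its length,
    so inserting interpolated samples on a straight taper leaves the value
    unchanged.
    """
    d1 = branch.diameters[:-1]
    d2 = branch.diameters[1:]
    h = np.linalg.norm(np.diff(branch.xyz, axis=0), axis=1)
    return float(np.sum((d1 + d2) / 2.0 * h) / np.sum(h))


def measure_tree(
    tree: VillousTree, angle_convention: str = "chord"
) -> list[BranchMetrics]:
    """Measure every branch; angle is taken against the parent branch.

    The root branch has no previous branch, so its angle is absent (None)
    rather than an error.
    """
    orders = terminal_distance_order(tree)
    out = []
    for bid in sorted(tree.branches):
        b = tree.branches[bid]
        try:
            angle = (
                None
                if b.parent_id is None
                else planar_branching_angle(
                    b, tree.branches[b.parent_id], angle_convention
                )
            )
            out.append(
                BranchMetrics(
                    branch_id=bid,
                    order=orders[bid],
                    planar_angle=angle,
                    tortuosity=tortuosity(b),
                    length=branch_length(b),
                    surface_area=frustum_surface_area(b),
                    volume=frustum_volume(b),
                    mean_diameter=mean_diameter(b),
                )
            )
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(
                f"tree {tree.tree_id}: {exc}"
            ) from exc
    return out


def metrics_table(
    records: list[TreeRecord], angle_convention: str = "chord"
) -> pd.DataFrame:
    """Per-branch metrics for a cohort, one row per branch.

    Columns: specimen_id, group, tree_id, branch_id, order, planar_angle_deg,
    tortuosity, length_um, surface_um2, volume_um3, mean_diameter_um.
    """
    rows = []
    for rec in records:
        for m in measure_tree(rec.tree, angle_convention):
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "group": rec.group_label,
                    "tree_id": rec.tree.tree_id,
                    "branch_id": m.branch_id,
                    "order": m.order,
                    "planar_angle_deg": m.planar_angle,
                    "tortuosity": m.tortuosity,
                    "length_um": m.length,
                    "surface_um2": m.surface_area,
                    "volume_um3": m.volume,
                    "mean_diameter_um": m.mean_diameter,
                }
            )
    return pd.DataFrame(rows)


def aggregate_specimen(
    records: list[TreeRecord],
    orders: tuple[int, ...] = (0, 1, 2),
    angle_convention: str = "chord",
) -> SpecimenAggregate:
    """Aggregate all trees of one specimen into per-order means.

    For each order k and metric, the unweighted arithmetic mean over all
    branches of order k across the specimen's trees, skipping absent values
    (a root branch contributes no angle).  A mean is None when no branch
    qualifies — e.g. a tree too small to contain bT2 branches.
    """
    specimen_ids = {r.specimen_id for r in records}
    if len(specimen_ids) != 1:
        raise ManifestError(f"records span several specimens: {sorted(specimen_ids)}")
    groups = {r.group_label for r in records}
    if len(groups) != 1:
        raise ManifestError(
            f"specimen {specimen_ids.pop()}: conflicting group labels {sorted(groups)}"
        )
    df = metrics_table(records, angle_convention)
    agg: dict[str, dict[int, float | None]] = {k: {} for k in METRIC_COLUMNS}
    counts: dict[int, int] = {}
    for k in orders:
        sub = df[df["order"] == k]
        counts[k] = len(sub)
        for short, col in METRIC_COLUMNS.items():
            vals = sub[col].dropna() if len(sub) else sub.get(col, pd.Series(dtype=float))
            agg[short][k] = float(vals.mean()) if len(vals) else None
    return SpecimenAggregate(
        specimen_id=records[0].specimen_id,
        group_label=records[0].group_label,
        mpa=agg["mpa"],
        mt=agg["mt"],
        ml=agg["ml"],
        msa=agg["msa"],
        mv=agg["mv"],
        branch_counts=counts,
    )


def aggregate_table(
    records: list[TreeRecord],
    orders: tuple[int, ...] = (0, 1, 2),
    angle_convention: str = "chord",
) -> pd.DataFrame:
    """One row per specimen with columns like mpa_bT0 ... mv_bT2 and n_bT<k>."""
    by_spec: dict[str, list[TreeRecord]] = {}
    for r in records:
        by_spec.setdefault(r.specimen_id, []).append(r)
    rows = []
    for sid in sorted(by_spec):
        a = aggregate_specimen(by_spec[sid], orders, angle_convention)
        row: dict[str, object] = {"specimen_id": sid, "group": a.group_label}
        for short in METRIC_COLUMNS:
            d = getattr(a, short)
            for k in orders:
                row[f"{short}_bT{k}"] = d[k]
        for k in orders:
            row[f"n_bT{k}"] = a.branch_counts[k]
        rows.append(row)
    return pd.DataFrame(rows)
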