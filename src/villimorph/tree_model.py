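"""Domain model for traced villous trees.

A peripheral villous tree is traced as a chain of 3D center points with
diameters.  Points where the centerline splits (degree >= 3) are *nodes*;
maximal node-free point chains are *branches*.  A branch either ends at a
node or at a free distal tip (a *terminal end*).  The proximal cut end where
tracing started is the *root* and never counts as a terminal end.

Branches are classified by *terminal distance order* (``bT``): the minimum
number of nodes between the branch's distal end and the nearest terminal end
of the tree.  ``bT0`` branches are in terminal position, ``bT1`` directly
preterminal, ``bT2`` two nodes away.

Trees are interchanged as SWC files (``id type x y z radius parent``,
coordinates and radii in micrometers); the model stores *diameters*
(2 x radius), since the villous literature reports branch diameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ManifestError, SWCFormatError, TreeStructureError

logger = logging.getLogger(__name__)

__all__ = [
    "SamplePoint",
    "Branch",
    "VillousTree",
    "TreeRecord",
    "read_swc",
    "write_swc",
    "terminal_distance_order",
    "read_manifest",
]


@dataclass(frozen=True)
class SamplePoint:
    """One traced center point with its local villus diameter (micrometers)."""

    x: float
    y: float
    z: float
    diameter: float

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("sample point coordinates must be finite")
        if not (math.isfinite(self.diameter) and self.diameter > 0):
            raise ValueError("sample point diameter must be positive and finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Branch:
    """A node-free chain of sample points, ordered proximal to distal.

    The first point of a non-root branch coincides with the last point of its
    parent branch (the shared node); consecutive points are never coincident.
    """

    branch_id: str
    xyz: np.ndarray          # (k, 3) float, k >= 2
    diameters: np.ndarray    # (k,) float, all > 0
    parent_id: str | None = None
    ends_terminal: bool = False

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError(f"branch {self.branch_id}: xyz must have shape (k, 3)")
        if self.diameters.shape != (self.xyz.shape[0],):
            raise ValueError(f"branch {self.branch_id}: one diameter per point required")
        if self.xyz.shape[0] < 2:
            raise ValueError(f"branch {self.branch_id}: at least 2 points required")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"branch {self.branch_id}: non-finite coordinates")
        if not np.all(self.diameters > 0):
            raise ValueError(f"branch {self.branch_id}: non-positive diameter")
        steps = np.linalg.norm(np.diff(self.xyz, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise ValueError(f"branch {self.branch_id}: coincident consecutive points")

    @property
    def n_points(self) -> int:
        return int(self.xyz.shape[0])

    @property
    def points(self) -> tuple[SamplePoint, ...]:
        return tuple(
            SamplePoint(*p, d) for p, d in zip(self.xyz, self.diameters)
        )

    @classmethod
    def from_points(
        cls,
        branch_id: str,
        points: Iterable[SamplePoint],
        parent_id: str | None = None,
        ends_terminal: bool = False,
    ) -> "Branch":
        pts = list(points)
        xyz = np.array([[p.x, p.y, p.z] for p in pts], dtype=float)
        diam = np.array([p.diameter for p in pts], dtype=float)
        return cls(branch_id, xyz, diam, parent_id, ends_terminal)


@dataclass
class VillousTree:
    """A rooted, acyclic collection of branches.

    Exactly one branch has no parent (the root branch, starting at the
    proximal cut end); every shared distal endpoint (node) has >= 2 child
    branches.
    """

    tree_id: str
    branches: dict[str, Branch]
    root_branch_id: str

    def __post_init__(self):
        self.validate()

    def children_of(self, branch_id: str) -> list[str]:
        return self._children.get(branch_id, [])

    def validate(self) -> None:
        roots = [b for b in self.branches.values() if b.parent_id is None]
        if len(roots) != 1 or roots[0].branch_id != self.root_branch_id:
            raise TreeStructureError(
                f"tree {self.tree_id}: exactly one parentless branch (the root) required"
            )
        children: dict[str, list[str]] = {}
        for b in self.branches.values():
            if b.parent_id is not None:
                if b.parent_id not in self.branches:
                    raise TreeStructureError(
                        f"tree {self.tree_id}: branch {b.branch_id} references "
                        f"missing parent {b.parent_id}"
                    )
                children.setdefault(b.parent_id, []).append(b.branch_id)
        # connectivity / acyclicity via traversal from the root
        seen: set[str] = set()
        stack = [self.root_branch_id]
        while stack:
            bid = stack.pop()
            if bid in seen:
                raise TreeStructureError(f"tree {self.tree_id}: cycle at branch {bid}")
            seen.add(bid)
            stack.extend(children.get(bid, []))
        if seen != set(self.branches):
            orphans = sorted(set(self.branches) - seen)
            raise TreeStructureError(
                f"tree {self.tree_id}: branches not reachable from root: {orphans}"
            )
        for b in self.branches.values():
            kids = children.get(b.branch_id, [])
            if b.ends_terminal and kids:
                raise TreeStructureError(
                    f"tree {self.tree_id}: terminal branch {b.branch_id} has children"
                )
            if not b.ends_terminal and len(kids) < 2:
                raise TreeStructureError(
                    f"tree {self.tree_id}: non-terminal branch {b.branch_id} must end "
                    f"at a node with >= 2 children (found {len(kids)})"
                )
            if b.parent_id is not None:
                parent = self.branches[b.parent_id]
                if not np.array_equal(b.xyz[0], parent.xyz[-1]):
                    raise TreeStructureError(
                        f"tree {self.tree_id}: branch {b.branch_id} does not start at "
                        f"its parent's distal endpoint"
                    )
        self._children = {k: sorted(v) for k, v in children.items()}

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def n_terminal_ends(self) -> int:
        return sum(1 for b in self.branches.values() if b.ends_terminal)


@dataclass
class TreeRecord:
    """One traced tree together with its specimen identity and clinical group."""

    specimen_id: str
    group_label: str  # "IUGR" or "normal" at ingest
    tree: VillousTree


# ---------------------------------------------------------------------------
# SWC reading / writing
# ---------------------------------------------------------------------------

def _parse_swc_rows(path: Path) -> list[tuple[int, int, float, float, float, float, int, int]]:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise SWCFormatError("expected 7 whitespace-separated columns", lineno)
            try:
                pid = int(parts[0])
                ptype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCFormatError(f"unparseable field ({exc})", lineno) from None
            if not all(math.isfinite(v) for v in (x, y, z, r)):
                raise SWCFormatError("non-finite coordinate or radius", lineno)
            if r <= 0:
                raise SWCFormatError(f"non-positive radius {r}", lineno)
            rows.append((pid, ptype, x, y, z, r, parent, lineno))
    return rows


def read_swc(path: str | Path, tree_id: str | None = None) -> VillousTree:
    """Read an SWC file into a :class:`VillousTree`.

    Point chains are split into branches at every point with >= 2 children;
    degree-2 points are interior samples of a branch.  Diameters are stored as
    2 x the SWC radius column.  Coincident consecutive points are merged with
    a warning.

    Raises :class:`SWCFormatError` naming the offending line for duplicate
    ids, missing parent references, multiple roots, cycles or non-positive
    radii.
    """
    path = Path(path)
    if tree_id is None:
        tree_id = path.stem
    rows = _parse_swc_rows(path)
    if not rows:
        raise SWCFormatError(f"{path}: no sample points")

    by_id: dict[int, tuple] = {}
    root_id: int | None = None
    for pid, ptype, x, y, z, r, parent, lineno in rows:
        if pid in by_id:
            raise SWCFormatError(f"duplicate point id {pid}", lineno)
        by_id[pid] = (x, y, z, r, parent, lineno)
        if parent == -1:
            if root_id is not None:
                raise SWCFormatError(f"multiple root points ({root_id} and {pid})", lineno)
            root_id = pid
    if root_id is None:
        raise SWCFormatError(f"{path}: no root point (parent == -1)")

    children: dict[int, list[int]] = {}
    for pid, (x, y, z, r, parent, lineno) in by_id.items():
        if parent == -1:
            continue
        if parent not in by_id:
            raise SWCFormatError(f"point {pid} references missing parent {parent}", lineno)
        children.setdefault(parent, []).append(pid)
    for kids in children.values():
        kids.sort()

    # reachability from the root detects cycles and disconnected components
    seen: set[int] = set()
    stack = [root_id]
    while stack:
        pid = stack.pop()
        seen.add(pid)
        stack.extend(children.get(pid, []))
    if seen != set(by_id):
        stray = min(set(by_id) - seen)
        raise SWCFormatError(
            f"point {stray} not connected to the root (cycle or second component)",
            by_id[stray][5],
        )

    if len(children.get(root_id, [])) > 1:
        raise SWCFormatError(
            f"root point {root_id} has {len(children[root_id])} children; the root "
            "must begin a single proximal branch", by_id[root_id][5]
        )
    if root_id not in children:
        raise SWCFormatError(f"{path}: tree has a single point, no branch")

    def point_of(pid: int) -> SamplePoint:
        x, y, z, r, _, _ = by_id[pid]
        return SamplePoint(x, y, z, 2.0 * r)

    # walk node-free chains, splitting at points with >= 2 children; a child
    # chain begins at the shared node point (the parent's distal endpoint)
    branches: dict[str, Branch] = {}
    counter = 0
    # queue entries: (chain prefix, parent branch id)
    work: list[tuple[list[int], str | None]] = [([root_id], None)]
    while work:
        chain, parent_bid = work.pop(0)
        cur = chain[-1]
        while True:
            kids = children.get(cur, [])
            if len(kids) == 1:
                cur = kids[0]
                chain.append(cur)
            else:
                break
        pts = [point_of(p) for p in chain]
        # tolerant ingest: merge coincident consecutive samples
        merged: list[SamplePoint] = [pts[0]]
        for p in pts[1:]:
            last = merged[-1]
            if (p.x, p.y, p.z) == (last.x, last.y, last.z):
                logger.warning(
                    "%s: merged coincident consecutive points near (%g, %g, %g)",
                    path.name, p.x, p.y, p.z,
                )
                continue
            merged.append(p)
        if len(merged) < 2:
            raise SWCFormatError(
                f"branch starting at point {chain[0]} collapses to a single "
                "distinct point",
                by_id[chain[0]][5],
            )
        bid = f"b{counter:04d}"
        counter += 1
        kids = children.get(cur, [])
        branches[bid] = Branch.from_points(
            bid, merged, parent_id=parent_bid, ends_terminal=not kids
        )
        for k in kids:
            work.append(([cur, k], bid))

    root_bid = next(b.branch_id for b in branches.values() if b.parent_id is None)
    return VillousTree(tree_id=tree_id, branches=branches, root_branch_id=root_bid)


def write_swc(tree: VillousTree, path: str | Path) -> None:
    """Write a tree as SWC (radius = diameter / 2, type column 0).

    Reading the file back reproduces the same branch decomposition,
    coordinates and diameters up to branch-id relabeling.
    """
    path = Path(path)
    lines = [f"# SWC export of villous tree {tree.tree_id}",
             "# columns: id type x y z radius parent"]
    next_id = 1
    # distal endpoint swc-id of each written branch, for child attachment
    tail_ids: dict[str, int] = {}
    order = [tree.root_branch_id]
    i = 0
    while i < len(order):
        order.extend(tree.children_of(order[i]))
        i += 1
    for bid in order:
        b = tree.branches[bid]
        if b.parent_id is None:
            prev = -1
            start = 0
        else:
            prev = tail_ids[b.parent_id]
            start = 1  # first point is the parent's distal endpoint, already written
        for (x, y, z), d in zip(b.xyz[start:], b.diameters[start:]):
            lines.append(
                f"{next_id} 0 {float(x)!r} {float(y)!r} {float(z)!r} "
                f"{float(d) / 2.0!r} {prev}"
            )
            prev = next_id
            next_id += 1
        tail_ids[bid] = prev
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Terminal distance ordering
# ---------------------------------------------------------------------------

def terminal_distance_order(tree: VillousTree) -> dict[str, int]:
    """Assign every branch its terminal distance order (bT index).

    A branch ending at a terminal end has order 0; otherwise the order is
    1 + the minimum order among its child branches (the node count to the
    nearest terminal end downstream).  The root end is never a terminal end.
    """
    orders: dict[str, int] = {}
    # post-order traversal without recursion
    stack: list[tuple[str, bool]] = [(tree.root_branch_id, False)]
    while stack:
        bid, expanded = stack.pop()
        kids = tree.children_of(bid)
        if not kids:
            orders[bid] = 0
            continue
        if expanded:
            orders[bid] = 1 + min(orders[k] for k in kids)
        else:
            stack.append((bid, True))
            stack.extend((k, False) for k in kids)
    return orders


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> list[TreeRecord]:
    """Load a cohort manifest CSV (columns specimen_id, group, swc_path).

    SWC paths are resolved relative to the manifest's directory.  A specimen
    may contribute several trees but must carry a single group label.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"specimen_id", "group", "swc_path"}
    if not required.issubset(df.columns):
        raise ManifestError(
            f"{path}: manifest must have columns {sorted(required)}; "
            f"found {sorted(df.columns)}"
        )
    groups = df.groupby("specimen_id")["group"].nunique()
    bad = groups[groups > 1]
    if len(bad):
        raise ManifestError(
            f"{path}: specimens with conflicting group labels: {sorted(bad.index)}"
        )
    records = []
    for row in df.itertuples(index=False):
        swc = Path(row.swc_path)
        if not swc.is_absolute():
            swc = path.parent / swc
        tree = read_swc(swc)
        records.append(TreeRecord(row.specimen_id, row.group, tree))
    return records
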