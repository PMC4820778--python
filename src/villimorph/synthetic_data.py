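"""Synthetic villous-tree cohorts with known ground truth.

No traced placental cohort is publicly deposited, so this module grows SWC
cohorts that reproduce the statistical structure the analysis pipeline is
built to detect, with every generated quantity recorded before geometric
realization so parameter-recovery tests can close the loop:

* three group profiles — IUGR (n=40), LT-normal (n=36) and HT-normal (n=14),
  together the 50 "clinically normal" specimens of which 28% are HT;
* terminal (bT0) branching angles drawn from group-specific mixtures: bimodal
  58/76 degrees for IUGR, bimodal 52/64 for LT-normal, unimodal 67 for
  HT-normal.  The mixture acts at the specimen level (each placenta has its
  own angle regime, drawn from one mixture component with a small
  between-placenta spread) so that per-placenta mean angles — the quantity
  the rose diagrams summarize — are themselves bimodal across a cohort;
* directly preterminal (bT1) tortuosity regimes separated by the 1.2
  cutoff: IUGR and LT-normal targets truncated below 1.2, HT-normal targets
  truncated above it, so the high-/low-tortuosity split is recoverable
  exactly;
* HT-normal branches at bT1 are longer (+40%) and thicker (+10%) than
  LT-normal ones, giving the HT group larger surface and volume means;
* tree sizes drawn from a shifted Poisson over terminal-end counts, with a
  group-specific probability that a tree is too small (a caterpillar
  topology) to contain any bT2 branch.

Cohort generation is fully deterministic for a fixed seed: each specimen
derives its own random substream from (seed, specimen counter).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GenerationError
from .tree_model import Branch, VillousTree, write_swc

__all__ = [
    "GroupProfile",
    "GroundTruthBranch",
    "default_profiles",
    "generate_branch_path",
    "generate_tree",
    "generate_cohort",
]


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mean, sd) truncated to [low, high]; drawn by rejection."""

    mean: float
    sd: float
    low: float = -math.inf
    high: float = math.inf

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0.0:
            return float(min(max(self.mean, self.low), self.high))
        for _ in range(10_000):
            v = rng.normal(self.mean, self.sd)
            if self.low <= v <= self.high:
                return float(v)
        raise GenerationError(
            f"rejection sampling failed for N({self.mean}, {self.sd}) on "
            f"[{self.low}, {self.high}]"
        )


@dataclass(frozen=True)
class GroupProfile:
    """Distributional ground truth from which one cohort group is drawn.

    ``angle_mixture`` lists (mean degrees, sd degrees, weight) components of
    terminal branching angles; a specimen first draws its component
    (stratified so realized counts match the weights), then its own angle
    center N(component mean, ``angle_between_sd``), and each branch draws
    N(center, component sd) truncated to (0, 180).
    """

    name: str
    group_label: str                  # label written to the manifest
    n_specimens: int
    angle_mixture: tuple[tuple[float, float, float], ...]
    tortuosity_bt1: TruncNormal
    tortuosity_other: TruncNormal
    branch_length_um: dict[int, tuple[float, float]]   # order -> (mean, sd)
    diameter_um: tuple[float, float]                   # distal bT0 (mean, sd)
    mean_terminals: float                              # shifted-Poisson mean
    prob_no_bt2: float
    angle_between_sd: float = 2.0
    diameter_order_step: float = 0.15   # relative widening per order proximally
    trifurcation_prob: float = 0.0

    def __post_init__(self):
        w = sum(c[2] for c in self.angle_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"profile {self.name}: mixture weights must sum to 1")
        if any(c[1] < 0 for c in self.angle_mixture):
            raise ValueError(f"profile {self.name}: negative angle sd")
        if self.tortuosity_bt1.low < 1.0 or self.tortuosity_other.low < 1.0:
            raise ValueError(f"profile {self.name}: tortuosity targets must be >= 1")
        if self.n_specimens < 1:
            raise ValueError(f"profile {self.name}: n_specimens must be >= 1")
        if not 0.0 <= self.prob_no_bt2 <= 1.0:
            raise ValueError(f"profile {self.name}: prob_no_bt2 must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruthBranch:
    """Targets recorded for one branch before its geometry is realized."""

    branch_id: str
    order: int
    angle_deg: float | None       # None for the root branch
    tortuosity: float
    length_um: float
    distal_diameter_um: float


BASE_LENGTHS = {0: (80.0, 20.0), 1: (100.0, 25.0), 2: (120.0, 30.0), 3: (140.0, 35.0)}


def default_profiles() -> list[GroupProfile]:
    """The three study groups with their published structure.

    IUGR: 40 specimens, terminal angles bimodal at 58/76 degrees, all bT1
    tortuosity below 1.2, 45% of trees without bT2 branches (18/40).
    LT-normal: 36 specimens, bimodal 52/64, tortuosity below 1.2.
    HT-normal: 14 specimens (14/50 = 28% of normals), unimodal 67, tortuosity
    above 1.2, bT1 branches 40% longer and 10% thicker than LT-normal.
    Normal groups: 22% of trees without bT2 (11/50).
    """
    low_t = TruncNormal(1.08, 0.04, 1.0, 1.2)
    high_t = TruncNormal(1.28, 0.05, 1.2, 1.6)
    mild_t = TruncNormal(1.05, 0.03, 1.0, 1.2)
    ht_lengths = {
        k: ((m * 1.4, s * 1.4) if k == 1 else (m, s)) for k, (m, s) in BASE_LENGTHS.items()
    }
    return [
        GroupProfile(
            name="IUGR",
            group_label="IUGR",
            n_specimens=40,
            angle_mixture=((58.0, 6.0, 0.5), (76.0, 6.0, 0.5)),
            tortuosity_bt1=low_t,
            tortuosity_other=mild_t,
            branch_length_um=dict(BASE_LENGTHS),
            diameter_um=(60.0, 8.0),
            mean_terminals=12.0,
            prob_no_bt2=0.45,
        ),
        GroupProfile(
            name="LT-normal",
            group_label="normal",
            n_specimens=36,
            angle_mixture=((52.0, 6.0, 0.5), (64.0, 6.0, 0.5)),
            tortuosity_bt1=low_t,
            tortuosity_other=mild_t,
            branch_length_um=dict(BASE_LENGTHS),
            diameter_um=(60.0, 8.0),
            mean_terminals=12.0,
            prob_no_bt2=0.22,
        ),
        GroupProfile(
            name="HT-normal",
            group_label="normal",
            n_specimens=14,
            angle_mixture=((67.0, 6.0, 1.0),),
            tortuosity_bt1=high_t,
            tortuosity_other=mild_t,
            branch_length_um=ht_lengths,
            diameter_um=(66.0, 8.8),
            mean_terminals=12.0,
            prob_no_bt2=0.22,
        ),
    ]


# ---------------------------------------------------------------------------
# Geometry realization
# ---------------------------------------------------------------------------

def _orthonormal_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def generate_branch_path(
    length: float,
    tortuosity_target: float,
    start: np.ndarray,
    direction: np.ndarray,
    n_points: int = 15,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Polyline of total length ``length`` whose chord lies along ``direction``.

    The chord length is ``length / tortuosity_target``; a sinusoidal
    out-of-chord perturbation (vanishing at both endpoints, integer number of
    turns) is superposed and its amplitude solved by bisection so that the
    polyline's measured tortuosity equals the target to ~1e-9 — round-tripping
    exactly through the tortuosity measurement, which is evaluated on the
    same polyline.
    """
    if tortuosity_target < 1.0:
        raise GenerationError(f"tortuosity target {tortuosity_target} < 1")
    if n_points < 2:
        raise GenerationError("a branch path needs at least 2 points")
    direction = np.asarray(direction, dtype=float)
    d = direction / np.linalg.norm(direction)
    chord = length / tortuosity_target
    t = np.linspace(0.0, 1.0, n_points)
    base = start[None, :] + np.outer(t * chord, d)
    if tortuosity_target == 1.0:
        return base
    rng = np.random.default_rng() if rng is None else rng
    u, v = _orthonormal_frame(d)
    turns = int(rng.integers(1, 3))
    phase = rng.uniform(0.0, 2.0 * math.pi)
    wave = np.outer(np.sin(2.0 * math.pi * turns * t + phase)
                    - ((1 - t) * math.sin(phase) + t * math.sin(2.0 * math.pi * turns + phase)),
                    u)

    def path_length(amp: float) -> float:
        pts = base + amp * wave
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    # bracket the amplitude, then bisect: polyline length grows monotonically
    lo_a, hi_a = 0.0, chord
    for _ in range(200):
        if path_length(hi_a) >= length:
            break
        hi_a *= 2.0
    else:
        raise GenerationError(
            f"cannot reach tortuosity {tortuosity_target} with this waveform"
        )
    for _ in range(200):
        mid = 0.5 * (lo_a + hi_a)
        if path_length(mid) < length:
            lo_a = mid
        else:
            hi_a = mid
        if hi_a - lo_a < 1e-14 * max(1.0, chord):
            break
    return base + 0.5 * (lo_a + hi_a) * wave


def _rotate_about(axis: np.ndarray, vec: np.ndarray, angle: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    return (
        vec * math.cos(angle)
        + np.cross(a, vec) * math.sin(angle)
        + a * np.dot(a, vec) * (1.0 - math.cos(angle))
    )


def _child_direction(
    parent_dir: np.ndarray, angle_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit vector at exactly ``angle_deg`` from parent_dir, uniform azimuth."""
    d = parent_dir / np.linalg.norm(parent_dir)
    u, _ = _orthonormal_frame(d)
    tilted = _rotate_about(u, d, math.radians(angle_deg))
    return _rotate_about(d, tilted, rng.uniform(0.0, 2.0 * math.pi))


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _split_counts(n: int, rng: np.random.Generator, force_deep: bool) -> tuple[int, int]:
    if force_deep:  # both subtrees get >= 2 terminals -> the root branch is bT2+
        k = int(rng.integers(2, n - 1))
    else:
        k = int(rng.integers(1, n))
    return k, n - k


def _build_topology(
    n_terminals: int, rng: np.random.Generator, caterpillar: bool
) -> list[tuple[int, int | None]]:
    """Return branches as (id, parent_id); terminal branches have no children.

    A caterpillar keeps one terminal per internal node, so every internal
    branch is directly preterminal (bT1) and the tree has no bT2 branch.
    """
    branches: list[tuple[int, int | None]] = []
    counter = [0]

    def new_branch(parent: int | None) -> int:
        bid = counter[0]
        counter[0] += 1
        branches.append((bid, parent))
        return bid

    def grow(n: int, parent: int | None, force_deep: bool) -> None:
        bid = new_branch(parent)
        if n == 1:
            return
        if caterpillar:
            grow(1, bid, False)
            grow(n - 1, bid, False)
            return
        k, rest = _split_counts(n, rng, force_deep and n >= 4)
        grow(k, bid, False)
        grow(rest, bid, False)

    if caterpillar:
        grow(n_terminals, None, False)
    else:
        # ensure at least one bT2 branch exists: the root's split leaves
        # >= 2 terminals on both sides
        grow(max(n_terminals, 4), None, True)
    return branches


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------

def generate_tree(
    profile: GroupProfile,
    rng: np.random.Generator,
    tree_id: str = "synthetic",
    angle_center: float | None = None,
    angle_sd: float | None = None,
) -> tuple[VillousTree, list[GroundTruthBranch]]:
    """Grow one tree from a profile; returns the tree and its ground truth.

    The number of terminal ends is 1 + Poisson(mean_terminals - 1); with
    probability ``prob_no_bt2`` the topology is a caterpillar (no bT2
    branch), otherwise a bT2 branch is guaranteed.  Child chords are placed
    at exactly the drawn branching angle (uniform azimuth), so the measured
    planar angle reproduces the draw to machine precision; branch paths hit
    their tortuosity targets by construction.
    """
    if angle_center is None or angle_sd is None:
        comps = profile.angle_mixture
        weights = np.array([c[2] for c in comps])
        j = int(rng.choice(len(comps), p=weights / weights.sum()))
        mean, sd, _ = comps[j]
        angle_center = TruncNormal(mean, profile.angle_between_sd, 1.0, 179.0).draw(rng)
        angle_sd = sd

    n_term = 1 + int(rng.poisson(max(profile.mean_terminals - 1.0, 0.0)))
    caterpillar = bool(rng.random() < profile.prob_no_bt2) or n_term <= 2
    topo = _build_topology(n_term, rng, caterpillar)
    children: dict[int, list[int]] = {}
    for bid, parent in topo:
        if parent is not None:
            children.setdefault(parent, []).append(bid)

    # orders from topology alone (geometry-independent)
    orders: dict[int, int] = {}

    def order_of(bid: int) -> int:
        kids = children.get(bid, [])
        if bid not in orders:
            orders[bid] = 0 if not kids else 1 + min(order_of(k) for k in kids)
        return orders[bid]

    for bid, _ in topo:
        order_of(bid)

    angle_dist = TruncNormal(angle_center, angle_sd, 1.0, 179.0)
    len_fallback = max(profile.branch_length_um)
    root_dir = _child_direction(np.array([0.0, 0.0, 1.0]), rng.uniform(0, 20), rng)

    branches: dict[str, Branch] = {}
    truth: list[GroundTruthBranch] = []
    # state per topological branch: (start point, chord direction, distal diameter)
    base_diam = float(max(10.0, rng.normal(*profile.diameter_um)))

    def realize(bid: int, parent_bid: int | None, start: np.ndarray,
                parent_dir: np.ndarray, prox_diam: float) -> None:
        k = orders[bid]
        if parent_bid is None:
            angle = None
            direction = parent_dir
        else:
            angle = angle_dist.draw(rng)
            direction = _child_direction(parent_dir, angle, rng)
        tort_dist = profile.tortuosity_bt1 if k == 1 else profile.tortuosity_other
        tort = tort_dist.draw(rng)
        mean_l, sd_l = profile.branch_length_um.get(
            k, profile.branch_length_um[len_fallback]
        )
        length = TruncNormal(mean_l, sd_l, max(10.0, 0.2 * mean_l), math.inf).draw(rng)
        distal_diam = float(
            max(8.0, base_diam * (1.0 + profile.diameter_order_step * k)
                * rng.normal(1.0, 0.05))
        )
        xyz = generate_branch_path(length, tort, start, direction, rng=rng)
        diams = np.linspace(prox_diam, distal_diam, xyz.shape[0])
        name = f"b{bid:04d}"
        branches[name] = Branch(
            branch_id=name,
            xyz=xyz,
            diameters=diams,
            parent_id=None if parent_bid is None else f"b{parent_bid:04d}",
            ends_terminal=bid not in children,
        )
        truth.append(
            GroundTruthBranch(name, k, angle, tort, length, distal_diam)
        )
        for kid in children.get(bid, []):
            realize(kid, bid, xyz[-1], direction, distal_diam)

    root_id = next(bid for bid, parent in topo if parent is None)
    root_prox = base_diam * (1.0 + profile.diameter_order_step * (orders[root_id] + 1))
    realize(root_id, None, np.zeros(3), root_dir, root_prox)

    tree = VillousTree(
        tree_id=tree_id,
        branches=branches,
        root_branch_id=f"b{root_id:04d}",
    )
    return tree, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _stratified_components(profile: GroupProfile, rng: np.random.Generator) -> list[int]:
    """Assign specimens to mixture components with realized counts matching
    the weights exactly (largest-remainder rounding), in random order."""
    n = profile.n_specimens
    weights = [c[2] for c in profile.angle_mixture]
    counts = [int(math.floor(w * n)) for w in weights]
    remainders = sorted(
        range(len(weights)), key=lambda j: weights[j] * n - counts[j], reverse=True
    )
    for j in remainders[: n - sum(counts)]:
        counts[j] += 1
    assignment = np.array([j for j, c in enumerate(counts) for _ in range(c)], dtype=int)
    rng.shuffle(assignment)
    return [int(j) for j in assignment]


def generate_cohort(
    profiles: Sequence[GroupProfile] | None = None,
    seed: int = 0,
    out_dir: str | Path = "cohort",
) -> Path:
    """Write one SWC per specimen, a manifest CSV and a ground-truth CSV.

    The manifest carries only the clinical labels (HT-/LT-normal specimens
    appear as "normal"); the true profile of each specimen is recorded in
    ``ground_truth.csv`` so the pipeline's rediscovery of the
    high-tortuosity subgroup can be scored.  Identical seeds give
    byte-identical outputs; each specimen uses an independent substream
    seeded by (seed, running specimen counter).
    """
    if profiles is None:
        profiles = default_profiles()
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("profile names must be distinct")
    out_dir = Path(out_dir)
    (out_dir / "swc").mkdir(parents=True, exist_ok=True)

    manifest_rows: list[tuple[str, str, str]] = []
    truth_rows: list[list] = []
    counter = 0
    label_counters: dict[str, int] = {}
    for profile in profiles:
        assign_rng = np.random.default_rng([seed, 10_000 + counter])
        components = _stratified_components(profile, assign_rng)
        for i in range(profile.n_specimens):
            rng = np.random.default_rng([seed, counter])
            idx = label_counters.get(profile.group_label, 0)
            label_counters[profile.group_label] = idx + 1
            sid = f"{profile.group_label.lower()}_{idx:03d}"
            mean, sd, _ = profile.angle_mixture[components[i]]
            center = TruncNormal(mean, profile.angle_between_sd, 1.0, 179.0).draw(rng)
            tree, truth = generate_tree(
                profile, rng, tree_id=sid, angle_center=center, angle_sd=sd
            )
            swc_rel = f"swc/{sid}.swc"
            write_swc(tree, out_dir / swc_rel)
            manifest_rows.append((sid, profile.group_label, swc_rel))
            for gt in truth:
                truth_rows.append(
                    [
                        sid,
                        profile.name,
                        sid,
                        gt.branch_id,
                        gt.order,
                        "" if gt.angle_deg is None else repr(gt.angle_deg),
                        repr(gt.tortuosity),
                        repr(gt.length_um),
                        repr(gt.distal_diameter_um),
                        repr(center),
                        components[i],
                    ]
                )
            counter += 1

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["specimen_id", "group", "swc_path"])
        w.writerows(manifest_rows)
    with open(out_dir / "ground_truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "specimen_id", "profile", "tree_id", "branch_id", "order",
                "angle_target_deg", "tortuosity_target", "length_um",
                "distal_diameter_um", "specimen_angle_center_deg",
                "angle_component",
            ]
        )
        w.writerows(truth_rows)
    return manifest
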