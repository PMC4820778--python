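"""End-to-end study pipeline: ingest -> measure -> aggregate -> split -> compare.

Reproduces the full analysis flow on a cohort of traced villous trees:

1. read the manifest and all SWC tracings (invalid trees exclude their
   specimen, with the reason logged and itemized in the report);
2. measure every branch and aggregate per specimen by terminal distance
   order (bT0-bT2);
3. split the clinically normal specimens into HT-normal / LT-normal at the
   bT1 tortuosity threshold (default 1.2);
4. for each metric (angle, tortuosity, length, surface, volume) and order:
   a two-group IUGR-vs-normal comparison (Student's t and rank-based, both
   reported) and a three-group Kruskal-Wallis with Dunn's pairwise
   contrasts over IUGR / HT-normal / LT-normal;
5. angular analysis of per-placenta mean terminal branching angles per
   group: rose histogram, wrapped-KDE modes, Hartigan's dip with a seeded
   Monte-Carlo p-value;
6. write a JSON report, CSV tables and figures.

The report is a pure function of (manifest contents, SWC bytes, config):
identical runs give identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    GroupedSample,
    angular_summary,
    dunns_posthoc,
    kruskal_wallis,
    split_ht_lt,
    two_sample_t,
)
from .errors import SWCFormatError, TreeStructureError, VillimorphError
from .morphometry import METRIC_COLUMNS, aggregate_table, metrics_table
from .tree_model import TreeRecord, _parse_swc_rows, read_swc, terminal_distance_order

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StudyReport", "run_study", "validate_tree"]


@dataclass
class RunConfig:
    """All analysis constants of one pipeline run."""

    manifest: Path
    out_dir: Path
    threshold: float = 1.2            # bT1 tortuosity cutoff for HT/LT
    orders: tuple[int, ...] = (0, 1, 2)
    dunn_adjustment: str = "bonferroni"
    rose_bin_width: float = 10.0      # degrees
    kde_bandwidth: float = 4.0        # degrees, mode detection
    dip_n_boot: int = 10_000
    seed: int = 0
    angle_convention: str = "chord"   # or "tangent"
    make_figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)
        if self.threshold <= 1.0:
            raise ValueError("tortuosity threshold must exceed 1")
        if self.dip_n_boot < 1000:
            raise ValueError("dip_n_boot must be >= 1000")
        if self.angle_convention not in ("chord", "tangent"):
            raise ValueError("angle convention must be 'chord' or 'tangent'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "orders" in data:
            data["orders"] = tuple(data["orders"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["manifest"] = str(self.manifest)
        d["out_dir"] = str(self.out_dir)
        d["orders"] = list(self.orders)
        return d


@dataclass
class StudyReport:
    """Everything one run produced, mirrored in ``report.json``."""

    aggregates: pd.DataFrame
    subgroups: dict[str, str]          # specimen -> IUGR / HT-normal / LT-normal
    tests: dict[str, dict]
    angular: dict[str, dict]
    excluded: list[dict]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "excluded": self.excluded,
            "subgroups": self.subgroups,
            "subgroup_counts": {
                g: sum(1 for v in self.subgroups.values() if v == g)
                for g in sorted(set(self.subgroups.values()))
            },
            "tests": self.tests,
            "angular_mpa_bT0": self.angular,
        }


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_records(config: RunConfig) -> tuple[list[TreeRecord], list[dict]]:
    df = pd.read_csv(config.manifest, dtype=str)
    required = {"specimen_id", "group", "swc_path"}
    if not required.issubset(df.columns):
        raise VillimorphError(
            f"manifest must have columns {sorted(required)}; found {sorted(df.columns)}"
        )
    records, excluded = [], []
    for row in df.itertuples(index=False):
        swc = Path(row.swc_path)
        if not swc.is_absolute():
            swc = config.manifest.parent / swc
        try:
            tree = read_swc(swc)
            records.append(TreeRecord(row.specimen_id, row.group, tree))
        except (OSError, VillimorphError) as exc:
            logger.warning("specimen %s: excluded (%s)", row.specimen_id, exc)
            excluded.append({"specimen_id": row.specimen_id, "reason": str(exc)})
    if not records:
        raise VillimorphError("no valid specimens in the manifest")
    return records, excluded


def _group_values(
    agg: pd.DataFrame, column: str, groups: dict[str, list[str]]
) -> dict[str, np.ndarray]:
    """Per-group defined values of one aggregate column (pairwise deletion)."""
    out = {}
    for gname, sids in groups.items():
        sub = agg[agg["specimen_id"].isin(sids)][column].dropna()
        if len(sub):
            out[gname] = sub.to_numpy(dtype=float)
    return out


def _test_battery(
    agg: pd.DataFrame,
    subgroups: dict[str, str],
    config: RunConfig,
) -> dict[str, dict]:
    two_groups = {
        "IUGR": [s for s, g in zip(agg["specimen_id"], agg["group"]) if g == "IUGR"],
        "normal": [s for s, g in zip(agg["specimen_id"], agg["group"]) if g != "IUGR"],
    }
    three_groups: dict[str, list[str]] = {}
    for sid, label in subgroups.items():
        three_groups.setdefault(label, []).append(sid)

    tests: dict[str, dict] = {}
    for short in METRIC_COLUMNS:
        for k in config.orders:
            col = f"{short}_bT{k}"
            entry: dict[str, dict] = {}
            g2 = _group_values(agg, col, two_groups)
            if len(g2) == 2 and all(len(v) >= 2 for v in g2.values()):
                sample = GroupedSample.from_groups(g2)
                entry["two_group"] = {
                    "n": {g: int(len(v)) for g, v in g2.items()},
                    "student_t": two_sample_t(g2["IUGR"], g2["normal"]).to_dict(),
                    "kruskal_wallis": kruskal_wallis(sample).to_dict(),
                }
            g3 = _group_values(agg, col, three_groups)
            if len(g3) >= 3 and sum(len(v) for v in g3.values()) >= 3:
                sample = GroupedSample.from_groups(g3)
                entry["three_group"] = {
                    "n": {g: int(len(v)) for g, v in g3.items()},
                    "kruskal_wallis": kruskal_wallis(sample).to_dict(),
                    "dunn": dunns_posthoc(sample, config.dunn_adjustment).to_dict(),
                }
            if entry:
                tests[col] = entry
    return tests


def _angular_battery(
    agg: pd.DataFrame, subgroups: dict[str, str], config: RunConfig
) -> dict[str, dict]:
    pools = {
        "IUGR": agg[agg["group"] == "IUGR"],
        "normal": agg[agg["group"] != "IUGR"],
    }
    for label in ("HT-normal", "LT-normal"):
        sids = [s for s, g in subgroups.items() if g == label]
        pools[label] = agg[agg["specimen_id"].isin(sids)]
    out = {}
    for gname, sub in pools.items():
        vals = sub["mpa_bT0"].dropna().to_numpy(dtype=float)
        if len(vals) < 4:
            continue
        summ = angular_summary(
            vals,
            bin_width=config.rose_bin_width,
            bandwidth=config.kde_bandwidth,
            n_boot=config.dip_n_boot,
            seed=config.seed,
        )
        out[gname] = {"n": int(len(vals)), **summ.to_dict()}
    return out


def _write_figures(
    agg: pd.DataFrame, subgroups: dict[str, str], angular: dict, config: RunConfig
) -> None:
    figdir = config.out_dir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    # rose diagrams of per-placenta mean terminal angles
    groups = list(angular)
    if groups:
        fig, axes = plt.subplots(
            1, len(groups), subplot_kw={"projection": "polar"},
            figsize=(4 * len(groups), 4),
        )
        axes = np.atleast_1d(axes)
        for ax, gname in zip(axes, groups):
            info = angular[gname]
            edges = np.radians(info["bin_edges_deg"])
            counts = info["counts"]
            ax.bar(
                (edges[:-1] + edges[1:]) / 2, counts,
                width=np.diff(edges), bottom=0.0, alpha=0.7, edgecolor="k",
            )
            ax.set_title(f"{gname} (n={info['n']})", fontsize=10)
            ax.set_thetamin(0)
            ax.set_thetamax(180)
        fig.suptitle("mean planar branching angle, bT0")
        fig.tight_layout()
        fig.savefig(figdir / "rose_mpa_bT0.png", dpi=120)
        plt.close(fig)
    # per-group scatter with mean +/- SD per metric and order
    order3 = ["IUGR", "LT-normal", "HT-normal"]
    for short in METRIC_COLUMNS:
        fig, axes = plt.subplots(1, len(config.orders), figsize=(3.2 * len(config.orders), 3.6))
        axes = np.atleast_1d(axes)
        for ax, k in zip(axes, config.orders):
            col = f"{short}_bT{k}"
            for i, gname in enumerate(order3):
                sids = [s for s, g in subgroups.items() if g == gname]
                vals = agg[agg["specimen_id"].isin(sids)][col].dropna().to_numpy(float)
                if not len(vals):
                    continue
                jitter = (np.arange(len(vals)) % 7 - 3) * 0.02
                ax.plot(np.full(len(vals), i) + jitter, vals, "o", ms=3, alpha=0.5)
                ax.errorbar(
                    [i], [vals.mean()], yerr=[vals.std(ddof=1)] if len(vals) > 1 else None,
                    fmt="_", color="k", capsize=4, ms=14,
                )
            ax.set_xticks(range(len(order3)))
            ax.set_xticklabels(order3, rotation=30, fontsize=8)
            ax.set_title(col, fontsize=10)
        fig.tight_layout()
        fig.savefig(figdir / f"{short}_groups.png", dpi=120)
        plt.close(fig)


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full analysis and write report, tables and figures."""
    logging.basicConfig(level=config.log_level)
    records, excluded = _load_records(config)
    config.out_dir.mkdir(parents=True, exist_ok=True)

    branch_df = metrics_table(records, config.angle_convention)
    agg = aggregate_table(records, config.orders, config.angle_convention)

    normals = agg[agg["group"] != "IUGR"]
    ht_lt = split_ht_lt(
        {
            r.specimen_id: (None if pd.isna(r.mt_bT1) else float(r.mt_bT1))
            for r in normals.itertuples(index=False)
        },
        threshold=config.threshold,
    )
    subgroups = {
        r.specimen_id: ("IUGR" if r.group == "IUGR" else ht_lt.get(r.specimen_id, "normal-unsplit"))
        for r in agg.itertuples(index=False)
    }

    tests = _test_battery(agg, subgroups, config)
    angular = _angular_battery(agg, subgroups, config)

    agg_csv = config.out_dir / "specimen_aggregates.csv"
    branch_csv = config.out_dir / "branch_metrics.csv"
    agg.to_csv(agg_csv, index=False)
    branch_df.to_csv(branch_csv, index=False)

    provenance = {
        "villimorph_version": __version__,
        "config": config.to_dict(),
        "inputs": {
            "manifest_sha256": _sha256_file(config.manifest),
            "n_swc_files": int(branch_df["tree_id"].nunique()),
        },
        "tables": {
            "specimen_aggregates_sha256": _sha256_file(agg_csv),
            "branch_metrics_sha256": _sha256_file(branch_csv),
        },
    }
    report = StudyReport(
        aggregates=agg,
        subgroups=subgroups,
        tests=tests,
        angular=angular,
        excluded=excluded,
        provenance=provenance,
    )
    (config.out_dir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    if config.make_figures:
        _write_figures(agg, subgroups, angular, config)
    return report


# ---------------------------------------------------------------------------
# Tree diagnostics
# ---------------------------------------------------------------------------

def validate_tree(path: str | Path) -> dict:
    """Diagnostics for one SWC file; always returns, never raises.

    Reports invariant violations (unparseable rows, duplicate ids, orphan
    points, cycles, multiple roots, non-positive radii), point/branch/node/
    terminal counts and the terminal-distance order histogram when the tree
    is valid.
    """
    path = Path(path)
    diag: dict = {"path": str(path), "violations": [], "n_points": 0}
    try:
        rows = _parse_swc_rows(path)
    except SWCFormatError as exc:
        diag["violations"].append(str(exc))
        return diag
    except OSError as exc:
        diag["violations"].append(f"unreadable: {exc}")
        return diag
    diag["n_points"] = len(rows)
    if not rows:
        diag["violations"].append("no points")
        return diag

    ids = [r[0] for r in rows]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        diag["violations"].append(f"duplicate point ids: {dupes}")
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    roots = [r[0] for r in rows if r[6] == -1]
    known = set(ids)
    for r in rows:
        pid, parent = r[0], r[6]
        if parent == -1:
            continue
        if parent not in known:
            diag["violations"].append(f"point {pid} has missing parent {parent}")
        else:
            g.add_edge(parent, pid)
    if len(roots) == 0:
        diag["violations"].append("no root point (parent == -1)")
    elif len(roots) > 1:
        diag["violations"].append(f"multiple roots: {sorted(roots)}")
    if not nx.is_directed_acyclic_graph(g):
        diag["violations"].append("cycle among parent links")
    elif roots:
        reachable = set(nx.descendants(g, roots[0])) | {roots[0]} if roots[0] in g else set()
        orphans = sorted(known - reachable)
        if orphans:
            diag["violations"].append(f"points not connected to root: {orphans}")

    if not diag["violations"]:
        try:
            tree = read_swc(path)
        except VillimorphError as exc:
            diag["violations"].append(str(exc))
            return diag
        orders = terminal_distance_order(tree)
        hist: dict[int, int] = {}
        for k in orders.values():
            hist[k] = hist.get(k, 0) + 1
        diag.update(
            n_branches=tree.n_branches,
            n_terminal_ends=tree.n_terminal_ends,
            n_nodes=sum(1 for b in tree.branches.values() if not b.ends_terminal),
            order_histogram={str(k): hist[k] for k in sorted(hist)},
        )
    return diag
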