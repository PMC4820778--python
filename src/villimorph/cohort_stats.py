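"""Cohort comparison statistics for per-placenta morphometric means.

The analysis battery mirrors common practice for small clinical cohorts with
non-normal per-specimen means:

* Kruskal-Wallis omnibus test (tie-corrected H, chi-square approximation)
  followed by Dunn's pairwise z-comparisons on the joint ranks, with
  configurable multiplicity adjustment (Bonferroni by default, or Holm);
* Student's / Welch's two-sample t-test for the macroscopic validation
  variables;
* classification of clinically normal specimens into high- and low-tortuosity
  subgroups (HT-normal / LT-normal) by their mean bT1 tortuosity relative to
  a 1.2 cutoff;
* angular summaries of terminal branching angles: rose histogram, mode
  detection on a wrapped kernel density, and Hartigan's dip statistic with a
  seeded Monte-Carlo uniform-null p-value for non-unimodality.

All rank statistics and the dip statistic are computed here from first
principles (scipy supplies only distribution functions); tests cross-check
them against permutation oracles and closed forms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupedSample",
    "TestResult",
    "AngularSummary",
    "kruskal_wallis",
    "dunns_posthoc",
    "two_sample_t",
    "split_ht_lt",
    "rose_histogram",
    "angular_modes",
    "hartigan_dip",
    "dip_test_pvalue",
    "significance_stars",
    "angular_summary",
]

logger = logging.getLogger(__name__)


def significance_stars(p: float) -> str:
    """Conventional star coding: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupedSample:
    """Scalar observations (one per specimen) with group labels."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != self.labels.shape or self.values.ndim != 1:
            raise ValueError("values and labels must be 1-D and aligned")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("observations must be finite")
        names, counts = np.unique(self.labels, return_counts=True)
        if len(names) < 2:
            raise ValueError("at least 2 groups required")
        if np.any(counts == 0):
            raise ValueError("every group must be non-empty")

    @classmethod
    def from_groups(cls, groups: Mapping[str, Sequence[float]]) -> "GroupedSample":
        values = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
        labels = np.concatenate(
            [np.full(len(v), k, dtype=object) for k, v in groups.items()]
        )
        return cls(values, labels)

    def groups(self) -> dict[str, np.ndarray]:
        return {
            str(name): self.values[self.labels == name]
            for name in np.unique(self.labels)
        }


@dataclass
class TestResult:
    """Outcome of one hypothesis test (omnibus or pairwise battery)."""

    method: str
    statistic: float
    p_value: float
    df: float | None = None
    adjustment: str | None = None
    pairwise: list[dict] | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "stars": significance_stars(self.p_value),
        }
        if self.df is not None:
            d["df"] = self.df
        if self.adjustment is not None:
            d["adjustment"] = self.adjustment
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise
        return d


@dataclass
class AngularSummary:
    """Rose histogram plus modes and dip test for one group's angles."""

    bin_edges: np.ndarray
    counts: np.ndarray
    modes: list[float]
    dip: float
    dip_pvalue: float | None = None

    def to_dict(self) -> dict:
        return {
            "bin_edges_deg": [float(e) for e in self.bin_edges],
            "counts": [int(c) for c in self.counts],
            "modes_deg": [float(m) for m in self.modes],
            "dip": self.dip,
            "dip_pvalue": self.dip_pvalue,
        }


# ---------------------------------------------------------------------------
# Rank-based tests
# ---------------------------------------------------------------------------

def _tie_term(pooled: np.ndarray) -> float:
    _, t = np.unique(pooled, return_counts=True)
    return float(np.sum(t.astype(float) ** 3 - t))


def kruskal_wallis(sample: GroupedSample) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    H = [12 / (N(N+1)) * sum R_j^2 / n_j - 3(N+1)] / [1 - sum(t^3 - t)/(N^3 - N)]
    over midranks of the pooled sample; df = groups - 1.
    """
    groups = sample.groups()
    n = sample.values.size
    if n < 3:
        raise ValueError("Kruskal-Wallis requires a total of at least 3 observations")
    ranks = sps.rankdata(sample.values)
    h = 0.0
    for name in groups:
        r = ranks[sample.labels == name]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(sample.values) / (n**3 - n)
    df = len(groups) - 1
    if correction <= 0.0:  # all observations identical
        return TestResult("kruskal-wallis", 0.0, 1.0, df=df)
    h /= correction
    h = max(h, 0.0)
    return TestResult("kruskal-wallis", h, float(sps.chi2.sf(h, df)), df=df)


def _adjust(p_raw: np.ndarray, method: str) -> np.ndarray:
    m = p_raw.size
    if method == "none":
        return p_raw.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p_raw)
    if method == "holm":
        order = np.argsort(p_raw)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p_raw[i])
            adj[i] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def dunns_posthoc(sample: GroupedSample, adjustment: str = "bonferroni") -> TestResult:
    """Dunn's pairwise comparisons on joint ranks after Kruskal-Wallis.

    For groups i, j: z = (Rbar_i - Rbar_j) / sqrt(V (1/n_i + 1/n_j)) with
    V = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1)); two-sided normal p per pair,
    then the chosen multiplicity adjustment over all pairs.
    """
    groups = sample.groups()
    names = sorted(groups)
    if len(names) < 3:
        raise ValueError(
            "Dunn's test needs >= 3 groups; use the omnibus Kruskal-Wallis "
            "(or a two-sample test) for 2 groups"
        )
    n = sample.values.size
    ranks = sps.rankdata(sample.values)
    mean_ranks = {g: float(ranks[sample.labels == g].mean()) for g in names}
    sizes = {g: int((sample.labels == g).sum()) for g in names}
    var = n * (n + 1) / 12.0 - _tie_term(sample.values) / (12.0 * (n - 1))
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    zs, ps = [], []
    for a, b in pairs:
        if var <= 0.0:
            z = 0.0
        else:
            se = math.sqrt(var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
        zs.append(z)
        ps.append(2.0 * float(sps.norm.sf(abs(z))))
    p_raw = np.array(ps)
    p_adj = _adjust(p_raw, adjustment)
    table = [
        {
            "groups": [a, b],
            "z": zs[i],
            "p_raw": float(p_raw[i]),
            "p_adj": float(p_adj[i]),
            "stars": significance_stars(float(p_adj[i])),
        }
        for i, (a, b) in enumerate(pairs)
    ]
    imax = int(np.argmax(np.abs(zs)))
    return TestResult(
        method="dunn",
        statistic=float(abs(zs[imax])),
        p_value=float(p_adj.min()),
        adjustment=adjustment,
        pairwise=table,
    )


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sided two-sample t-test, pooled-variance by default or Welch.

    Degenerate inputs follow the conventional limits: zero variance in both
    samples gives p = 1 for equal means and p = 0 (flagged in the method
    name) for unequal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    name = "welch-t" if welch else "student-t"
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return TestResult(name, 0.0, 1.0, df=float(a.size + b.size - 2))
        return TestResult(name + " (degenerate: zero variance)", math.inf, 0.0)
    if welch:
        sa, sb = va / a.size, vb / b.size
        se = math.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    else:
        sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
        se = math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
        df = float(a.size + b.size - 2)
    t = diff / se
    return TestResult(name, float(t), 2.0 * float(sps.t.sf(abs(t), df)), df=df)


# ---------------------------------------------------------------------------
# HT / LT subgrouping
# ---------------------------------------------------------------------------

def split_ht_lt(
    mt_bt1: Mapping[str, float | None], threshold: float = 1.2
) -> dict[str, str]:
    """Label clinically normal specimens by their mean bT1 tortuosity.

    Above the threshold: ``HT-normal``; below: ``LT-normal``.  A value exactly
    equal to the threshold is labeled LT-normal with a warning (the subgroup
    definition is strictly "more than" the cutoff).  Specimens without a
    defined mean bT1 tortuosity are excluded and logged.
    """
    if threshold <= 1.0:
        raise ValueError("tortuosity threshold must exceed 1")
    labels: dict[str, str] = {}
    for sid, value in mt_bt1.items():
        if value is None or (isinstance(value, float) and math.isnan(value)):
            logger.warning("specimen %s: no bT1 tortuosity, excluded from HT/LT split", sid)
            continue
        if value > threshold:
            labels[sid] = "HT-normal"
        else:
            if value == threshold:
                logger.warning(
                    "specimen %s: mean bT1 tortuosity exactly at the %g cutoff; "
                    "labeled LT-normal", sid, threshold,
                )
            labels[sid] = "LT-normal"
    return labels


# ---------------------------------------------------------------------------
# Angular statistics
# ---------------------------------------------------------------------------

def rose_histogram(
    angles: Sequence[float], bin_width: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sector counts for a rose diagram over the full circle.

    Returns (bin_edges, counts) with sectors [0, w), [w, 2w), ... covering
    360 degrees; counts sum to the sample size.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle sample")
    if not (bin_width > 0 and abs(360.0 / bin_width - round(360.0 / bin_width)) < 1e-9):
        raise ValueError("bin width must divide 360 degrees")
    nbins = int(round(360.0 / bin_width))
    counts, edges = np.histogram(np.mod(angles, 360.0), bins=nbins, range=(0.0, 360.0))
    return edges, counts


def _wrapped_density(angles: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    # Gaussian kernel wrapped on the 360-degree circle (3 images suffice for
    # bandwidths well under 60 degrees).
    delta = grid[:, None] - angles[None, :]
    dens = np.zeros(grid.size)
    for shift in (-360.0, 0.0, 360.0):
        dens += np.exp(-0.5 * ((delta + shift) / bandwidth) ** 2).sum(axis=1)
    return dens / (angles.size * bandwidth * math.sqrt(2.0 * math.pi))


def angular_modes(angles: Sequence[float], bandwidth: float = 4.0) -> list[float]:
    """Angles (degrees) of local maxima of a wrapped kernel density.

    The density is evaluated on a 1-degree grid around the circle; local
    maxima falling in [0, 180] are reported, and maxima closer than the
    bandwidth are merged into the higher one.  Returned ascending.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 1:
        raise ValueError("empty angle sample")
    grid = np.arange(0.0, 360.0, 1.0)
    dens = _wrapped_density(np.mod(angles, 360.0), grid, bandwidth)
    left = np.roll(dens, 1)
    right = np.roll(dens, -1)
    is_max = (dens >= left) & (dens >= right) & ((dens > left) | (dens > right))
    cand = [(dens[i], grid[i]) for i in np.flatnonzero(is_max) if grid[i] <= 180.0]
    cand.sort(reverse=True)  # by density, highest first
    kept: list[float] = []
    for _, theta in cand:
        d_circ = [min(abs(theta - k), 360.0 - abs(theta - k)) for k in kept]
        if all(d >= bandwidth for d in d_circ):
            kept.append(theta)
    return sorted(kept)


# ---------------------------------------------------------------------------
# Hartigan's dip statistic
# ---------------------------------------------------------------------------

def _lower_hull(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    idx: list[int] = []
    for i in range(xs.size):
        while len(idx) >= 2:
            i1, i2 = idx[-2], idx[-1]
            cross = (xs[i2] - xs[i1]) * (ys[i] - ys[i1]) - (ys[i2] - ys[i1]) * (
                xs[i] - xs[i1]
            )
            if cross <= 0.0:  # i2 on or above the chord i1 -> i
                idx.pop()
            else:
                break
        idx.append(i)
    return np.array(idx, dtype=int)


def _upper_hull(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    idx: list[int] = []
    for i in range(xs.size):
        while len(idx) >= 2:
            i1, i2 = idx[-2], idx[-1]
            cross = (xs[i2] - xs[i1]) * (ys[i] - ys[i1]) - (ys[i2] - ys[i1]) * (
                xs[i] - xs[i1]
            )
            if cross >= 0.0:  # i2 on or below the chord i1 -> i
                idx.pop()
            else:
                break
        idx.append(i)
    return np.array(idx, dtype=int)


def hartigan_dip(values: Sequence[float]) -> float:
    """Hartigan's dip: sup-distance from the closest unimodal distribution.

    Computed by the greatest-convex-minorant / least-concave-majorant
    iteration on the sorted sample: the candidate modal interval is shrunk to
    the touchpoints bracketing the largest gap between the two hulls, while
    the convex (left) and concave (right) flanks contribute their maximal
    deviation from the empirical distribution function; the final dip is half
    the largest such deviation.  Bounded by [0, 0.25]; identically-valued
    samples give 0 by convention.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    v, counts = np.unique(x, return_counts=True)
    m = v.size
    if m == 1:
        return 0.0
    cum = np.cumsum(counts) / n       # F(v_k)
    low = cum - counts / n            # F(v_k-)

    lo, hi = 0, m - 1
    dip = 0.0
    while hi > lo:
        g_idx = _lower_hull(v[lo : hi + 1], low[lo : hi + 1]) + lo
        l_idx = _upper_hull(v[lo : hi + 1], cum[lo : hi + 1]) + lo
        gcm_curve = np.interp(v[lo : hi + 1], v[g_idx], low[g_idx])
        lcm_curve = np.interp(v[lo : hi + 1], v[l_idx], cum[l_idx])
        # gap between the hull curves, measured at every touchpoint of either
        # hull; each candidate carries the modal interval it would imply
        cands: list[tuple[float, int, int]] = []
        for t in l_idx:
            gap = cum[t] - gcm_curve[t - lo]
            left = int(g_idx[g_idx <= t].max())
            cands.append((float(gap), left, int(t)))
        for s in g_idx:
            gap = lcm_curve[s - lo] - low[s]
            right = int(l_idx[l_idx >= s].min())
            cands.append((float(gap), int(s), right))
        d = max(c[0] for c in cands)
        if d <= dip:
            break
        eps = 1e-12 * max(1.0, abs(d))
        shrinkers = [
            c for c in cands if c[0] >= d - eps and (c[1], c[2]) != (lo, hi)
        ]
        _, nlo, nhi = shrinkers[0]
        # convex flank [lo, nlo]: deviation of F above its minorant; the new
        # modal endpoint's own jump is excluded (a unimodal law may place an
        # atom at its mode)
        dip_l = float((cum[lo:nlo] - gcm_curve[: nlo - lo]).max()) if nlo > lo else 0.0
        dip_u = (
            float((lcm_curve[nhi + 1 - lo :] - low[nhi + 1 : hi + 1]).max())
            if nhi < hi
            else 0.0
        )
        dip = max(dip, dip_l, dip_u)
        lo, hi = nlo, nhi
    return dip / 2.0


@lru_cache(maxsize=64)
def _null_dips(n: int, n_boot: int, seed: int) -> tuple[float, ...]:
    rng = np.random.default_rng(seed)
    return tuple(hartigan_dip(rng.random(n)) for _ in range(n_boot))


def dip_test_pvalue(
    values: Sequence[float], n_boot: int = 10_000, seed: int = 0
) -> TestResult:
    """Monte-Carlo p-value of the dip against a uniform null of equal size.

    p is the fraction of ``n_boot`` seeded uniform(0,1) samples of the same
    size whose dip is at least the observed dip; the dip is scale-free, so
    the uniform null serves any sample.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("dip test needs n >= 4")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for a stable p-value")
    d = hartigan_dip(values)
    null = np.array(_null_dips(int(values.size), int(n_boot), int(seed)))
    p = float(np.mean(null >= d))
    return TestResult("hartigan-dip (Monte-Carlo)", d, p)


def angular_summary(
    angles: Sequence[float],
    bin_width: float = 10.0,
    bandwidth: float = 4.0,
    n_boot: int = 10_000,
    seed: int = 0,
) -> AngularSummary:
    """Rose histogram, KDE modes and dip test for one group's angle sample."""
    angles = np.asarray(angles, dtype=float)
    edges, counts = rose_histogram(angles, bin_width)
    modes = angular_modes(angles, bandwidth)
    if angles.size >= 4:
        dip_res = dip_test_pvalue(angles, n_boot=n_boot, seed=seed)
        dip, dip_p = dip_res.statistic, dip_res.p_value
    else:
        dip, dip_p = (hartigan_dip(angles) if angles.size else 0.0), None
    return AngularSummary(edges, counts, modes, dip, dip_p)
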