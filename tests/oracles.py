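"""Independent oracles used by the test suite.

Everything here is deliberately coded from scratch (path enumeration, LP
feasibility, direct permutation), sharing no logic with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog
from scipy.stats import rankdata

from villimorph.tree_model import Branch, VillousTree


# ---------------------------------------------------------------------------
# Terminal distance ordering: exhaustive downstream path search
# ---------------------------------------------------------------------------

def brute_force_orders(tree: VillousTree) -> dict[str, int]:
    """Order of a branch = min node count to a terminal end, by enumerating
    every downstream path explicitly."""
    orders = {}
    for bid in tree.branches:
        best = None
        stack = [(bid, 0)]
        while stack:
            cur, nodes = stack.pop()
            if tree.branches[cur].ends_terminal:
                best = nodes if best is None else min(best, nodes)
            else:
                for k in tree.children_of(cur):
                    stack.append((k, nodes + 1))
        orders[bid] = best
    return orders


def random_tree(rng: np.random.Generator, max_branches: int = 50) -> VillousTree:
    """A random rooted tree with 2-3 children per node, straight unit branches."""
    branches: dict[str, Branch] = {}
    counter = [0]
    work = []  # (parent_bid, start point)

    def add_branch(parent_bid, start):
        bid = f"b{counter[0]:03d}"
        counter[0] += 1
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        end = start + d
        nkids = int(rng.integers(2, 4))
        # expanding must leave room for >= 2 children each a full branch
        expand = counter[0] + nkids <= max_branches and rng.random() < 0.75
        branches[bid] = Branch(
            bid,
            np.vstack([start, end]),
            np.array([1.0, 1.0]),
            parent_id=parent_bid,
            ends_terminal=not expand,
        )
        if expand:
            for _ in range(nkids):
                work.append((bid, end))
        return bid

    root = add_branch(None, np.zeros(3))
    while work:
        parent, start = work.pop(int(rng.integers(len(work))))
        add_branch(parent, start)
    return VillousTree("random", branches, root)


# ---------------------------------------------------------------------------
# Hartigan dip: LP feasibility over piecewise-linear unimodal CDFs
# ---------------------------------------------------------------------------

def dip_oracle_lp(x) -> float:
    """Minimize sup|F - G| over unimodal G by linear programming.

    G is piecewise linear on the distinct data values, their midpoints and
    two far-out anchors (G=0 / G=1); for each candidate mode knot, G is
    convex to its left and concave to its right, with a jump allowed only at
    the mode.  At each data value v the corridor is
    G(v) >= F(v) - d and G(v-) <= F(v-) + d; d is minimized.
    """
    x = np.sort(np.asarray(x, float))
    n = x.size
    v, counts = np.unique(x, return_counts=True)
    if v.size == 1:
        return 0.0
    cum = np.cumsum(counts) / n
    low = cum - counts / n
    span = v[-1] - v[0]
    mids = (v[:-1] + v[1:]) / 2
    grid = np.sort(np.concatenate([[v[0] - 1e6 * span], v, mids, [v[-1] + 1e6 * span]]))
    K = grid.size
    data_pos = {val: int(np.searchsorted(grid, val)) for val in v}

    best = np.inf
    for mode_k in range(K):
        nv = K + 2          # grid values + pre-jump value at the mode + d
        PRE, D = K, K + 1
        A_ub, b_ub = [], []

        def leq(coefs, rhs):
            row = np.zeros(nv)
            for k, c in coefs.items():
                row[k] += c
            A_ub.append(row)
            b_ub.append(rhs)

        for k in range(K - 1):
            if k + 1 == mode_k:
                leq({k: 1, PRE: -1}, 0.0)
            else:
                leq({k: 1, k + 1: -1}, 0.0)
        if mode_k > 0:
            leq({PRE: 1, mode_k: -1}, 0.0)

        def val_var(k):  # value of G approached from the left at grid point k
            return PRE if (k == mode_k and k != 0) else k

        for k in range(1, mode_k):
            h1, h2 = grid[k] - grid[k - 1], grid[k + 1] - grid[k]
            leq({val_var(k - 1): -1 / h1, k: 1 / h1 + 1 / h2, val_var(k + 1): -1 / h2}, 0.0)
        for k in range(mode_k + 1, K - 1):
            h1, h2 = grid[k] - grid[k - 1], grid[k + 1] - grid[k]
            leq({k - 1: 1 / h1, k: -1 / h1 - 1 / h2, k + 1: 1 / h2}, 0.0)
        for val, lo_p, cu_p in zip(v, low, cum):
            k = data_pos[val]
            leq({k: -1, D: -1}, -cu_p)          # G(v) >= F(v) - d
            leq({val_var(k): 1, D: -1}, lo_p)   # G(v-) <= F(v-) + d
        bounds = [(0, 1)] * (K + 1) + [(0, 0.5)]
        bounds[0] = (0, 0)
        bounds[K - 1] = (1, 1)
        c_obj = np.zeros(nv)
        c_obj[D] = 1.0
        res = linprog(c_obj, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=bounds, method="highs")
        if res.success:
            best = min(best, res.fun)
    return float(best)


# ---------------------------------------------------------------------------
# Permutation oracles for rank statistics (independent implementations)
# ---------------------------------------------------------------------------

def kw_statistic_oracle(values: np.ndarray, groups: np.ndarray) -> float:
    """Tie-corrected H computed directly from rank sums."""
    N = values.size
    ranks = rankdata(values)
    h = 0.0
    for g in np.unique(groups):
        r = ranks[groups == g]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, t = np.unique(values, return_counts=True)
    corr = 1.0 - np.sum(t.astype(float) ** 3 - t) / (N**3 - N)
    return h / corr if corr > 0 else 0.0


def kw_perm_pvalue(values, groups, n_perm: int, seed: int) -> tuple[float, float]:
    """Permutation p-value of H and its Monte-Carlo SE."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    h_obs = kw_statistic_oracle(values, groups)
    hits = sum(
        kw_statistic_oracle(values, rng.permutation(groups)) >= h_obs - 1e-12
        for _ in range(n_perm)
    )
    p = hits / n_perm
    return p, max(np.sqrt(p * (1 - p) / n_perm), 1e-4)


def dunn_z_oracle(values: np.ndarray, groups: np.ndarray, a, b) -> float:
    N = values.size
    ranks = rankdata(values)
    _, t = np.unique(values, return_counts=True)
    var = N * (N + 1) / 12.0 - np.sum(t.astype(float) ** 3 - t) / (12.0 * (N - 1))
    ra, rb = ranks[groups == a], ranks[groups == b]
    return (ra.mean() - rb.mean()) / np.sqrt(var * (1 / ra.size + 1 / rb.size))


def dunn_perm_pvalue(values, groups, a, b, n_perm: int, seed: int) -> tuple[float, float]:
    """Two-sided permutation p-value of Dunn's z for one pair, plus its SE."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    z_obs = abs(dunn_z_oracle(values, groups, a, b))
    hits = sum(
        abs(dunn_z_oracle(values, rng.permutation(groups), a, b)) >= z_obs - 1e-12
        for _ in range(n_perm)
    )
    p = hits / n_perm
    return p, max(np.sqrt(p * (1 - p) / n_perm), 1e-4)
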