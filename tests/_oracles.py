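"""Independent brute-force reference implementations used only by tests.

Each oracle restates its operation's definition in the most direct form
available (recursion, exhaustive enumeration, O(n^2) scans) so that the
package's optimized implementations can be checked against something that
shares none of their code paths.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def levenshtein_recursive(a, b, _memo=None):
    """Edit distance straight from the recursive definition (memoized)."""
    if _memo is None:
        _memo = {}
    a, b = tuple(a), tuple(b)
    key = (a, b)
    if key in _memo:
        return _memo[key]
    if not a:
        d = len(b)
    elif not b:
        d = len(a)
    else:
        cost = 0 if a[0] == b[0] else 1
        d = min(
            levenshtein_recursive(a[1:], b, _memo) + 1,
            levenshtein_recursive(a, b[1:], _memo) + 1,
            levenshtein_recursive(a[1:], b[1:], _memo) + cost,
        )
    _memo[key] = d
    return d


def dbscan_bruteforce(points, eps, min_pts):
    """DBSCAN by direct neighborhood expansion over the O(n^2) distance matrix.

    Returns (labels, core) with noise = -1.  Border points join the cluster
    of whichever core point reaches them first in scan order, which matches
    scikit-learn's ordering semantics.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=bool)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    neighbors = [np.flatnonzero(d2[i] <= eps * eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels, core


def same_partition(labels_a, labels_b):
    """True if two clusterings agree up to relabelling (noise fixed at -1)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        return False
    if not np.array_equal(labels_a == -1, labels_b == -1):
        return False
    mapping: dict[int, int] = {}
    seen: set[int] = set()
    for a, b in zip(labels_a, labels_b):
        if a == -1:
            continue
        if a in mapping:
            if mapping[a] != b:
                return False
        else:
            if b in seen:
                return False
            mapping[a] = b
            seen.add(b)
    return True


def mann_whitney_u(x, y):
    """U statistic of x: #(x_i > y_j) pairs with ties counting one half."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_exact_p(x, y):
    """Exact two-sided p by full enumeration of all C(n_x+n_y, n_x) labelings.

    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))) over the permutation
    distribution of the first-sample U statistic.
    """
    x = list(x)
    y = list(y)
    pooled = x + y
    n = len(pooled)
    u_obs = mann_whitney_u(x, y)
    total = comb(n, len(x))
    n_le = n_ge = 0
    for idx in combinations(range(n), len(x)):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in set(idx)]
        u = mann_whitney_u(xs, ys)
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def containment_cell(x, y, grid):
    """Cell of (x, y) by scanning every cell's half-open rectangle."""
    if not (0 <= x <= grid.width and 0 <= y <= grid.height):
        return None
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x0, x1 = c * grid.cell_width, (c + 1) * grid.cell_width
            y0, y1 = r * grid.cell_height, (r + 1) * grid.cell_height
            right = x < x1 or (c == grid.n_cols - 1 and x <= grid.width)
            bottom = y < y1 or (r == grid.n_rows - 1 and y <= grid.height)
            if x0 <= x and right and y0 <= y and bottom:
                return (r, c)
    return None


def all_sequences(alphabet, max_len):
    """Every token sequence of length 0..max_len over the alphabet."""
    seqs = [()]
    frontier = [()]
    for _ in range(max_len):
        frontier = [s + (t,) for s in frontier for t in alphabet]
        seqs.extend(frontier)
    return seqs
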