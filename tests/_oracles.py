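"""Independent oracles for the test suite.

Everything here is deliberately written against *different* formulations
than the implementation: exhaustive enumeration for MSTs, the cross-product
closed form for point-segment distance, and dense parametric sampling for
inter-segment distances.  None of it imports pantracks internals.
"""

from __future__ import annotations

import numpy as np
from numba import njit


# ---------------------------------------------------------------------------
# Exhaustive MST oracle: enumerate all n^(n-2) labelled spanning trees of the
# complete graph via Prüfer sequences and return the minimum total weight.
# ---------------------------------------------------------------------------

@njit(cache=False)
def _min_spanning_weight_numba(dist: np.ndarray, n: int) -> float:  # pragma: no cover
    n_seq = 1
    for _ in range(n - 2):
        n_seq *= n
    best = 1e300
    seq = np.empty(max(n - 2, 1), np.int64)
    for code in range(n_seq):
        c = code
        for k in range(n - 2):
            seq[k] = c % n
            c //= n
        deg = np.ones(n, np.int64)
        for k in range(n - 2):
            deg[seq[k]] += 1
        used = np.zeros(n, np.bool_)
        w = 0.0
        for k in range(n - 2):
            leaf = -1
            for v in range(n):
                if not used[v] and deg[v] == 1:
                    leaf = v
                    break
            w += dist[leaf, seq[k]]
            used[leaf] = True
            deg[seq[k]] -= 1
        u = -1
        v2 = -1
        for x in range(n):
            if not used[x] and deg[x] == 1:
                if u == -1:
                    u = x
                else:
                    v2 = x
        w += dist[u, v2]
        if w < best:
            best = w
    return best


def exhaustive_mst_length(points: np.ndarray) -> float:
    """Minimum spanning-tree length over all labelled spanning trees.

    *points* is an (n, 2) array, 2 <= n <= 9 (9^7 trees is the practical
    ceiling).  Enumerates every Prüfer sequence.
    """
    n = len(points)
    diff = points[:, None, :] - points[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    if n == 2:
        return float(dist[0, 1])
    return float(_min_spanning_weight_numba(dist, n))


def enumerate_spanning_tree_lengths(points: np.ndarray) -> list:
    """Total lengths of ALL labelled spanning trees (pure Python, tiny n).

    Independent of the numba path; usable for n <= 5 fixtures where the
    full length multiset matters (e.g. verifying a merge result against
    every alternative tree).
    """
    import itertools

    n = len(points)
    diff = points[:, None, :] - points[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    if n == 2:
        return [float(dist[0, 1])]
    out = []
    for seq in itertools.product(range(n), repeat=n - 2):
        deg = [1] * n
        for v in seq:
            deg[v] += 1
        used = [False] * n
        w = 0.0
        for v in seq:
            leaf = next(x for x in range(n) if not used[x] and deg[x] == 1)
            w += dist[leaf, v]
            used[leaf] = True
            deg[v] -= 1
        u, v2 = [x for x in range(n) if not used[x] and deg[x] == 1]
        w += dist[u, v2]
        out.append(float(w))
    return out


# ---------------------------------------------------------------------------
# Point-segment distance: cross-product closed form.
# ---------------------------------------------------------------------------

def point_segment_oracle(px, py, ax, ay, bx, by):
    """Analytic distance and foot test, vectorised.

    Perpendicular distance |cross(b-a, p-a)| / |b-a| where the projection
    parameter lies in [0, 1], else distance to the nearer endpoint.
    Returns (distance, inside) arrays.
    """
    px, py, ax, ay, bx, by = map(np.asarray, (px, py, ax, ay, bx, by))
    dx = bx - ax
    dy = by - ay
    l2 = dx * dx + dy * dy
    t = ((px - ax) * dx + (py - ay) * dy) / np.where(l2 > 0, l2, 1.0)
    d_perp = np.abs(dx * (py - ay) - dy * (px - ax)) / np.sqrt(np.where(l2 > 0, l2, 1.0))
    d_end = np.minimum(np.hypot(px - ax, py - ay), np.hypot(px - bx, py - by))
    inside = (l2 > 0) & (t >= 0.0) & (t <= 1.0)
    return np.where(inside, d_perp, d_end), inside


# ---------------------------------------------------------------------------
# Inter-segment minimum distance: dense parametric sampling.
# ---------------------------------------------------------------------------

def dmin_sampling_oracle(s1, s2, k: int = 1000) -> float:
    """Brute-force minimum distance over a k x k parametric grid."""
    (a1, b1), (a2, b2) = s1, s2
    t = np.linspace(0.0, 1.0, k)
    p1 = np.asarray(a1) + t[:, None] * (np.asarray(b1) - np.asarray(a1))
    p2 = np.asarray(a2) + t[:, None] * (np.asarray(b2) - np.asarray(a2))
    dx = p1[:, None, 0] - p2[None, :, 0]
    dy = p1[:, None, 1] - p2[None, :, 1]
    return float(np.hypot(dx, dy).min())
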