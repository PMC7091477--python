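"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: DBSCAN is re-derived
from the O(n^2) pairwise distance matrix, and the rank-sum p-value from
exhaustive enumeration of group assignments.
"""

from itertools import combinations

import numpy as np

from polyquant.datatypes import LocalizationTable


def brute_force_dbscan(locs: LocalizationTable, eps: float, min_pts: int) -> np.ndarray:
    """O(n^2) DBSCAN with the canonical (frame, x, y) tie-break.

    Core points have >= min_pts points (self included) within eps; clusters
    are connected components of core points numbered by the canonical rank
    of their first core point; border points join the lowest reachable
    cluster id.  Returns labels in the input row order (-1 = noise).
    """
    n = len(locs)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels
    order = np.lexsort((locs.y_nm, locs.x_nm, locs.frame))
    pts = np.column_stack([locs.x_nm[order], locs.y_nm[order]])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    adj = d <= eps
    core = adj.sum(axis=1) >= min_pts

    lab = np.full(n, -1, dtype=np.int64)
    cid = 0
    for i in range(n):
        if not core[i] or lab[i] != -1:
            continue
        frontier = [i]
        lab[i] = cid
        while frontier:
            j = frontier.pop()
            for k in np.flatnonzero(adj[j] & core):
                if lab[k] == -1:
                    lab[k] = cid
                    frontier.append(int(k))
        cid += 1
    for i in range(n):
        if core[i]:
            continue
        reachable = lab[adj[i] & core]
        if len(reachable):
            lab[i] = reachable.min()
    labels[order] = lab
    return labels


def same_partition(labels_a: np.ndarray, labels_b: np.ndarray) -> bool:
    """True when two labelings agree up to a permutation of cluster ids."""
    if len(labels_a) != len(labels_b):
        return False
    if not np.array_equal(labels_a == -1, labels_b == -1):
        return False
    mapping: dict[int, int] = {}
    reverse: dict[int, int] = {}
    for a, b in zip(labels_a, labels_b):
        if a == -1:
            continue
        if mapping.setdefault(int(a), int(b)) != b:
            return False
        if reverse.setdefault(int(b), int(a)) != a:
            return False
    return True


def exact_rank_sum_p(a, b) -> float:
    """Two-sided Mann-Whitney p by exhaustive enumeration (no ties)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    n_a = len(a)

    def u_of(sel):
        u = 0
        rest = [v for i, v in enumerate(pooled) if i not in sel]
        for i in sel:
            u += sum(pooled[i] > w for w in rest)
        return u

    sel_obs = tuple(sorted(pooled.index(v) for v in a))
    # pooled.index misbehaves with duplicates; oracle restricted to tie-free data
    assert len(set(pooled)) == len(pooled)
    u_obs = u_of(sel_obs)
    n = len(pooled)
    mean_u = n_a * (n - n_a) / 2
    count = 0
    total = 0
    for sel in combinations(range(n), n_a):
        u = u_of(sel)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total
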