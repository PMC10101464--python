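"""Independent brute-force oracles used only by the test suite.

Each function here is a deliberately simple reference implementation, written
separately from the package code paths it checks.
"""

from __future__ import annotations

import numpy as np

NEG_INF = float("-inf")


def sw_affine_score(a: str, b: str, match=5, mismatch=-4, open_=-8, extend=-2) -> float:
    """Full-DP Smith–Waterman with affine gaps (gap of length L costs
    open + (L-1)*extend); returns the best local score (floor 0)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + open_, E[i, j - 1] + extend)
            F[i, j] = max(H[i - 1, j] + open_, F[i - 1, j] + extend)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def infix_edit_distance(query: str, target: str) -> int:
    """Unbanded DP edit distance of `query` against the best-matching infix of
    `target` (end gaps on the target are free)."""
    n, m = len(query), len(target)
    prev = np.zeros(m + 1, dtype=int)  # empty-query row: free target prefix
    for i in range(1, n + 1):
        cur = np.empty(m + 1, dtype=int)
        cur[0] = i
        for j in range(1, m + 1):
            cost = 0 if query[i - 1] == target[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev.min())


def mcl_dense_oracle(nodes, weighted_edges, inflation=2.0, iterations=200):
    """Plain dense MCL iteration (no pruning, no convergence test) run for a
    fixed number of rounds; clusters read off attractor-row supports."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, w in weighted_edges:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(m, loop)
    m = m / m.sum(axis=0)
    for _ in range(iterations):
        m = m @ m
        m = m ** inflation
        m = m / m.sum(axis=0)
    labels = {}
    attractors = [i for i in range(n) if m[i, i] > 1e-9]
    for j in range(n):
        masses = [(m[i, j], -i) for i in attractors if m[i, j] > 1e-9]
        owner = -max(masses)[1] if masses else j
        labels[nodes[j]] = owner
    return labels


def shared_count_oracle(mat: np.ndarray) -> np.ndarray:
    """Pairwise row set-intersection sizes by an explicit double loop."""
    n = mat.shape[0]
    sets = [set(np.nonzero(row)[0]) for row in mat]
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for k in range(n):
            out[i, k] = len(sets[i] & sets[k])
    return out


def partitions_equal(a: dict, b: dict) -> bool:
    """True iff two label maps induce the same partition of the same keys."""
    if set(a) != set(b):
        return False
    groups_a = {}
    groups_b = {}
    for k in a:
        groups_a.setdefault(a[k], set()).add(k)
        groups_b.setdefault(b[k], set()).add(k)
    return set(map(frozenset, groups_a.values())) == set(
        map(frozenset, groups_b.values())
    )
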