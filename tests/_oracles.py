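"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's algorithms: cluster distances are
recomputed from the original pairwise distances at every agglomeration
step (closed form for Ward), the waterfall sample order is found by
exhaustive permutation search, and leader crossings are checked by
pairwise segment intersection.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def _square(d: np.ndarray, n: int) -> np.ndarray:
    sq = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            sq[i, j] = sq[j, i] = d[k]
            k += 1
    return sq


def _cluster_distance(A, B, D, method):
    A, B = list(A), list(B)
    if method == "single":
        return min(D[a, b] for a in A for b in B)
    if method == "complete":
        return max(D[a, b] for a in A for b in B)
    if method == "average":
        return float(np.mean([D[a, b] for a in A for b in B]))
    # ward: closed form over original distances
    nA, nB = len(A), len(B)
    D2 = D**2
    cross = sum(D2[a, b] for a in A for b in B) / (nA * nB)
    wA = sum(D2[a, b] for a in A for b in A) / (2 * nA * nA)
    wB = sum(D2[a, b] for a in B for b in B) / (2 * nB * nB)
    return float(np.sqrt(max(0.0, (2 * nA * nB / (nA + nB)) * (cross - wA - wB))))


def brute_force_linkage(d: np.ndarray, n: int, method: str):
    """O(n^3+) agglomeration recomputing cluster distances from scratch.

    Returns (merges, partitions) where merges is a list of
    (lo_node, hi_node, height) and partitions[k] is the set-partition into
    k clusters (frozensets of leaves) that existed when k clusters were
    active. Tie rule: smallest (lo, hi) node-id pair.
    """
    D = _square(np.asarray(d, dtype=float), n)
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges = []
    partitions = {n: set(clusters.values())}
    for step in range(n - 1):
        best = None
        for a, b in combinations(sorted(clusters), 2):
            dist = _cluster_distance(clusters[a], clusters[b], D, method)
            lo, hi = min(a, b), max(a, b)
            cand = (dist, lo, hi)
            if best is None or cand < best:
                best = cand
        dist, lo, hi = best
        merges.append((lo, hi, dist))
        merged = clusters.pop(lo) | clusters.pop(hi)
        clusters[n + step] = merged
        partitions[n - step - 1] = set(clusters.values())
    return merges, partitions


def brute_force_leaf_order(merges, n: int) -> list[int]:
    """Recursive traversal; the child subtree holding the smaller original
    leaf index goes left."""
    children = {n + t: (l, r) for t, (l, r, _) in enumerate(merges)}

    def walk(node):
        if node < n:
            return [node]
        l, r = children[node]
        wl, wr = walk(l), walk(r)
        return wl + wr if min(wl) <= min(wr) else wr + wl

    return walk(2 * n - 2) if n > 1 else [0]


def brute_force_memo_samples(gene_order, samples, cells):
    """Exhaustive search for the sample permutation whose sequence of
    binary altered-vectors (in gene order) is lexicographically greatest;
    ties resolved toward the original sample order."""
    def vec(s):
        return tuple(1 if (g, s) in cells else 0 for g in gene_order)

    best_score = None
    best_perm = None
    for perm in permutations(range(len(samples))):
        score = tuple(vec(samples[i]) for i in perm)
        if (
            best_score is None
            or score > best_score
            or (score == best_score and perm < best_perm)
        ):
            best_score, best_perm = score, perm
    return [samples[i] for i in best_perm]


def segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments p1-p2 and p3-p4."""
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def count_leader_crossings(leaders) -> int:
    """Pairwise crossings between leader polylines (lists of points)."""
    crossings = 0
    for (la, lb) in combinations(leaders, 2):
        segs_a = list(zip(la, la[1:]))
        segs_b = list(zip(lb, lb[1:]))
        if any(
            segments_intersect(a0, a1, b0, b1)
            for a0, a1 in segs_a
            for b0, b1 in segs_b
        ):
            crossings += 1
    return crossings
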