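"""Agglomerative clustering, leaf ordering, tree cuts and split resolution.

The engine carries its own agglomerator rather than delegating, because
display order must be reproducible bit-for-bit across platforms: the
tie-break rule (among equally close cluster pairs, merge the pair whose
(lower node id, higher node id) is lexicographically smallest) and the
left-child convention (the lower-indexed node at merge time) are part of
the contract. Supported linkages are single, complete, average (UPGMA)
and Ward; supported metrics are euclidean, cityblock and correlation
(1 - Pearson r). All are monotone linkages, so merge heights are
non-decreasing.

Missing values are handled pairwise-complete in the distance step; a pair
of items with no co-observed entries is an error, never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import LabeledMatrix, SceneMapError

METHODS = ("single", "complete", "average", "ward")
METRICS = ("euclidean", "correlation", "cityblock")


@dataclass
class LinkageResult:
    """Agglomerative merge tree over ``n_leaves`` items.

    ``merges[t] = (left, right, height)`` merges nodes ``left < right``
    into new node ``n_leaves + t``; node ids 0..n-1 are leaves.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int
    method: str
    metric: str

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise SceneMapError(
                f"{self.n_leaves} leaves need {self.n_leaves - 1} merges, "
                f"got {len(self.merges)}"
            )

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def children(self) -> dict[int, tuple[int, int]]:
        return {
            self.n_leaves + t: (l, r) for t, (l, r, _) in enumerate(self.merges)
        }


@dataclass
class SplitResolution:
    """Ordered partition of axis positions into display groups.

    ``groups`` is a list of (label, member_indices); group order and the
    within-group member order are the final display order. ``group_links``
    holds per-group trees where a categorical split was re-clustered
    internally, aligned with ``groups`` (None where no tree applies).
    """

    groups: list[tuple[str, list[int]]]
    group_links: list[LinkageResult | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.group_links:
            self.group_links = [None] * len(self.groups)
        n = sum(len(m) for _, m in self.groups)
        flat = self.order()
        if sorted(flat) != list(range(n)):
            raise SceneMapError("split groups must partition the axis positions")

    def order(self) -> list[int]:
        out: list[int] = []
        for _, members in self.groups:
            out.extend(members)
        return out

    def sizes(self) -> list[int]:
        return [len(m) for _, m in self.groups]

    @property
    def labels(self) -> list[str]:
        return [g for g, _ in self.groups]


def _axis_data(matrix: LabeledMatrix, axis: str) -> tuple[np.ndarray, list[str]]:
    if axis in ("rows", "row", 0):
        return matrix.values, matrix.row_ids
    if axis in ("cols", "col", "columns", 1):
        return matrix.values.T, matrix.col_ids
    raise SceneMapError(f"axis must be 'rows' or 'cols', got {axis!r}")


def pairwise_distance(
    matrix: LabeledMatrix, axis: str = "rows", metric: str = "euclidean"
) -> np.ndarray:
    """Condensed distance vector over the chosen axis.

    Distances use pairwise-complete observations: each pair is compared
    over the entries observed in both items. The correlation metric is
    1 - Pearson r over co-observed entries.
    """
    if metric not in METRICS:
        raise SceneMapError(f"unsupported metric {metric!r}; choose from {METRICS}")
    data, ids = _axis_data(matrix, axis)
    n = data.shape[0]
    if n < 2:
        raise SceneMapError("need at least 2 items to compute distances")
    obs = np.isfinite(data)
    for i in range(n):
        if not obs[i].any():
            raise SceneMapError(f"item {ids[i]!r} has no observed values")
        if metric == "correlation":
            vals = data[i][obs[i]]
            if vals.size and np.ptp(vals) == 0.0:
                raise SceneMapError(
                    f"zero-variance item {ids[i]!r} under correlation metric"
                )
    out = np.empty(n * (n - 1) // 2, dtype=float)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            if not both.any():
                raise SceneMapError(
                    f"items {ids[i]!r} and {ids[j]!r} share no observed entries"
                )
            a, b = data[i][both], data[j][both]
            if metric == "euclidean":
                d = float(np.sqrt(np.sum((a - b) ** 2)))
            elif metric == "cityblock":
                d = float(np.sum(np.abs(a - b)))
            else:  # correlation
                a0, b0 = a - a.mean(), b - b.mean()
                denom = np.sqrt(np.sum(a0**2) * np.sum(b0**2))
                if denom == 0.0:
                    raise SceneMapError(
                        f"zero variance between {ids[i]!r} and {ids[j]!r} "
                        "over co-observed entries"
                    )
                d = float(1.0 - np.sum(a0 * b0) / denom)
            out[k] = d
            k += 1
    return out


def _condensed_to_square(d: np.ndarray, n: int) -> np.ndarray:
    if len(d) != n * (n - 1) // 2:
        raise SceneMapError(
            f"condensed vector length {len(d)} does not fit {n} leaves"
        )
    sq = np.zeros((n, n), dtype=float)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            sq[i, j] = sq[j, i] = d[k]
            k += 1
    return sq


def linkage(
    distances: np.ndarray,
    method: str = "average",
    n_leaves: int | None = None,
    metric: str = "euclidean",
) -> LinkageResult:
    """Agglomerate a condensed distance vector into a merge tree.

    Inter-cluster distances follow the Lance–Williams updates for the
    chosen method (Ward on squared distances, heights as square roots).
    Ties are broken toward the pair with the lexicographically smallest
    (lower, higher) node ids.
    """
    if method not in METHODS:
        raise SceneMapError(f"unsupported method {method!r}; choose from {METHODS}")
    distances = np.asarray(distances, dtype=float)
    if not np.all(np.isfinite(distances)):
        raise SceneMapError("distances contain NaN or infinity")
    if n_leaves is None:
        # invert k = n(n-1)/2
        n_leaves = int(round((1 + np.sqrt(1 + 8 * len(distances))) / 2))
    n = n_leaves
    if n < 2:
        raise SceneMapError("need at least 2 leaves")
    D = _condensed_to_square(distances, n)
    if method == "ward":
        D = D**2
    node_of = list(range(n))  # active slot -> node id
    size = [1] * n
    active = list(range(n))  # active slots
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        best = None  # (dist, lo_node, hi_node, slot_i, slot_j)
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                si, sj = active[ai], active[aj]
                d = D[si, sj]
                ni, nj = node_of[si], node_of[sj]
                lo, hi = (ni, nj) if ni < nj else (nj, ni)
                cand = (d, lo, hi, si, sj)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        d, lo, hi, si, sj = best
        height = float(np.sqrt(d)) if method == "ward" else float(d)
        merges.append((lo, hi, height))
        ni, nj = size[si], size[sj]
        # update distances from the merged cluster (kept in slot si)
        for sk in active:
            if sk in (si, sj):
                continue
            dik, djk, dij = D[si, sk], D[sj, sk], D[si, sj]
            nk = size[sk]
            if method == "single":
                dnew = min(dik, djk)
            elif method == "complete":
                dnew = max(dik, djk)
            elif method == "average":
                dnew = (ni * dik + nj * djk) / (ni + nj)
            else:  # ward, on squared distances
                dnew = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (
                    ni + nj + nk
                )
            D[si, sk] = D[sk, si] = dnew
        node_of[si] = n + step
        size[si] = ni + nj
        active.remove(sj)
    return LinkageResult(merges=merges, n_leaves=n, method=method, metric=metric)


def leaf_order(link: LinkageResult) -> list[int]:
    """Left-to-right leaf permutation of the merge tree.

    Depth-first from the root; at every internal node the left child is
    the subtree containing the smaller original leaf index, so the leaf
    carrying index 0 always sits leftmost.
    """
    n = link.n_leaves
    children = link.children()
    min_leaf: dict[int, int] = {i: i for i in range(n)}
    for t, (l, r, _) in enumerate(link.merges):
        min_leaf[n + t] = min(min_leaf[l], min_leaf[r])
    order: list[int] = []
    stack = [2 * n - 2] if n > 1 else [0]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            a, b = children[node]
            left, right = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
            stack.append(right)
            stack.append(left)
    return order


def cut_tree(link: LinkageResult, k: int) -> list[int]:
    """Flat clustering by undoing the last ``k - 1`` merges.

    Returns a label in 1..k per leaf; labels are numbered by first
    appearance in leaf order.
    """
    n = link.n_leaves
    if not 1 <= k <= n:
        raise SceneMapError(f"k={k} out of range 1..{n}")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for t in range(n - k):
        left, right, _ = link.merges[t]
        members[n + t] = members.pop(left) + members.pop(right)
    # members now holds the k surviving subtrees
    pos = {leaf: p for p, leaf in enumerate(leaf_order(link))}
    roots = sorted(members.values(), key=lambda m: min(pos[x] for x in m))
    labels = [0] * n
    for lab, mem in enumerate(roots, start=1):
        for leaf in mem:
            labels[leaf] = lab
    return labels


def resolve_split(
    matrix: LabeledMatrix,
    axis: str,
    split: int | Sequence | None = None,
    link: LinkageResult | None = None,
    group_order: Sequence[str] | None = None,
) -> SplitResolution:
    """Resolve a split request into ordered display groups.

    ``split`` may be None (one group), an integer k (cut of the global
    tree, which requires ``link``), or a categorical vector along the
    axis. Integer-split groups are ordered by leaf order with members in
    leaf order. Categorical groups come in first-appearance order (or
    ``group_order``); when a tree is available each group is re-ordered
    by a linkage computed on that group alone.
    """
    data, ids = _axis_data(matrix, axis)
    n = data.shape[0]

    if split is None:
        order = leaf_order(link) if link is not None else list(range(n))
        return SplitResolution(groups=[("all", order)])

    if isinstance(split, (int, np.integer)):
        if link is None:
            raise SceneMapError("integer split requires a clustering tree")
        labels = cut_tree(link, int(split))
        order = leaf_order(link)
        groups: dict[int, list[int]] = {}
        group_seq: list[int] = []
        for leaf in order:
            lab = labels[leaf]
            if lab not in groups:
                groups[lab] = []
                group_seq.append(lab)
            groups[lab].append(leaf)
        return SplitResolution(
            groups=[(str(lab), groups[lab]) for lab in group_seq]
        )

    # categorical vector
    vec = list(split)
    if len(vec) != n:
        raise SceneMapError(
            f"categorical split has {len(vec)} entries for {n} axis positions"
        )
    missing = [ids[i] for i, v in enumerate(vec) if v is None or str(v).strip() == ""]
    if missing:
        raise SceneMapError(
            "categorical split has missing entries for ids: " + ", ".join(missing)
        )
    vec = [str(v) for v in vec]
    levels: list[str] = []
    for v in vec:
        if v not in levels:
            levels.append(v)
    if group_order is not None:
        extra = [l for l in levels if l not in group_order]
        if extra:
            raise SceneMapError(
                "group_order is missing observed levels: " + ", ".join(extra)
            )
        levels = [l for l in group_order if l in levels]
    members0 = {lev: [i for i, v in enumerate(vec) if v == lev] for lev in levels}
    groups_out: list[tuple[str, list[int]]] = []
    group_links: list[LinkageResult | None] = []
    for lev in levels:
        mem = members0[lev]
        glink = None
        if link is not None and len(mem) >= 2:
            sub = (
                matrix.take_rows(mem)
                if axis in ("rows", "row", 0)
                else matrix.take_cols(mem)
            )
            d = pairwise_distance(sub, axis="rows" if axis in ("rows", "row", 0) else "cols", metric=link.metric)
            glink = linkage(d, method=link.method, n_leaves=len(mem), metric=link.metric)
            mem = [mem[p] for p in leaf_order(glink)]
        groups_out.append((lev, mem))
        group_links.append(glink)
    return SplitResolution(groups=groups_out, group_links=group_links)
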