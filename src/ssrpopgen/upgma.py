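"""UPGMA clustering of a population distance matrix and Newick output.

True average linkage: the distance between clusters is the arithmetic
mean of all inter-leaf distances, maintained incrementally through the
cluster-size-weighted update
``d(ij, k) = (n_i d(i,k) + n_j d(j,k)) / (n_i + n_j)``.
Each merge is placed at half the merged distance, so the cophenetic
distance between two leaves is twice the height of their lowest common
merge, and the resulting tree is ultrametric with non-decreasing merge
heights.

Ties on the minimal distance are broken deterministically by the
lexicographically smallest pair of cluster representative labels (the
representative being the smallest leaf label contained).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["UltrametricTree", "upgma", "to_newick", "cluster_membership"]

_PLAIN_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


@dataclass(frozen=True)
class UltrametricTree:
    """UPGMA merge history over a fixed leaf set.

    Leaves are nodes ``0 .. n-1`` in input order; merge ``m`` creates
    internal node ``n + m`` from ``(left, right)`` at ``height``.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_members(self) -> list[list[int]]:
        """Leaf indices under every node (leaves first, then merges in order)."""
        members = [[i] for i in range(self.n_leaves)]
        for left, right, _ in self.merges:
            members.append(members[left] + members[right])
        return members

    def node_heights(self) -> list[float]:
        return [0.0] * self.n_leaves + [h for _, _, h in self.merges]

    def cophenetic(self) -> np.ndarray:
        """Matrix of cophenetic distances (2 x height of the lowest common merge)."""
        n = self.n_leaves
        out = np.zeros((n, n))
        members = self.node_members()
        for m, (left, right, height) in enumerate(self.merges):
            for a in members[left]:
                for b in members[right]:
                    out[a, b] = out[b, a] = 2.0 * height
        return out


def upgma(d: DistanceMatrix) -> UltrametricTree:
    """Average-linkage agglomeration of a validated distance matrix."""
    if not isinstance(d, DistanceMatrix):
        raise TypeError("upgma expects a DistanceMatrix")
    n = len(d.labels)
    if n < 2:
        raise ValueError("need at least two leaves")
    if not np.isfinite(d.values).all():
        raise ValueError("non-finite distances; substitute a sentinel first")

    size = {i: 1 for i in range(n)}
    rep = {i: d.labels[i] for i in range(n)}  # smallest contained leaf label
    dist = {
        (i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((rep[kv[0][0]], rep[kv[0][1]])))),
        )
        (i, j), dmin = best
        left, right = (i, j) if rep[i] <= rep[j] else (j, i)
        merges.append((left, right, dmin / 2.0))
        new = next_id
        next_id += 1
        for k in active - {i, j}:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(new, k), max(new, k))] = (size[i] * dik + size[j] * djk) / (
                size[i] + size[j]
            )
        del dist[(min(i, j), max(i, j))]
        size[new] = size[i] + size[j]
        rep[new] = min(rep[i], rep[j])
        active -= {i, j}
        active.add(new)
    return UltrametricTree(tuple(d.labels), tuple(merges))


def _quote_label(label: str) -> str:
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(t: UltrametricTree, digits: int = 10) -> str:
    """Newick string with branch lengths equal to height differences.

    Each internal node's children are ordered by their smallest
    contained leaf (in input order); labels with spaces or other
    non-identifier characters are single-quoted.
    """
    heights = t.node_heights()
    children: dict[int, tuple[int, int]] = {
        t.n_leaves + m: (left, right) for m, (left, right, _) in enumerate(t.merges)
    }
    members = t.node_members()

    def render(node: int, parent_height: float) -> str:
        branch = parent_height - heights[node]
        if node < t.n_leaves:
            body = _quote_label(t.leaves[node])
        else:
            kids = sorted(children[node], key=lambda c: min(members[c]))
            body = "(" + ",".join(render(c, heights[node]) for c in kids) + ")"
        return f"{body}:{branch:.{digits}g}"

    root = t.n_leaves + len(t.merges) - 1
    kids = sorted(children[root], key=lambda c: min(members[c]))
    return "(" + ",".join(render(c, heights[root]) for c in kids) + ");"


def cluster_membership(t: UltrametricTree, k: int) -> dict[str, int]:
    """Cut the tree into exactly ``k`` clusters by undoing the last ``k - 1`` merges.

    Cluster indices are assigned in leaf input order starting at 0.  If
    the cut falls inside a run of equal-height merges the division is
    still deterministic (merge order decides) but a warning is logged.
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    kept = t.merges[: n - k]
    if 0 < n - k < len(t.merges):
        h_last_kept = kept[-1][2]
        h_first_cut = t.merges[n - k][2]
        if h_last_kept == h_first_cut:
            logger.warning(
                "cluster cut at k=%d falls inside tied merge heights (%.6g); "
                "resolved by merge order", k, h_first_cut,
            )
    parent = list(range(n + len(kept)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (left, right, _) in enumerate(kept):
        node = n + m
        parent[find(left)] = node
        parent[find(right)] = node

    cluster_of_root: dict[int, int] = {}
    out: dict[str, int] = {}
    for i, leaf in enumerate(t.leaves):
        root = find(i)
        if root not in cluster_of_root:
            cluster_of_root[root] = len(cluster_of_root)
        out[leaf] = cluster_of_root[root]
    return out
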