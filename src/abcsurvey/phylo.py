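"""Neighbor-joining tree construction from a pairwise distance matrix.

The classic Saitou-Nei agglomeration: at each step join the pair minimizing
Q(i,j) = (n-2)d(i,j) - r_i - r_j. On an additive matrix this recovers the
unique generating tree with exact branch lengths (the four-point
condition), which is what the subfamily-assignment stage relies on and what
the tests assert. Output is an unrooted tree serialized as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> set[str]:
        if self.is_leaf():
            return {self.name}
        out: set[str] = set()
        for child, _ in self.children:
            out |= child.leaf_names()
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.name or ""
        inner = ",".join(
            f"{child._newick()}:{length:.6f}" for child, length in self.children
        )
        return f"({inner})" + (self.name or "")


def neighbor_joining(distances: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Build an unrooted NJ tree; the return node is the final trifurcation."""
    n = len(labels)
    if distances.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n < 2:
        raise ValueError("need at least two taxa")
    if not np.allclose(distances, distances.T):
        raise ValueError("distance matrix must be symmetric")
    d = distances.astype(float).copy()
    nodes = [TreeNode(name=label) for label in labels]
    active = list(range(n))

    if n == 2:
        root = TreeNode()
        root.children = [(nodes[0], d[0, 1] / 2), (nodes[1], d[0, 1] / 2)]
        return root

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = dij / 2 + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        new = TreeNode()
        new.children = [(nodes[i], li), (nodes[j], lj)]
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = (d[i, k] + d[j, k] - dij) / 2
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    root = TreeNode()
    root.children = [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    return root


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (one side each), for topology comparison."""
    all_leaves = frozenset(tree.leaf_names())
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode):
        for child, _ in node.children:
            side = frozenset(child.leaf_names())
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(min(side, all_leaves - side, key=sorted))
            walk(child)

    walk(tree)
    return splits
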