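"""Tree utilities shared across the pipeline.

Trees are :class:`skbio.TreeNode` objects throughout: rooted, with branch
lengths, leaves named after genomes or protein ids. Helpers here cover
neighbor joining on corrected distances, midpoint rooting, patristic
distances, bipartition sets for bootstrap supports, and a flat array view
of a rooted tree used by the gain/loss likelihood machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

# p-distances are capped here before the Poisson correction -ln(1-p) so that
# saturated pairs stay finite.
MAX_P_DISTANCE = 0.95


def p_distance_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise p-distances over an encoded alignment (n_rows, n_cols).

    Sites where either row is a gap/unknown (index < 0) are excluded for
    that pair; pairs with no comparable sites get the maximum distance.
    """
    valid = mat >= 0
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        diff = (mat[i] != mat) & both
        nb = both.sum(axis=1)
        nd = diff.sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(nb > 0, nd / np.maximum(nb, 1), MAX_P_DISTANCE)
        d[i] = p
    np.fill_diagonal(d, 0.0)
    return np.minimum((d + d.T) / 2.0, MAX_P_DISTANCE)


def poisson_correct(p: np.ndarray) -> np.ndarray:
    return -np.log(1.0 - np.minimum(p, MAX_P_DISTANCE))


def nj_midpoint(dist: np.ndarray, ids: list[str]) -> TreeNode:
    """Neighbor-joining tree from a distance matrix, midpoint-rooted."""
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    dm = DistanceMatrix(np.maximum(dist, 0.0), ids)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    rooted = tree.root_at_midpoint()
    return rooted


def patristic_matrix(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf ids and the matrix of path-length (patristic) distances."""
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    return ids, dm.data.copy()


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits of the (unrooted view of the) tree.

    Each split is normalised as a frozenset of the two frozensets of leaf
    names, so rooting does not affect membership.
    """
    all_leaves = frozenset(n.name for n in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(frozenset((side, frozenset(other))))
    return splits


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    sa, sb = bipartitions(a), bipartitions(b)
    return len(sa ^ sb)


@dataclass
class TreeArrays:
    """Flat, postorder-indexed view of a rooted tree for vectorised pruning.

    Node 0..n_leaves-1 are leaves (in ``leaf_names`` order); internal nodes
    follow in postorder; the root is last.
    """

    leaf_names: list[str]
    node_names: list[str]
    parent: np.ndarray  # parent index per node; -1 at root
    length: np.ndarray  # branch length to parent; 0 at root
    postorder: np.ndarray  # node indices, children before parents
    children: list[list[int]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])


def tree_arrays(tree: TreeNode) -> TreeArrays:
    tips = list(tree.tips())
    for t in tips:
        if t.length is None:
            raise ValueError(f"leaf {t.name!r} has no branch length")
    leaf_names = [t.name for t in tips]
    index = {id(t): i for i, t in enumerate(tips)}
    nodes = [None] * len(tips)
    order = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            order.append(index[id(node)])
        else:
            if node is not tree and node.length is None:
                raise ValueError("internal node missing branch length")
            index[id(node)] = len(nodes)
            nodes.append(node)
            order.append(index[id(node)])
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    length = np.zeros(n)
    names = [""] * n
    children: list[list[int]] = [[] for _ in range(n)]
    for node in tree.traverse(include_self=True):
        i = index[id(node)]
        names[i] = node.name or f"_n{i}"
        if node.parent is not None:
            p = index[id(node.parent)]
            parent[i] = p
            children[p].append(i)
            length[i] = float(node.length or 0.0)
    return TreeArrays(
        leaf_names=leaf_names,
        node_names=names,
        parent=parent,
        length=length,
        postorder=np.array(order, dtype=np.int64),
        children=children,
    )
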