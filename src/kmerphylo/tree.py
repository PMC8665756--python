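"""Trees from compatible split sets, and Newick serialization.

A pairwise-compatible split system is exactly the edge set of an unrooted
tree.  Newick requires a root, so a synthetic root is placed such that taxon 0
is outside every nontrivial cluster; the rooted tree still represents the
unrooted split system faithfully.
"""

from __future__ import annotations

import re

import dendropy

from kmerphylo.filters import compatible
from kmerphylo.seqio import TaxonTable
from kmerphylo.splits import (
    Split,
    SplitCounts,
    SplitSystem,
    WeightedSplit,
    canonical_side,
    sort_key,
)


class IncompatibleSplitsError(ValueError):
    """Raised when a tree is requested from a non-tree-like split set."""


class TreeNode:
    """Rooted tree node: leaves carry a taxon label, edges a branch length."""

    __slots__ = ("label", "branch_length", "children")

    def __init__(
        self,
        label: str | None = None,
        branch_length: float = 0.0,
        children: list["TreeNode"] | None = None,
    ) -> None:
        self.label = label
        self.branch_length = branch_length
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({to_newick(self)!r})"


#: alias used in type hints across the package
PhyloTree = TreeNode


def check_pairwise_compatible(system: SplitSystem) -> None:
    splits = [ws.split for ws in system.splits]
    for i in range(len(splits)):
        for j in range(i + 1, len(splits)):
            if not compatible(splits[i], splits[j]):
                raise IncompatibleSplitsError(
                    f"splits {splits[i].indices()} and {splits[j].indices()} "
                    "are incompatible; cannot build a tree"
                )


def splits_to_tree(system: SplitSystem) -> TreeNode:
    """Build the rooted tree realizing a pairwise-compatible split system.

    Each split is oriented to the side not containing taxon 0, which turns the
    nontrivial splits into a laminar family of clusters; clusters are inserted
    into a star tree in decreasing size order.  Trivial splits set the leaf
    branch lengths (0 if absent); nontrivial splits set internal branch
    lengths.  Children are ordered by smallest contained taxon index so the
    Newick string is reproducible.
    """
    check_pairwise_compatible(system)
    taxa = system.taxa
    n = taxa.n
    full = (1 << n) - 1
    leaf_weight = [0.0] * n
    clusters: list[tuple[int, float]] = []
    for ws in system.splits:
        side = ws.split.side
        cluster = side if not (side & 1) else side ^ full
        size = cluster.bit_count()
        if size == 1:
            leaf_weight[cluster.bit_length() - 1] = ws.weight
        elif size == n - 1:
            # cluster is everything-but-taxon-0: the trivial split of taxon 0
            leaf_weight[0] = ws.weight
        else:
            clusters.append((cluster, ws.weight))

    leaves = [
        TreeNode(label=taxa.names[i], branch_length=leaf_weight[i]) for i in range(n)
    ]
    root = TreeNode(children=list(leaves))
    mask_of: dict[int, int] = {id(leaves[i]): 1 << i for i in range(n)}
    mask_of[id(root)] = full

    clusters.sort(key=lambda item: (-item[0].bit_count(), item[0]))
    for cluster, weight in clusters:
        node = root
        while True:
            inner = next(
                (
                    child
                    for child in node.children
                    if cluster & mask_of[id(child)] == cluster
                    and mask_of[id(child)] != cluster
                ),
                None,
            )
            if inner is None:
                break
            node = inner
        group = [c for c in node.children if mask_of[id(c)] & cluster == mask_of[id(c)]]
        union = 0
        for c in group:
            union |= mask_of[id(c)]
        if union != cluster:
            raise IncompatibleSplitsError(
                f"cluster {bin(cluster)} does not align with the current tree"
            )  # unreachable for a pairwise-compatible system
        new = TreeNode(branch_length=weight, children=group)
        mask_of[id(new)] = cluster
        node.children = [c for c in node.children if c not in group] + [new]

    def order(node: TreeNode) -> int:
        if node.is_leaf:
            return taxa.index(node.label)
        return min(order(child) for child in node.children)

    def sort_children(node: TreeNode) -> None:
        node.children.sort(key=order)
        for child in node.children:
            sort_children(child)

    sort_children(root)
    return root


def tree_to_splits(tree: TreeNode, taxa: TaxonTable) -> SplitSystem:
    """One split per edge: leaves below the edge vs the rest, weight = length.

    If the same bipartition is induced by two edges (a degree-2 root), their
    branch lengths are summed, matching the unrooted reading of the tree.
    Counts are not recoverable from a tree and are set to zero.
    """
    n = taxa.n
    index = {name: i for i, name in enumerate(taxa.names)}
    weights: dict[int, float] = {}

    def visit(node: TreeNode) -> int:
        if node.is_leaf:
            if node.label not in index:
                raise ValueError(f"leaf {node.label!r} not in taxon table")
            mask = 1 << index[node.label]
        else:
            mask = 0
            for child in node.children:
                mask |= visit(child)
        if mask != (1 << n) - 1:  # skip the root edge
            side = canonical_side(mask, n)
            weights[side] = weights.get(side, 0.0) + node.branch_length
        return mask

    seen = visit(tree)
    if seen != (1 << n) - 1:
        raise ValueError("tree leaf set does not cover the taxon table")
    weighted = [
        WeightedSplit(split=Split(side=side, n=n), counts=SplitCounts(0, 0), weight=w)
        for side, w in weights.items()
    ]
    weighted.sort(key=sort_key)
    return SplitSystem(taxa=taxa, splits=tuple(weighted))


_LABEL_UNSAFE = re.compile(r"[\s;(),:]")


def _sanitize(label: str) -> str:
    return _LABEL_UNSAFE.sub("_", label)


def to_newick(tree: TreeNode) -> str:
    """Newick string, branch lengths with 6 significant digits, ';'-terminated."""

    def render(node: TreeNode, with_length: bool = True) -> str:
        if node.is_leaf:
            body = _sanitize(node.label)
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
        if with_length:
            body += f":{node.branch_length:.6g}"
        return body

    return render(tree, with_length=False) + ";\n"


def write_newick(tree: TreeNode, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree))


def read_newick(source: str, is_path: bool = True) -> TreeNode:
    """Parse a Newick tree (file path or literal string) into a :class:`TreeNode`."""
    if is_path:
        dtree = dendropy.Tree.get(path=source, schema="newick")
    else:
        dtree = dendropy.Tree.get(data=source, schema="newick")

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            label=dnode.taxon.label if dnode.taxon is not None else None,
            branch_length=dnode.edge.length if dnode.edge.length is not None else 0.0,
            children=[convert(child) for child in dnode.child_nodes()],
        )
        return node

    return convert(dtree.seed_node)
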