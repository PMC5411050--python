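"""Seeded synthetic tree generators (Yule, caterpillar, balanced).

Every stage of the pipeline is testable from these without external data.
Branch lengths are i.i.d. exponential by default, which exercises both the
minimum- and maximum-gap branches of the circle-stack clamp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree_io import PhyloTree, TreeNode


@dataclass
class TreeGenSpec:
    kind: str = "yule"  # yule | caterpillar | balanced
    n_leaves: int = 16
    seed: int = 0
    length_rate: float = 1.0  # exponential rate for branch lengths

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.length_rate <= 0:
            raise ValueError("length_rate must be > 0")
        if self.kind not in ("yule", "caterpillar", "balanced"):
            raise ValueError(f"unknown tree kind {self.kind!r}")


def _finish(root: TreeNode) -> PhyloTree:
    tree = PhyloTree(root=root)
    for k, leaf in enumerate(tree.leaves):
        if not leaf.name:
            leaf.name = f"T{k + 1}"
    return tree


def yule_tree(spec: TreeGenSpec) -> PhyloTree:
    """Pure-birth tree: split a uniformly chosen leaf until n_leaves.

    Branch lengths are i.i.d. exponential(length_rate). Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    root = TreeNode()
    if spec.n_leaves == 1:
        root.children = [TreeNode(parent=root)]
        tips = list(root.children)
    else:
        root.children = [TreeNode(parent=root), TreeNode(parent=root)]
        tips = list(root.children)
        while len(tips) < spec.n_leaves:
            idx = int(rng.integers(len(tips)))
            chosen = tips.pop(idx)
            chosen.children = [TreeNode(parent=chosen), TreeNode(parent=chosen)]
            tips.extend(chosen.children)
    tree = PhyloTree(root=root)
    for node in tree.nodes():  # pre-order: length draws are id-ordered
        if node is not root:
            node.branch_length = float(rng.exponential(1.0 / spec.length_rate))
    tree._reindex()  # refresh total_length after assigning lengths
    return _finish(tree.root)


def caterpillar_tree(n: int, branch_length: float = 1.0) -> PhyloTree:
    """Fully pectinate tree: leaf depths 1..n-1 with the deepest doubled."""
    if n < 2:
        raise ValueError("caterpillar needs n >= 2 leaves")
    root = TreeNode()
    cur = root
    for _ in range(n - 2):
        inner = TreeNode(parent=cur, branch_length=branch_length)
        leaf = TreeNode(parent=cur, branch_length=branch_length)
        cur.children = [inner, leaf]
        cur = inner
    cur.children = [
        TreeNode(parent=cur, branch_length=branch_length),
        TreeNode(parent=cur, branch_length=branch_length),
    ]
    return _finish(root)


def balanced_tree(depth: int, branch_length: float = 1.0) -> PhyloTree:
    """Complete binary tree with 2**depth leaves, all at the same depth."""
    if depth < 1:
        raise ValueError("balanced tree needs depth >= 1")

    def grow(node: TreeNode, remaining: int) -> None:
        if remaining == 0:
            return
        node.children = [
            TreeNode(parent=node, branch_length=branch_length),
            TreeNode(parent=node, branch_length=branch_length),
        ]
        for child in node.children:
            grow(child, remaining - 1)

    root = TreeNode()
    grow(root, depth)
    return _finish(root)


def generate(spec: TreeGenSpec) -> PhyloTree:
    if spec.kind == "yule":
        return yule_tree(spec)
    if spec.kind == "caterpillar":
        return caterpillar_tree(spec.n_leaves)
    return balanced_tree(max(1, int(np.log2(max(2, spec.n_leaves)))))
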