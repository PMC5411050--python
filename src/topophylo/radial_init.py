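"""Radial phylogram initial placement.

Leaves are spread evenly on a circle in Newick order; each internal node
sits at the mean of its children's angles at a radius proportional to its
topological depth (the "tightness" constant). Because subtree leaves are
angularly contiguous, clades start uncrossed, which is the whole point of
initializing this way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .stack_builder import StackConfig
from .tree_io import PhyloTree, TreeNode


@dataclass
class HomePositions:
    positions: dict[int, tuple[float, float]] = field(default_factory=dict)
    tightness: float = 100.0

    def __getitem__(self, node_id: int) -> tuple[float, float]:
        return self.positions[node_id]


def leaf_angles(tree: PhyloTree) -> dict[int, float]:
    """Angle 2*pi*k/n for leaf k of n, in Newick (left-to-right) order."""
    n = tree.n_leaves
    return {leaf.id: 2.0 * math.pi * k / n for k, leaf in enumerate(tree.leaves)}


def default_tightness(tree: PhyloTree, stack_config: StackConfig | None = None) -> float:
    """3 * gap_max * mean leaf depth: initial spacing comfortably exceeds
    typical rest distances so nothing starts deeply overlapped."""
    cfg = stack_config or StackConfig()
    mean_depth = sum(leaf.depth for leaf in tree.leaves) / tree.n_leaves
    return 3.0 * cfg.gap_max * mean_depth


def home_positions(tree: PhyloTree, tightness: float) -> HomePositions:
    """Radial embedding: radius = tightness * depth, root at the origin.

    Internal angles are the arithmetic mean of the children's angles (leaf
    angles are monotone in Newick order, so the mean always falls inside
    the clade's own sector, even for sectors wider than pi).
    """
    if tightness <= 0:
        raise ValueError("tightness must be positive")
    angles = dict(leaf_angles(tree))

    def resolve_angle(node: TreeNode) -> float:
        if node.id in angles:
            return angles[node.id]
        mean = sum(resolve_angle(c) for c in node.children) / len(node.children)
        angles[node.id] = mean
        return mean

    positions: dict[int, tuple[float, float]] = {}
    # post-order so children's angles exist before the parent's; iterative
    # to survive pectinate trees of arbitrary depth
    order: list[TreeNode] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(node.children)
    for node in reversed(order):
        theta = resolve_angle(node)
        r = tightness * node.depth
        positions[node.id] = (r * math.cos(theta), r * math.sin(theta))
    return HomePositions(positions=positions, tightness=tightness)
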