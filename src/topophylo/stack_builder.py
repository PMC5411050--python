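"""Circle stacks: one concentric circle per ancestor level of each leaf.

Circle area is proportional to the cumulative branch length from the leaf
up to the ancestor at that level, so radius = sqrt(area / pi). Consecutive
radii are clamped to differ by at least ``gap_min`` (15 px) and at most
``gap_max`` (30 px), which keeps tiny branches visible and huge branches
bounded. The smallest circle (the label circle) sits at the leaf's own
depth; the largest, at level 1, represents relatedness at the root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .tree_io import PhyloTree, TreeNode, path_length_to_ancestor


@dataclass(frozen=True)
class Circle:
    level: int
    radius: float  # px
    area_raw: float  # px^2, pre-clamp area at this level


@dataclass
class CircleStack:
    leaf_id: int
    circles: list[Circle] = field(default_factory=list)  # top (deepest) first

    def radius_at(self, level: int) -> float:
        for c in self.circles:
            if c.level == level:
                return c.radius
        raise KeyError(f"stack for leaf {self.leaf_id} has no level {level}")

    @property
    def top(self) -> Circle:
        return self.circles[0]

    @property
    def bottom(self) -> Circle:
        return self.circles[-1]


@dataclass
class StackConfig:
    gap_min: float = 15.0
    gap_max: float = 30.0
    top_radius: float = 12.0
    # px^2 of circle area per tree unit of branch length; None = choose per
    # tree so the deepest leaf's unclamped level-1 radius is 150 px
    unit_scale: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.gap_min <= self.gap_max:
            raise ValueError("require 0 < gap_min <= gap_max")
        if self.top_radius <= 0:
            raise ValueError("top_radius must be positive")


#: unclamped level-1 radius of the deepest leaf under the automatic scale
AUTO_SCALE_TARGET_RADIUS = 150.0


def radius_from_area(area: float) -> float:
    """Radius of a disk with the given area: sqrt(area / pi)."""
    if area < 0:
        raise ValueError(f"area must be non-negative, got {area}")
    return math.sqrt(area / math.pi)


def clamp_gap(proposed_gap: float, config: StackConfig) -> float:
    """Clamp an inter-circle radius difference into [gap_min, gap_max]."""
    return min(config.gap_max, max(config.gap_min, proposed_gap))


def resolve_unit_scale(tree: PhyloTree, config: StackConfig) -> float:
    """The configured unit_scale, or the per-tree automatic one."""
    if config.unit_scale is not None:
        return config.unit_scale
    longest = max(
        (path_length_to_ancestor(leaf, 1) for leaf in tree.leaves),
        default=0.0,
    )
    if longest <= 0:
        return 1.0
    return math.pi * AUTO_SCALE_TARGET_RADIUS**2 / longest


def build_stack(tree: PhyloTree, leaf: TreeNode, config: StackConfig) -> CircleStack:
    """Build the circle stack of one terminal node.

    Starts from the label circle (``top_radius``) at the leaf's own depth
    and walks toward the root, adding one circle per level whose radius is
    the previous radius plus the clamped area-based gap. Clamping is
    sequential from the top down, so radii are strictly increasing toward
    level 1 by construction.
    """
    if not leaf.is_leaf:
        raise ValueError("stacks exist only for terminal nodes")
    scale = resolve_unit_scale(tree, config)
    depth = leaf.depth
    circles = [Circle(level=depth, radius=config.top_radius, area_raw=0.0)]
    prev_radius = config.top_radius
    for level in range(depth - 1, 0, -1):
        area = scale * path_length_to_ancestor(leaf, level)
        proposed = radius_from_area(area) - prev_radius
        radius = prev_radius + clamp_gap(proposed, config)
        circles.append(Circle(level=level, radius=radius, area_raw=area))
        prev_radius = radius
    return CircleStack(leaf_id=leaf.id, circles=circles)


def build_all_stacks(tree: PhyloTree, config: StackConfig) -> dict[int, CircleStack]:
    """One stack per leaf, keyed by leaf id; deterministic."""
    resolved = StackConfig(
        gap_min=config.gap_min,
        gap_max=config.gap_max,
        top_radius=config.top_radius,
        unit_scale=resolve_unit_scale(tree, config),
    )
    return {leaf.id: build_stack(tree, leaf, resolved) for leaf in tree.leaves}
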