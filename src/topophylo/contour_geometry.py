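"""Per-level union-of-disks contours — the topographic bands.

At each level d the converged layout leaves one circle per sufficiently
deep leaf; overlapping circles of a level merge visually into one plateau.
Here that merge is made explicit geometry: the zero isocontour of the
union signed distance field f(x, y) = min_i (|x - c_i| - r_i), traced by
marching squares on a regular grid. Components of the circle-overlap graph
(an exact computation, independent of the raster) map contour polygons to
the leaf sets they enclose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Point, Polygon
from skimage import measure

from .stack_builder import CircleStack

#: padding beyond the biggest radius when sizing the raster, px
GRID_PAD = 4.0


@dataclass
class LevelContours:
    level: int
    polygons: list[np.ndarray] = field(default_factory=list)  # (k, 2) vertex arrays
    component_leaves: list[set[int]] = field(default_factory=list)


def _circles_at_level(
    stacks: dict[int, CircleStack],
    positions: dict[int, tuple[float, float]],
    level: int,
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Leaf ids, centers (m,2) and radii (m,) of circles present at a level."""
    ids, centers, radii = [], [], []
    for leaf_id, stack in stacks.items():
        for c in stack.circles:
            if c.level == level:
                ids.append(leaf_id)
                centers.append(positions[leaf_id])
                radii.append(c.radius)
                break
    return ids, np.asarray(centers, dtype=float), np.asarray(radii, dtype=float)


def level_components(
    stacks: dict[int, CircleStack],
    positions: dict[int, tuple[float, float]],
    level: int,
) -> list[set[int]]:
    """Connected components of the circle-overlap graph at one level.

    Two circles are joined iff their centers are closer than the sum of
    their radii. Returned in order of each component's smallest leaf id.
    """
    if level < 1:
        raise ValueError("levels start at 1")
    ids, centers, radii = _circles_at_level(stacks, positions, level)
    m = len(ids)
    if m == 0:
        return []
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    adj = dist < (radii[:, None] + radii[None, :])
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps: dict[int, set[int]] = {}
    for leaf_id, lab in zip(ids, labels):
        comps.setdefault(int(lab), set()).add(leaf_id)
    return sorted(comps.values(), key=min)


def extract_level_contours(
    stacks: dict[int, CircleStack],
    positions: dict[int, tuple[float, float]],
    level: int,
    grid_px: float = 2.0,
) -> LevelContours:
    """Trace the merged outline of all circles at one level.

    Marching squares on the signed distance field at spacing ``grid_px``;
    one closed polygon per connected blob, each mapped to the leaf ids
    whose circle centers it contains.
    """
    if grid_px <= 0:
        raise ValueError("grid_px must be positive")
    ids, centers, radii = _circles_at_level(stacks, positions, level)
    if len(ids) == 0:
        return LevelContours(level=level)

    pad = radii.max() + GRID_PAD
    x0, y0 = centers.min(axis=0) - pad
    x1, y1 = centers.max(axis=0) + pad
    xs = np.arange(x0, x1 + grid_px, grid_px)
    ys = np.arange(y0, y1 + grid_px, grid_px)
    gx, gy = np.meshgrid(xs, ys)  # rows follow y, cols follow x

    f = np.full(gx.shape, np.inf)
    for (cx, cy), r in zip(centers, radii):
        d = np.sqrt((gx - cx) ** 2 + (gy - cy) ** 2) - r
        np.minimum(f, d, out=f)

    # exact overlap-graph components; polygons get the exact leaf sets so
    # purity metrics never inherit raster error
    exact = level_components(stacks, positions, level)
    comp_of_leaf = {leaf_id: k for k, comp in enumerate(exact) for leaf_id in comp}

    polygons: list[np.ndarray] = []
    component_leaves: list[set[int]] = []
    for contour in measure.find_contours(f, 0.0):
        # rows are y indices, cols are x indices -> world coordinates
        world = np.column_stack(
            (x0 + contour[:, 1] * grid_px, y0 + contour[:, 0] * grid_px)
        )
        poly = Polygon(world)
        if not poly.is_valid or poly.area == 0:
            continue
        inside = {
            leaf_id
            for leaf_id, (cx, cy) in zip(ids, centers)
            if poly.contains(Point(cx, cy))
        }
        if not inside:
            continue  # raster sliver enclosing no circle center
        leafset: set[int] = set()
        for leaf_id in inside:
            leafset |= exact[comp_of_leaf[leaf_id]]
        polygons.append(world)
        component_leaves.append(leafset)
    return LevelContours(
        level=level, polygons=polygons, component_leaves=component_leaves
    )


def extract_all_contours(
    stacks: dict[int, CircleStack],
    positions: dict[int, tuple[float, float]],
    max_level: int,
    grid_px: float = 2.0,
) -> list[LevelContours]:
    return [
        extract_level_contours(stacks, positions, level, grid_px)
        for level in range(1, max_level + 1)
    ]


def clade_purity(tree, contours_by_level) -> dict[int, float]:
    """Fraction of components per level whose leaf set is exactly some
    clade (tree node at that depth with its descendant leaves).

    Computed from the exact overlap graph carried in ``component_leaves``,
    so raster error does not contaminate the metric. 1.0 at every level
    means the layout's spatial grouping reproduces the tree's clades.
    """
    # descendant leaf set of every node, one post-order pass
    order = list(tree.nodes())
    leafsets: dict[int, frozenset[int]] = {}
    for node in reversed(order):
        if node.is_leaf:
            leafsets[node.id] = frozenset({node.id})
        else:
            acc: frozenset[int] = frozenset()
            for child in node.children:
                acc |= leafsets[child.id]
            leafsets[node.id] = acc
    clades_by_depth: dict[int, list[frozenset[int]]] = {}
    for node in order:
        clades_by_depth.setdefault(node.depth, []).append(leafsets[node.id])

    purity: dict[int, float] = {}
    for lc in contours_by_level:
        comps = lc.component_leaves
        if not comps:
            purity[lc.level] = 1.0
            continue
        clades = set(clades_by_depth.get(lc.level, []))
        hits = sum(1 for comp in comps if frozenset(comp) in clades)
        purity[lc.level] = hits / len(comps)
    return purity
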